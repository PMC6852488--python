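"""Synthetic plant-seed-predator communities with full ground truth.

The generator emulates the statistical structure of a tropical-forest
seed-rearing study: a lognormal seed-rain distribution across plant
species, a strongly right-skewed predator diet-richness distribution
(most species monophagous, host ranges capped at 7), phylogenetically
clustered host ranges (extra hosts are congeners of the first host with
a configurable probability), binomial per-seed attack with at most one
predator developing per seed, and sampling effort that censors rare
interactions (a fixed per-species seed target, scaled down for the
rarest species).

Every random draw flows from a single integer seed, so whole communities
and their derived tables are bit-reproducible.  The latent ("true") web,
host sets and attack rates are retained so parameter-recovery tests can
compare estimates against ground truth.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import Dataset
from .signal import brownian_tips, tree_to_arrays

__all__ = [
    "SyntheticConfig",
    "SyntheticCommunity",
    "simulate_phylogeny",
    "simulate_community",
    "simulate_rearing",
    "simulate_traps",
    "simulate_dataset",
]

TRAIT_COLUMNS = [
    "seed_abundance",
    "max_height",
    "n_confamilials",
    "n_congenerics",
    "adult_abundance",
    "seed_mass",
    "endocarp_investment",
    "polyphenol_concentration",
    "seed_crop_cv",
    "fruiting_season",
    "cofruiting_overlap",
    "growth_form",
    "rgr",
]


@dataclass
class SyntheticConfig:
    """Study-condition defaults for the community generator.

    The defaults mirror the field design the analysis was built for:
    478 woody plant species and 369 seed-predator species (orders split
    60/30/10% Coleoptera/Lepidoptera/Hymenoptera), a 200-seed collection
    target per species, and a 100 m^2 trap network (200 traps of
    0.5 m^2).  The specialisation parameters put three quarters of
    predators on a single host and cap host ranges at 7, giving a mean
    latent diet richness near 1.25; extra hosts are congeneric with
    probability 0.375.
    """

    n_plants: int = 478
    n_predators: int = 369
    seed: int = 0
    abundance_mu: float = 1.0  # lognormal log-mean of seeds per m^2
    abundance_sigma: float = 1.5
    specialisation: float = 0.75  # P(monophagous)
    host_range_geometric_p: float = 0.5  # zero-truncated geometric for R >= 2 draws
    host_range_cap: int = 7
    phylo_clustering: float = 0.375  # P(extra host is congeneric)
    attack_beta_a: float = 1.0
    attack_beta_b: float = 9.0
    brood_size: int = 1
    rearing_success: float = 1.0
    dissection_sensitivity: float = 1.0
    sampling_effort: int = 200  # target seeds per plant species
    seeds_per_sample: int = 25
    undersample_quantile: float = 0.25  # rarest quarter gets reduced effort
    min_effort_fraction: float = 0.05
    trap_area: float = 100.0  # m^2, whole network
    trap_overdispersion: float = 1.0  # NB shape; np.inf -> Poisson
    zero_trap_fraction: float = 0.25  # rarest plants never seen in traps
    missing_spf_fraction: float = 0.06
    multiseed_fraction: float = 0.045
    genus_cut_depth: float = 0.8  # of unit tree depth; deeper cut -> fewer genera
    order_proportions: tuple[float, float, float] = (0.6, 0.3, 0.1)
    trait_missingness: float = 0.15
    trait_effects: dict = field(default_factory=dict)


@dataclass
class SyntheticCommunity:
    phylogeny: dendropy.Tree
    plants: pd.DataFrame  # species, genus, density, traits...
    predators: pd.DataFrame  # species, order, host ranges
    links: pd.DataFrame  # plant_species, insect_species, attack_rate
    true_alpha: pd.DataFrame  # plants x predators kill density (per m^2)
    config: SyntheticConfig


def simulate_phylogeny(
    n_tips: int, seed: int | None = None, genus_cut_depth: float = 0.8
) -> dendropy.Tree:
    """Yule pure-birth tree scaled to unit depth, tips named Gxxx_spyyy.

    Genera are induced by cutting the tree at ``genus_cut_depth``: every
    lineage crossing that depth founds a genus and its descendant tips
    share the genus token.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    max_depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= max_depth
    tree.calc_node_root_distances(return_leaf_distances_only=False)

    # genus assignment: each edge crossing the cut depth founds a genus
    genus_counter = itertools.count(1)
    sp_counter = itertools.count(1)

    def assign(node, genus):
        depth = node.root_distance
        parent_depth = depth - (node.edge.length or 0.0)
        if genus is None and depth >= genus_cut_depth > parent_depth:
            genus = f"G{next(genus_counter):03d}"
        if node.is_leaf():
            if genus is None:  # tip shallower than the cut: own genus
                genus = f"G{next(genus_counter):03d}"
            node.taxon.label = f"{genus}_sp{next(sp_counter):03d}"
        else:
            for child in node.child_nodes():
                assign(child, genus)

    assign(tree.seed_node, None)
    tree.taxon_namespace.sort(key=lambda t: t.label)
    return tree


def _kill_probabilities(rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """P(seed killed by predator k) under independent attack with uniform
    resolution when several predators strike the same seed."""
    L = len(rates)
    if L == 1:
        return rates.copy()
    if L <= 16:
        probs = np.zeros(L)
        for mask in range(1, 1 << L):
            members = [k for k in range(L) if mask >> k & 1]
            p = 1.0
            for k in range(L):
                p *= rates[k] if (mask >> k & 1) else 1.0 - rates[k]
            for k in members:
                probs[k] += p / len(members)
        return probs
    draws = rng.random((200_000, L)) < rates
    hits = draws.sum(axis=1)
    weights = np.where(hits > 0, 1.0 / np.maximum(hits, 1), 0.0)
    return (draws * weights[:, None]).mean(axis=0)


def simulate_community(config: SyntheticConfig) -> SyntheticCommunity:
    """Draw a full latent community (plants, traits, predators, links)."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_phylogeny(
        config.n_plants, seed=int(rng.integers(2**31 - 1)), genus_cut_depth=config.genus_cut_depth
    )
    arr = tree_to_arrays(tree)
    species = list(arr.labels)
    genera = [s.split("_")[0] for s in species]
    density = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=len(species))

    plants = pd.DataFrame({"plant_species": species, "genus": genera, "density": density})
    plants = pd.concat([plants, _simulate_traits(arr, plants, rng, config)], axis=1)

    orders = rng.choice(
        ["Coleoptera", "Lepidoptera", "Hymenoptera"],
        size=config.n_predators,
        p=list(config.order_proportions),
    )
    predators = pd.DataFrame(
        {
            "insect_species": [f"pred{j:04d}" for j in range(1, config.n_predators + 1)],
            "insect_order": orders,
        }
    )

    genus_members: dict[str, list[int]] = {}
    for i, g in enumerate(genera):
        genus_members.setdefault(g, []).append(i)

    link_rows = []
    for j, pred in enumerate(predators["insect_species"]):
        if rng.random() < config.specialisation:
            R = 1
        else:
            R = min(int(rng.geometric(config.host_range_geometric_p)), config.host_range_cap)
        first = int(rng.integers(len(species)))
        hosts = [first]
        while len(hosts) < R:
            congeners = [i for i in genus_members[genera[first]] if i not in hosts]
            if congeners and rng.random() < config.phylo_clustering:
                hosts.append(int(rng.choice(congeners)))
            else:
                remaining = np.setdiff1d(np.arange(len(species)), hosts)
                hosts.append(int(rng.choice(remaining)))
        for i in hosts:
            link_rows.append(
                {
                    "plant_species": species[i],
                    "insect_species": pred,
                    "attack_rate": float(
                        rng.beta(config.attack_beta_a, config.attack_beta_b)
                    ),
                }
            )
    links = pd.DataFrame(link_rows)

    # latent kill densities, accounting for the one-predator-per-seed rule
    alpha = pd.DataFrame(
        0.0, index=species, columns=list(predators["insect_species"])
    )
    for plant, group in links.groupby("plant_species"):
        rates = group["attack_rate"].to_numpy()
        kill = _kill_probabilities(rates, rng)
        dens = float(plants.loc[plants["plant_species"] == plant, "density"].iloc[0])
        for (_, row), p_kill in zip(group.iterrows(), kill):
            alpha.loc[plant, row["insect_species"]] = dens * p_kill

    return SyntheticCommunity(tree, plants, predators, links, alpha, config)


def _simulate_traits(
    arr, plants: pd.DataFrame, rng: np.random.Generator, config: SyntheticConfig
) -> pd.DataFrame:
    """Trait table with phylogenetic structure and injected missingness."""
    n = len(plants)
    bm = brownian_tips(arr, 8, rng)  # shared Brownian backbone, unit rate
    genera = plants["genus"]
    fam_proxy = genera.str.slice(0, 2)  # coarse clades standing in for families
    traits = pd.DataFrame(index=plants.index)
    traits["seed_abundance"] = np.log10(plants["density"]) + rng.normal(0, 0.2, n)
    traits["max_height"] = 5 + 15 * np.exp(bm[0]) / (1 + np.exp(bm[0])) + rng.normal(0, 2, n)
    traits["n_confamilials"] = fam_proxy.map(fam_proxy.value_counts()) - 1
    traits["n_congenerics"] = genera.map(genera.value_counts()) - 1
    traits["adult_abundance"] = np.exp(rng.normal(2, 1, n))
    traits["seed_mass"] = np.exp(bm[1] + rng.normal(0, 0.5, n))
    traits["endocarp_investment"] = np.clip(0.3 + 0.2 * bm[2] + rng.normal(0, 0.1, n), 0, 1)
    traits["polyphenol_concentration"] = np.exp(0.5 * bm[3] + rng.normal(0, 0.3, n))
    traits["seed_crop_cv"] = np.abs(1 + 0.5 * bm[4] + rng.normal(0, 0.3, n))
    traits["fruiting_season"] = np.where(bm[5] + rng.normal(0, 0.5, n) > 0, "wet", "dry")
    traits["cofruiting_overlap"] = np.clip(0.5 + 0.2 * bm[6] + rng.normal(0, 0.1, n), 0, 1)
    traits["growth_form"] = np.select(
        [bm[7] < -0.5, bm[7] > 0.5], ["liana", "shrub"], default="tree"
    )
    traits["rgr"] = np.abs(rng.normal(1, 0.3, n))
    if config.trait_missingness > 0:
        for col in TRAIT_COLUMNS:
            mask = rng.random(n) < config.trait_missingness
            traits.loc[mask, col] = np.nan
    return traits


def simulate_rearing(
    community: SyntheticCommunity, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rearing samples and emergence records for a community.

    Effort per species targets ``sampling_effort`` seeds, scaled down by
    density rank for the rarest quarter (rank-based rather than random so
    the well-sampled subset is stable across seeds at fixed config).
    Each seed is attacked independently by each of the plant's linked
    predators; simultaneous strikes are resolved uniformly, so at most
    one predator develops per seed.  Dissections score attacked seeds as
    predated with probability ``dissection_sensitivity``.
    """
    config = community.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    plants = community.plants
    ranks = plants["density"].rank(pct=True)
    effort_frac = np.clip(
        ranks / max(config.undersample_quantile, 1e-9), config.min_effort_fraction, 1.0
    )
    links_by_plant = {
        plant: grp for plant, grp in community.links.groupby("plant_species")
    }
    order_of = dict(
        zip(community.predators["insect_species"], community.predators["insect_order"])
    )

    dates = pd.date_range("2010-07-01", "2013-11-30", freq="D")
    rearing_rows, emergence_rows = [], []
    sample_counter = itertools.count(1)
    for (_, plant_row), frac in zip(plants.iterrows(), effort_frac):
        plant = plant_row["plant_species"]
        target = max(1, int(round(config.sampling_effort * frac)))
        n_samples = max(1, int(round(target / config.seeds_per_sample)))
        sizes = rng.multinomial(target, np.full(n_samples, 1 / n_samples))
        sizes = sizes[sizes > 0]
        grp = links_by_plant.get(plant)
        rates = grp["attack_rate"].to_numpy() if grp is not None else np.empty(0)
        preds = list(grp["insect_species"]) if grp is not None else []
        for size in sizes:
            sid = f"S{next(sample_counter):06d}"
            attacked_by = np.zeros(len(preds), dtype=np.int64)
            n_attacked = 0
            if preds:
                strikes = rng.random((size, len(preds))) < rates
                hits = strikes.sum(axis=1)
                for s in np.nonzero(hits)[0]:
                    winners = np.nonzero(strikes[s])[0]
                    attacked_by[rng.choice(winners)] += 1
                n_attacked = int((hits > 0).sum())
            n_predated = int(rng.binomial(n_attacked, config.dissection_sensitivity))
            rearing_rows.append(
                {
                    "sample_id": sid,
                    "plant_species": plant,
                    "date": str(dates[int(rng.integers(len(dates)))].date()),
                    "site": "mainland" if rng.random() < 0.024 else "island",
                    "maturity": "mature" if rng.random() < 0.8 else "immature",
                    "n_seeds": int(size),
                    "n_fruits": 0,
                    "n_seeds_dissected": int(size),
                    "n_seeds_predated": n_predated,
                }
            )
            for k, pred in enumerate(preds):
                emerged = int(
                    rng.binomial(attacked_by[k] * config.brood_size, config.rearing_success)
                )
                if emerged > 0:
                    emergence_rows.append(
                        {
                            "sample_id": sid,
                            "insect_species": pred,
                            "insect_order": order_of[pred],
                            "insect_family": "fam1",
                            "life_stage": "adult",
                            "count": emerged,
                            "is_seed_predator": True,
                        }
                    )
    rearing = pd.DataFrame(rearing_rows)
    emergence_cols = [
        "sample_id",
        "insect_species",
        "insect_order",
        "insect_family",
        "life_stage",
        "count",
        "is_seed_predator",
    ]
    emergences = pd.DataFrame(emergence_rows, columns=emergence_cols)
    return rearing, emergences


def simulate_traps(
    community: SyntheticCommunity, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Seed-trap records: negative-binomial counts of the latent seed rain.

    The rarest ``zero_trap_fraction`` of species is truncated to zero
    (reared but never trapped, hence excluded from the web); a further
    fraction lacks seeds-per-fruit metadata, and a small fraction is
    flagged as multi-seeded-fruit feeders to exercise both exclusion
    rules downstream.
    """
    config = community.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    plants = community.plants
    mu = plants["density"].to_numpy() * config.trap_area
    k = config.trap_overdispersion
    if np.isinf(k):
        seeds = rng.poisson(mu)
    else:
        seeds = rng.negative_binomial(k, k / (k + mu))
    ranks = plants["density"].rank(pct=True).to_numpy()
    seeds = np.where(ranks <= config.zero_trap_fraction, 0, seeds)
    spf = np.round(np.exp(rng.normal(0.5, 0.8, len(plants))) + 0.5)
    missing = rng.random(len(plants)) < config.missing_spf_fraction
    multiseed = rng.random(len(plants)) < config.multiseed_fraction
    return pd.DataFrame(
        {
            "plant_species": plants["plant_species"],
            "seeds_observed": seeds.astype(int),
            "trap_area_m2": config.trap_area,
            "seeds_per_fruit": np.where(missing, np.nan, spf),
            "multiseed_excluded": multiseed,
        }
    )


def simulate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[Dataset, SyntheticCommunity]:
    """One call from config to a validated :class:`~seedweb.io.Dataset`."""
    config = config or SyntheticConfig()
    community = simulate_community(config)
    rearing, emergences = simulate_rearing(community)
    traps = simulate_traps(community)
    traits = community.plants[["plant_species"] + TRAIT_COLUMNS].copy()
    dataset = Dataset(
        rearing=rearing,
        emergences=emergences,
        traps=traps,
        traits=traits,
        phylogeny=community.phylogeny,
    )
    return dataset, community
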