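"""End-to-end orchestration: one config in, one report bundle out.

``run_all`` executes summarise -> build_web -> specialisation metrics ->
PAC -> phylogenetic signal -> trait models in order and aggregates every
statistic, the exact configuration and the package version into a single
JSON-serialisable report.  Each random stage receives its own seed
derived by hashing (top-level seed, stage name), so any stage is
reproducible in isolation and independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import build_web, detection_curve, list_associations, summarise_plants
from .io import Dataset, read_dataset, write_web
from .pac import pac_exceedance, pac_matrix, pac_phylo_correlation
from .signal import blomberg_K, fritz_purvis_D, genus_of, graft_at_genus
from .specialisation import (
    H2_prime,
    chao1_coverage,
    compare_orders_dprime,
    connectance,
    d_prime_all,
    diet_richness,
)
from .simulate import SyntheticConfig, simulate_dataset
from .traits import run_trait_analysis

__all__ = ["RunConfig", "run_all", "stage_seed", "prepare_tree"]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; every field has a default."""

    rearing: str | None = None
    emergence: str | None = None
    traps: str | None = None
    traits: str | None = None
    tree: str | None = None
    seed: int = 0
    well_sampled_threshold: int = 200
    drop_singletons: bool = False
    orders: tuple[str, ...] = ("Coleoptera", "Lepidoptera")
    pac_threshold: float = 0.1
    min_individuals: int = 10
    n_perm: int = 1000
    n_rand: int = 999
    n_trees: int = 500
    skip: tuple[str, ...] = ()
    outdir: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed by hashing (top seed, stage name)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def prepare_tree(tree, species):
    """Graft data species missing from the tree at their genus; drop the rest.

    Returns (tree, grafted_names, dropped_names).
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    grafted, dropped = [], []
    for sp in species:
        if sp in tips:
            continue
        try:
            tree = graft_at_genus(tree, sp, genus_of(sp))
            tips.add(sp)
            grafted.append(sp)
        except ValueError:
            dropped.append(sp)
    return tree, grafted, dropped


def _load(config: RunConfig) -> tuple[Dataset, object | None]:
    if config.rearing is not None:
        paths = {
            "rearing": config.rearing,
            "emergence": config.emergence,
            "traps": config.traps,
            "traits": config.traits,
        }
        return read_dataset(paths, phylogeny_path=config.tree), None
    syn = SyntheticConfig(seed=stage_seed(config.seed, "simulate"), **config.synthetic)
    dataset, community = simulate_dataset(syn)
    return dataset, community


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; any stage failure aborts with its name."""
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    stage = "load"
    try:
        dataset, community = _load(config)

        stage = "summarise"
        summaries = summarise_plants(dataset, config.well_sampled_threshold)
        det = detection_curve(summaries)
        report["stages"]["summaries"] = {
            "n_plant_species": int(len(summaries)),
            "n_well_sampled": int(summaries["well_sampled"].sum()),
            "n_attacked": int(summaries["predator_incidence"].sum()),
            "attacked_fraction": float(summaries["predator_incidence"].mean()),
            "attacked_fraction_well_sampled": float(
                summaries.loc[summaries["well_sampled"], "predator_incidence"].mean()
            ),
            "detection_slope": _nan_to_none(det.slope),
            "detection_p": _nan_to_none(det.p_value),
            "detection_slope_well_sampled": _nan_to_none(det.slope_well_sampled),
            "detection_p_well_sampled": _nan_to_none(det.p_value_well_sampled),
        }

        stage = "associations"
        assoc = list_associations(dataset)
        chao = chao1_coverage(assoc["n_individuals"])
        richness = diet_richness(dataset, config.min_individuals)
        richness_all = diet_richness(dataset, 1)
        report["stages"]["associations"] = {
            "n_interactions": int(len(assoc)),
            "chao1": vars(chao),
            "mean_diet_richness": float(richness_all["richness"].mean()),
            "max_diet_richness": int(richness_all["richness"].max()),
            "n_predators_min_individuals": int(len(richness)),
            "monophagy_fraction": float((richness["richness"] == 1).mean())
            if len(richness)
            else None,
        }

        stage = "build_web"
        web = None
        if "build_web" not in config.skip and dataset.traps is not None:
            web = build_web(
                dataset,
                assoc,
                drop_singletons=config.drop_singletons,
                orders=set(config.orders),
            )
            report["stages"]["web"] = {
                "n_plants": web.n_plants,
                "n_predators": web.n_predators,
                "n_links": int((web.alpha > 0).sum()),
                "n_exclusions": len(web.exclusion_log),
                "exclusion_reasons": _reason_counts(web.exclusion_log),
            }

        stage = "metrics"
        if web is not None and "metrics" not in config.skip:
            total_individuals = _individuals_in_web(assoc, web)
            d_all = d_prime_all(web, integer_total=total_individuals)
            d_series = pd.Series(d_all, index=web.predators)
            order_of = dict(zip(assoc["insect_species"], assoc["insect_order"]))
            groups = {
                o: d_series[[p for p in web.predators if order_of.get(p) == o]].to_numpy()
                for o in config.orders
            }
            wilcoxon = None
            if all(len(v) > 0 for v in groups.values()) and len(groups) == 2:
                wilcoxon = compare_orders_dprime(groups)
            report["stages"]["metrics"] = {
                "connectance": connectance(web),
                "H2_prime": H2_prime(web, integer_total=total_individuals),
                "median_d_prime": float(np.median(d_all)),
                "d_prime_range": [float(d_all.min()), float(d_all.max())],
                "wilcoxon_orders": wilcoxon,
                "integer_total": total_individuals,
            }
            report["d_prime"] = {k: float(v) for k, v in d_series.items()}

        stage = "pac"
        if web is not None and "pac" not in config.skip:
            pac = pac_matrix(web)
            exceed = pac_exceedance(pac, config.pac_threshold)
            entry = {"exceedance": exceed}
            if dataset.phylogeny is not None:
                try:
                    entry["phylo_correlation"] = pac_phylo_correlation(
                        pac, dataset.phylogeny
                    )
                except ValueError as err:
                    entry["phylo_correlation"] = {"error": str(err)}
            report["stages"]["pac"] = entry

        stage = "phylo_signal"
        if dataset.phylogeny is not None and "phylo_signal" not in config.skip:
            ws = summaries[summaries["well_sampled"]]
            tree, grafted, droppedlist = prepare_tree(dataset.phylogeny, list(ws.index))
            usable = [s for s in ws.index if s not in droppedlist]
            sig = {"n_grafted": len(grafted), "n_dropped": len(droppedlist)}
            incidence = ws.loc[usable, "predator_incidence"].astype(int)
            if incidence.nunique() == 2:
                d_res = fritz_purvis_D(
                    tree, incidence, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, "fritz_purvis_D"),
                )
                sig["incidence_D"] = {
                    "D": d_res.D,
                    "p_D_less_1": d_res.p_D_less_1,
                    "p_D_greater_0": d_res.p_D_greater_0,
                }
            for resp in ("predator_richness", "predation_rate"):
                series = ws.loc[usable, resp].dropna().astype(float)
                if series.var() > 0:
                    k_res = blomberg_K(
                        tree, series, n_rand=config.n_rand,
                        seed=stage_seed(config.seed, f"blomberg_K:{resp}"),
                    )
                    sig[f"{resp}_K"] = {"K": k_res.K, "p": k_res.p}
            report["stages"]["phylo_signal"] = sig

        stage = "traits"
        if dataset.traits is not None and "traits" not in config.skip:
            results = run_trait_analysis(
                dataset,
                n_trees=config.n_trees,
                seed=stage_seed(config.seed, "traits"),
                well_sampled_threshold=config.well_sampled_threshold,
            )
            report["stages"]["traits"] = {
                run: {
                    resp: {
                        "kappa": res.kappa,
                        "pseudo_R2": res.pseudo_R2,
                        "n_species": res.n_species,
                        "top_traits": list(res.importances.index[:3]),
                        "importances": {k: float(v) for k, v in res.importances.items()},
                    }
                    for resp, res in by_resp.items()
                }
                for run, by_resp in results.items()
            }
        for name in config.skip:
            report["stages"].setdefault(name, "skipped")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        if web is not None:
            write_web(web, outdir / "web.csv")
        if "d_prime" in report:
            pd.Series(report["d_prime"]).rename("d_prime").to_csv(
                outdir / "d_prime.csv", index_label="insect_species"
            )
    return report


def _individuals_in_web(assoc: pd.DataFrame, web) -> int:
    plants = set(web.plants)
    preds = set(web.predators)
    mask = assoc["plant_species"].isin(plants) & assoc["insect_species"].isin(preds)
    total = int(assoc.loc[mask, "n_individuals"].sum())
    return max(total, 1)


def _reason_counts(log):
    out: dict[str, int] = {}
    for _, reason in log:
        out[reason] = out.get(reason, 0) + 1
    return out


def _nan_to_none(x):
    if x is None:
        return None
    x = float(x)
    return None if np.isnan(x) else x


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
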