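"""Aggregation of rearing data into per-plant summaries and the
quantitative food web.

The response variables per plant species are the incidence of seed
predators (was any seed predator reared), seed predator richness (number
of seed-predator species reared) and the seed predation rate (proportion
of dissected seeds with evidence of attack).  Plant species with at least
``well_sampled_threshold`` seeds (200 by default) are flagged
well-sampled; below that sample size the probability of detecting a
predator at all still depends on effort.

Link weights in the quantitative web are estimated seeds killed per m^2:

    alpha_ik = density_i * attacked_seeds_ik / seeds_sampled_i

where attacked_seeds_ik is the number of sampled seeds of plant i
attributed to predator k and density_i is the seed rain measured by the
trap network.  Exclusion rules applied while building the web (species
absent from traps, Hymenoptera, multi-seeded-fruit feeders, missing
seeds-per-fruit metadata) are recorded in the web's exclusion log.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Dataset, QuantitativeWeb, normalise_name

__all__ = [
    "summarise_plants",
    "list_associations",
    "build_web",
    "detection_curve",
    "DetectionCurve",
]

DEFAULT_ORDERS = frozenset({"Coleoptera", "Lepidoptera"})


def summarise_plants(
    dataset: Dataset, well_sampled_threshold: int = 200
) -> pd.DataFrame:
    """Per-plant response variables.

    Returns a DataFrame indexed by plant species with columns
    ``total_seeds, total_fruits, n_samples, predator_incidence,
    predator_richness, seeds_dissected, seeds_predated, predation_rate,
    well_sampled``.  ``predation_rate`` is NaN for species with no
    dissected seeds.  Only emergences flagged as seed predators count
    towards incidence and richness.
    """
    r = dataset.rearing
    agg = r.groupby("plant_species", sort=True).agg(
        total_seeds=("n_seeds", "sum"),
        total_fruits=("n_fruits", "sum"),
        n_samples=("sample_id", "count"),
        seeds_dissected=("n_seeds_dissected", "sum"),
        seeds_predated=("n_seeds_predated", "sum"),
    )
    em = dataset.emergences
    em = em[em["is_seed_predator"]]
    em = em.merge(
        r[["sample_id", "plant_species"]], on="sample_id", how="left"
    )
    richness = em.groupby("plant_species")["insect_species"].nunique()
    agg["predator_richness"] = richness.reindex(agg.index).fillna(0).astype(int)
    agg["predator_incidence"] = agg["predator_richness"] > 0
    with np.errstate(invalid="ignore"):
        agg["predation_rate"] = np.where(
            agg["seeds_dissected"] > 0,
            agg["seeds_predated"] / agg["seeds_dissected"].replace(0, np.nan),
            np.nan,
        )
    agg["well_sampled"] = agg["total_seeds"] >= well_sampled_threshold
    return agg


def list_associations(dataset: Dataset) -> pd.DataFrame:
    """One row per (plant, seed-predator) pair with >= 1 reared individual.

    Columns: ``plant_species, insect_species, insect_order,
    n_individuals, n_samples_observed, attributed_seeds,
    emergence_per_attacked_seed, fallback``.

    Within a plant, predated-seed counts are apportioned among its
    predator species proportionally to reared-individual counts (at a
    provisional one insect per seed); the emergence-per-attacked-seed
    ratio is then re-estimated per association.  When individuals emerged
    but no seed was scored predated (conservative dissection scoring) the
    ratio falls back to 1.0 and the attacked-seed count is imputed as the
    individual count, with ``fallback=True``.
    """
    r = dataset.rearing
    em = dataset.emergences
    em = em[em["is_seed_predator"]]
    em = em.merge(r[["sample_id", "plant_species"]], on="sample_id", how="left")
    assoc = em.groupby(["plant_species", "insect_species"], as_index=False).agg(
        insect_order=("insect_order", "first"),
        n_individuals=("count", "sum"),
        n_samples_observed=("sample_id", "nunique"),
    )
    predated = r.groupby("plant_species")["n_seeds_predated"].sum()
    total_ind = assoc.groupby("plant_species")["n_individuals"].transform("sum")
    plant_predated = assoc["plant_species"].map(predated).fillna(0)
    attributed = plant_predated * assoc["n_individuals"] / total_ind
    fallback = attributed <= 0
    attributed = attributed.where(~fallback, assoc["n_individuals"].astype(float))
    eps = assoc["n_individuals"] / attributed
    assoc["attributed_seeds"] = attributed
    assoc["emergence_per_attacked_seed"] = eps.where(~fallback, 1.0)
    assoc["fallback"] = fallback
    return assoc


def build_web(
    dataset: Dataset,
    associations: pd.DataFrame | None = None,
    *,
    drop_singletons: bool = False,
    orders: frozenset[str] | set[str] = DEFAULT_ORDERS,
) -> QuantitativeWeb:
    """Build the quantitative plant x seed-predator web.

    Exclusion rules (each removal is recorded in ``exclusion_log``):

    - plants never observed in the seed traps (no density estimate);
    - Hymenoptera, always (no reliable per-seed emergence counts), plus
      any order outside ``orders``;
    - plants flagged ``multiseed_excluded`` in the trap table (predators
      consume several small seeds inside one fruit, kills unquantifiable);
    - plants with fruit collections but no seeds-per-fruit metadata;
    - with ``drop_singletons``, associations seen once (one individual in
      one sample);
    - plants or predators left with no positive link.

    Raises ``ValueError`` if nothing remains.
    """
    if dataset.traps is None:
        raise ValueError("a trap table is required to build the web")
    if associations is None:
        associations = list_associations(dataset)
    assoc = associations.copy()
    log: list[tuple[str, str]] = []

    if "Hymenoptera" in orders:
        orders = set(orders) - {"Hymenoptera"}
    for name in sorted(set(assoc.loc[~assoc["insect_order"].isin(orders), "insect_species"])):
        log.append((name, "order_excluded"))
    assoc = assoc[assoc["insect_order"].isin(orders)]

    traps = dataset.traps
    dens = {}
    spf = {}
    meta_missing = set()
    multiseed = set()
    for _, row in traps.iterrows():
        key = normalise_name(row["plant_species"])
        dens[key] = row["seeds_observed"] / row["trap_area_m2"]
        if pd.isna(row.get("seeds_per_fruit")):
            meta_missing.add(key)
        else:
            spf[key] = float(row["seeds_per_fruit"])
        if bool(row.get("multiseed_excluded", False)):
            multiseed.add(key)

    r = dataset.rearing.copy()
    r["_key"] = r["plant_species"].map(normalise_name)
    totals = r.groupby("_key").agg(
        n_seeds=("n_seeds", "sum"), n_fruits=("n_fruits", "sum")
    )
    # fruit collections are converted to seed equivalents with the
    # per-species mean seeds-per-fruit from the trap metadata
    seeds_sampled = {
        key: row["n_seeds"] + row["n_fruits"] * spf.get(key, 1.0)
        for key, row in totals.iterrows()
    }

    assoc["_key"] = assoc["plant_species"].map(normalise_name)
    keep_rows = []
    for _, row in assoc.iterrows():
        key = row["_key"]
        plant = row["plant_species"]
        if key not in dens or dens[key] <= 0:
            log.append((plant, "absent_from_traps"))
        elif key in multiseed:
            log.append((plant, "multiseeded_fruit_excluded"))
        elif key in meta_missing:
            log.append((plant, "missing_seeds_per_fruit"))
        elif drop_singletons and row["n_individuals"] == 1 and row["n_samples_observed"] == 1:
            log.append((f"{plant} x {row['insect_species']}", "singleton_dropped"))
        else:
            keep_rows.append(True)
            continue
        keep_rows.append(False)
    assoc = assoc[np.array(keep_rows, dtype=bool)] if keep_rows else assoc.iloc[:0]
    if assoc.empty:
        raise ValueError("no links remain after exclusions; web would be empty")

    plants_raw = {}
    for _, row in assoc.iterrows():
        plants_raw.setdefault(row["_key"], row["plant_species"])
    predators_raw = sorted(set(assoc["insect_species"]))
    p_index = {k: i for i, k in enumerate(plants_raw)}
    k_index = {k: i for i, k in enumerate(predators_raw)}
    alpha = np.zeros((len(p_index), len(k_index)))
    for _, row in assoc.iterrows():
        i = p_index[row["_key"]]
        k = k_index[row["insect_species"]]
        n_sampled = seeds_sampled.get(row["_key"], np.nan)
        alpha[i, k] += dens[row["_key"]] * row["attributed_seeds"] / n_sampled

    density = np.array([dens[k] for k in p_index])
    plants = [plants_raw[k] for k in p_index]

    # drop empty rows/columns (can arise only via singleton dropping)
    row_ok = alpha.sum(axis=1) > 0
    col_ok = alpha.sum(axis=0) > 0
    for name, ok in zip(plants, row_ok):
        if not ok:
            log.append((name, "no_positive_links"))
    for name, ok in zip(predators_raw, col_ok):
        if not ok:
            log.append((name, "no_positive_links"))
    alpha = alpha[np.ix_(row_ok, col_ok)]
    plants = [p for p, ok in zip(plants, row_ok) if ok]
    predators = [p for p, ok in zip(predators_raw, col_ok) if ok]
    density = density[row_ok]

    # canonical ordering: descending marginal totals, ties alphabetical
    row_order = sorted(
        range(len(plants)), key=lambda i: (-alpha[i].sum(), plants[i])
    )
    col_order = sorted(
        range(len(predators)), key=lambda k: (-alpha[:, k].sum(), predators[k])
    )
    return QuantitativeWeb(
        plants=[plants[i] for i in row_order],
        predators=[predators[k] for k in col_order],
        alpha=alpha[np.ix_(row_order, col_order)],
        plant_density=density[row_order],
        exclusion_log=log,
    )


@dataclass
class DetectionCurve:
    """Logistic fit of predator detection probability on sampling effort."""

    slope: float
    p_value: float
    fitted: pd.Series
    slope_well_sampled: float | None
    p_value_well_sampled: float | None
    degenerate: bool


def detection_curve(summaries: pd.DataFrame) -> DetectionCurve:
    """Fit P(incidence) against log10(total seeds) by logistic regression.

    Also refits on the well-sampled subset only; above the 200-seed
    threshold the detection/effort relationship is expected to vanish.
    Returns a degenerate-fit flag when incidence is constant or fewer than
    two species are available.
    """
    y = summaries["predator_incidence"].astype(float)
    if len(summaries) < 2 or y.nunique() < 2:
        return DetectionCurve(np.nan, np.nan, pd.Series(dtype=float), None, None, True)
    x = np.log10(summaries["total_seeds"].astype(float).clip(lower=1))
    X = sm.add_constant(x.to_numpy())
    fit = sm.Logit(y.to_numpy(), X).fit(disp=0)
    slope, p = fit.params[1], fit.pvalues[1]
    fitted = pd.Series(fit.predict(X), index=summaries.index)

    ws = summaries[summaries["well_sampled"]]
    slope_ws = p_ws = None
    if len(ws) >= 2 and ws["predator_incidence"].astype(float).nunique() == 2:
        xw = np.log10(ws["total_seeds"].astype(float))
        Xw = sm.add_constant(xw.to_numpy())
        try:
            fw = sm.Logit(ws["predator_incidence"].astype(float).to_numpy(), Xw).fit(
                disp=0
            )
            slope_ws, p_ws = fw.params[1], fw.pvalues[1]
        except Exception:
            pass
    return DetectionCurve(slope, p, fitted, slope_ws, p_ws, False)
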