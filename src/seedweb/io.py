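"""Domain containers and CSV/Newick readers and writers.

All tabular inputs are UTF-8, comma-separated CSV with a mandatory header
row.  Species names are matched after trimming, collapsing internal
whitespace and case-folding, but the original spelling is preserved on
output.  The documented schemas:

``rearing.csv``
    sample_id, plant_species, date, site, maturity, n_seeds, n_fruits,
    n_seeds_dissected, n_seeds_predated
``emergence.csv``
    sample_id, insect_species, insect_order, insect_family, life_stage,
    count, is_seed_predator
``traps.csv``
    plant_species, seeds_observed, trap_area_m2, seeds_per_fruit
    (optional extra column: multiseed_excluded)
``traits.csv``
    plant_species plus one column per trait (numeric or categorical,
    missing values allowed)

The phylogeny is standard Newick with branch lengths, read through
dendropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ReferentialError",
    "Dataset",
    "QuantitativeWeb",
    "normalise_name",
    "read_dataset",
    "read_newick",
    "write_newick",
    "write_web",
    "read_web",
]

REARING_COLUMNS = [
    "sample_id",
    "plant_species",
    "date",
    "site",
    "maturity",
    "n_seeds",
    "n_fruits",
    "n_seeds_dissected",
    "n_seeds_predated",
]
EMERGENCE_COLUMNS = [
    "sample_id",
    "insect_species",
    "insect_order",
    "insect_family",
    "life_stage",
    "count",
    "is_seed_predator",
]
TRAP_COLUMNS = ["plant_species", "seeds_observed", "trap_area_m2", "seeds_per_fruit"]

KNOWN_ORDERS = ("Coleoptera", "Lepidoptera", "Hymenoptera", "other")


class SchemaError(ValueError):
    """A table is missing a required column or violates a field invariant."""


class ReferentialError(ValueError):
    """A table references identifiers that do not resolve."""


def normalise_name(name: str) -> str:
    """Canonical form of a species name used for cross-table matching."""
    return " ".join(str(name).split()).casefold()


@dataclass
class Dataset:
    """A validated bundle of rearing, emergence, trap and trait tables.

    The tables keep their original (whitespace-trimmed) species spellings;
    joins inside the package go through :func:`normalise_name`.
    """

    rearing: pd.DataFrame
    emergences: pd.DataFrame
    traps: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None
    phylogeny: dendropy.Tree | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_columns(self.rearing, REARING_COLUMNS, "rearing")
        _check_columns(self.emergences, EMERGENCE_COLUMNS, "emergence")
        if self.traps is not None:
            _check_columns(self.traps, TRAP_COLUMNS, "traps")
            if (self.traps["trap_area_m2"] <= 0).any():
                raise SchemaError("traps: trap_area_m2 must be positive")
            if (self.traps["seeds_observed"] < 0).any():
                raise SchemaError("traps: seeds_observed must be >= 0")
        r = self.rearing
        for col in ("n_seeds", "n_fruits", "n_seeds_dissected", "n_seeds_predated"):
            if (r[col] < 0).any():
                raise SchemaError(f"rearing: negative values in {col}")
        if (r["n_seeds_predated"] > r["n_seeds_dissected"]).any():
            bad = r.loc[r["n_seeds_predated"] > r["n_seeds_dissected"], "sample_id"]
            raise SchemaError(
                f"rearing: n_seeds_predated > n_seeds_dissected for samples {list(bad)[:5]}"
            )
        if (r["n_seeds_dissected"] > r["n_seeds"]).any():
            bad = r.loc[r["n_seeds_dissected"] > r["n_seeds"], "sample_id"]
            raise SchemaError(
                f"rearing: n_seeds_dissected > n_seeds for samples {list(bad)[:5]}"
            )
        if ((r["n_seeds"] == 0) & (r["n_fruits"] == 0)).any():
            raise SchemaError("rearing: sample with neither seeds nor fruits")
        if (self.emergences["count"] < 1).any():
            raise SchemaError("emergence: count must be >= 1")
        known = set(r["sample_id"])
        orphans = sorted(set(self.emergences["sample_id"]) - known)
        if orphans:
            raise ReferentialError(
                f"emergence rows reference unknown sample_ids: {orphans[:10]}"
            )


@dataclass
class QuantitativeWeb:
    """A bipartite plants x predators web of quantitative link weights.

    ``alpha[i, k]`` is the estimated number of seeds of plant ``i`` killed
    by predator ``k`` per m^2 of seed rain; ``plant_density`` is the seed
    rain (seeds per m^2) of each plant, the quantity the lower bars of the
    classic bipartite web plot are drawn from.
    """

    plants: list[str]
    predators: list[str]
    alpha: np.ndarray  # (n_plants, n_predators), nonnegative
    plant_density: np.ndarray  # (n_plants,), seeds per m^2
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.plant_density = np.asarray(self.plant_density, dtype=float)
        if self.alpha.shape != (len(self.plants), len(self.predators)):
            raise ValueError("alpha shape does not match species lists")
        if not np.isfinite(self.alpha).all() or (self.alpha < 0).any():
            raise ValueError("alpha must be finite and nonnegative")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_predators(self) -> int:
        return len(self.predators)

    def subweb(self, predator_mask: Sequence[bool]) -> "QuantitativeWeb":
        """Restrict to a subset of predator columns, dropping empty plant rows."""
        mask = np.asarray(predator_mask, dtype=bool)
        alpha = self.alpha[:, mask]
        keep_rows = alpha.sum(axis=1) > 0
        return QuantitativeWeb(
            plants=[p for p, k in zip(self.plants, keep_rows) if k],
            predators=[q for q, k in zip(self.predators, mask) if k],
            alpha=alpha[keep_rows],
            plant_density=self.plant_density[keep_rows],
            exclusion_log=list(self.exclusion_log),
        )


def _check_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {missing}")


def _clean_names(series: pd.Series) -> pd.Series:
    return series.astype(str).map(lambda s: " ".join(s.split()))


def read_dataset(
    paths: Mapping[str, str | Path],
    phylogeny_path: str | Path | None = None,
) -> Dataset:
    """Read and validate a full dataset from CSV files.

    Parameters
    ----------
    paths
        Mapping with keys ``rearing`` and ``emergence`` (required) and
        ``traps`` and ``traits`` (optional), each a CSV path.
    phylogeny_path
        Optional Newick file for the plant phylogeny.

    Duplicate emergence rows for the same (sample_id, insect_species,
    life_stage) are summed.  Species-name whitespace is trimmed and
    collapsed; the original case is preserved.
    """
    rearing = pd.read_csv(paths["rearing"])
    emergences = pd.read_csv(paths["emergence"])
    _check_columns(rearing, REARING_COLUMNS, "rearing")
    _check_columns(emergences, EMERGENCE_COLUMNS, "emergence")
    rearing["plant_species"] = _clean_names(rearing["plant_species"])
    rearing["date"] = pd.to_datetime(rearing["date"], format="ISO8601")
    emergences["insect_species"] = _clean_names(emergences["insect_species"])
    emergences["is_seed_predator"] = emergences["is_seed_predator"].astype(bool)

    group_keys = ["sample_id", "insect_species", "life_stage"]
    carry = {
        "insect_order": "first",
        "insect_family": "first",
        "is_seed_predator": "first",
        "count": "sum",
    }
    emergences = (
        emergences.groupby(group_keys, as_index=False, sort=False).agg(carry)
    )[EMERGENCE_COLUMNS]

    traps = traits = None
    if paths.get("traps") is not None:
        traps = pd.read_csv(paths["traps"])
        _check_columns(traps, TRAP_COLUMNS, "traps")
        traps["plant_species"] = _clean_names(traps["plant_species"])
    if paths.get("traits") is not None:
        traits = pd.read_csv(paths["traits"])
        _check_columns(traits, ["plant_species"], "traits")
        traits["plant_species"] = _clean_names(traits["plant_species"])

    tree = read_newick(phylogeny_path) if phylogeny_path is not None else None
    return Dataset(rearing, emergences, traps, traits, tree)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted, branch-length-bearing Newick tree.

    Raises on duplicate or missing tip labels and on negative branch
    lengths; polytomies are permitted.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as err:  # dendropy raises its own hierarchy
        raise ValueError(f"could not parse Newick file {path}: {err}") from err
    tree.is_rooted = True
    return _validate_tree(tree)


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unlabelled tip")
        labels.append(leaf.taxon.label)
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def write_web(web: QuantitativeWeb, path: str | Path) -> None:
    """Write a web as a long-format edge list plus a plant-density sidecar.

    Zero-weight links are omitted (sparse convention).  The sidecar file is
    ``<path stem>_plants.csv``.  Re-reading with :func:`read_web`
    reproduces the web exactly (weights serialised at full precision).
    """
    path = Path(path)
    rows, cols = np.nonzero(web.alpha)
    if rows.size == 0:
        warnings.warn("writing an empty web: no positive links", stacklevel=2)
    edges = pd.DataFrame(
        {
            "plant_species": [web.plants[i] for i in rows],
            "insect_species": [web.predators[k] for k in cols],
            "weight": [repr(float(web.alpha[i, k])) for i, k in zip(rows, cols)],
        }
    )
    edges.to_csv(path, index=False)
    sidecar = path.with_name(path.stem + "_plants.csv")
    pd.DataFrame(
        {
            "plant_species": web.plants,
            "seed_density_per_m2": [repr(float(v)) for v in web.plant_density],
        }
    ).to_csv(sidecar, index=False)


def read_web(path: str | Path) -> QuantitativeWeb:
    """Inverse of :func:`write_web`."""
    path = Path(path)
    edges = pd.read_csv(path, dtype={"weight": float}, float_precision="round_trip")
    sidecar = pd.read_csv(
        path.with_name(path.stem + "_plants.csv"),
        dtype={"seed_density_per_m2": float},
        float_precision="round_trip",
    )
    plants = list(sidecar["plant_species"].astype(str))
    predators = sorted(set(edges["insect_species"].astype(str)))
    # preserve first-appearance ordering of predators in the edge list
    seen: dict[str, int] = {}
    for name in edges["insect_species"].astype(str):
        seen.setdefault(name, len(seen))
    predators = sorted(seen, key=seen.get)
    alpha = np.zeros((len(plants), len(predators)))
    p_index = {p: i for i, p in enumerate(plants)}
    k_index = {k: i for i, k in enumerate(predators)}
    for _, row in edges.iterrows():
        alpha[p_index[str(row["plant_species"])], k_index[str(row["insect_species"])]] = row[
            "weight"
        ]
    return QuantitativeWeb(
        plants=plants,
        predators=predators,
        alpha=alpha,
        plant_density=sidecar["seed_density_per_m2"].to_numpy(),
    )
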