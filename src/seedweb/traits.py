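"""Trait-based prediction of seed-predator attack.

A bootstrap ensemble of randomised decision trees predicts the three
per-plant responses (incidence, richness, predation rate) from a mixed
categorical/continuous trait table with missing values.  Evaluation is
strictly out-of-bag: each species is predicted only by trees whose
bootstrap sample omitted it, so the reported Cohen's kappa and pseudo-R2
measure generalisation, not fit.  Variable importance is the mean change
in OOB accuracy (classification) or OOB squared error (regression) when
one trait's values are permuted.

Missing values are handled by median (numeric) or mode (categorical)
imputation plus a missingness-indicator column per incomplete trait, so
"being unmeasured" remains available as a split variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .assembly import summarise_plants
from .io import Dataset

__all__ = [
    "cohens_kappa",
    "pseudo_r2",
    "ForestResult",
    "fit_trait_forest",
    "run_trait_analysis",
]


def cohens_kappa(
    predicted, observed, baseline: str = "majority"
) -> float:
    """Chance-corrected classification accuracy.

    kappa = (Accuracy - BaselineAccuracy) / (1 - BaselineAccuracy), with
    BaselineAccuracy the majority-class proportion of the observations
    (the no-information rate).  ``baseline="marginal"`` uses the classic
    Cohen definition (expected agreement from the marginal products)
    instead.  Undefined (raises) when the observations are monomorphic.
    """
    pred = np.asarray(predicted)
    obs = np.asarray(observed)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be paired vectors")
    acc = float((pred == obs).mean())
    classes, counts = np.unique(obs, return_counts=True)
    if baseline == "majority":
        base = counts.max() / obs.size
    elif baseline == "marginal":
        base = sum(
            (obs == c).mean() * (pred == c).mean() for c in classes
        )
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    if base >= 1.0:
        raise ValueError("baseline accuracy is 1 (monomorphic observations)")
    return (acc - base) / (1.0 - base)


def pseudo_r2(predicted, observed) -> float:
    """1 - SS_res / SS_tot on (out-of-bag) predictions."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("observed variance must be positive")
    return 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot


@dataclass
class ForestResult:
    response: str
    task: str  # "classification" | "regression"
    kappa: float | None
    pseudo_R2: float | None
    importances: pd.Series
    oob_predictions: pd.Series
    hyperparams: dict = field(default_factory=dict)
    n_species: int = 0


def _encode_traits(traits: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Impute + encode a trait table; returns (matrix, colnames, base traits)."""
    cols = []
    names = []
    for name in traits.columns:
        col = traits[name]
        if col.dtype.kind in "biufc":
            filled = col.astype(float)
            fill_value = filled.median()
        else:
            codes = col.astype("category").cat.codes.astype(float)
            filled = codes.replace(-1, np.nan)
            mode = filled.mode()
            fill_value = mode.iloc[0] if len(mode) else 0.0
        missing = filled.isna()
        cols.append(filled.fillna(fill_value).to_numpy())
        names.append(name)
        if missing.any():
            cols.append(missing.to_numpy(dtype=float))
            names.append(f"{name}__missing")
    return np.column_stack(cols), names, list(traits.columns)


def fit_trait_forest(
    traits: pd.DataFrame,
    response: pd.Series,
    task: str | None = None,
    n_trees: int = 500,
    max_features: str | int | None = None,
    min_samples_leaf: int = 5,
    seed: int | None = None,
) -> ForestResult:
    """Fit the OOB-evaluated randomised-tree ensemble.

    ``traits`` is indexed by species; ``response`` must share that index.
    ``task`` defaults to classification for boolean/binary responses and
    regression otherwise.  Feature-subset sizes default to ceil(sqrt(p))
    for classification and ceil(p/3) for regression.  Deterministic for a
    fixed ``seed``.
    """
    common = traits.index.intersection(response.dropna().index)
    if len(common) == 0:
        raise ValueError("response undefined for all species")
    traits = traits.loc[common]
    y_raw = response.loc[common]
    if task is None:
        task = (
            "classification"
            if y_raw.dtype == bool or set(pd.unique(y_raw.dropna())) <= {0, 1, True, False}
            else "regression"
        )
    X, feat_names, base_traits = _encode_traits(traits)
    n, p = X.shape
    if task == "classification":
        y = y_raw.astype(int).to_numpy()
        mf = max_features or int(np.ceil(np.sqrt(p)))
        TreeCls = DecisionTreeClassifier
    else:
        y = y_raw.astype(float).to_numpy()
        mf = max_features or int(np.ceil(p / 3))
        TreeCls = DecisionTreeRegressor

    rng = np.random.default_rng(seed)
    # accumulators for OOB predictions and per-feature permuted predictions
    if task == "classification":
        votes = np.zeros((n, len(np.unique(y))))
        perm_votes = np.zeros((p, n, len(np.unique(y))))
        y_codes = pd.Categorical(y).codes
        cats = pd.Categorical(y).categories.to_numpy()
    else:
        votes = np.zeros(n)
        perm_votes = np.zeros((p, n))
        counts = np.zeros(n)
        perm_counts = np.zeros((p, n))
    oob_counts = np.zeros(n)

    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size == 0:
            continue
        tree = TreeCls(
            max_features=mf,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        oob_counts[oob] += 1
        if task == "classification":
            # soft voting: accumulate class probabilities, as sklearn forests do
            proba = tree.predict_proba(X[oob])
            for ci, c in enumerate(cats):
                votes[oob, ci] += proba[:, list(tree.classes_).index(c)] if c in tree.classes_ else 0.0
        else:
            votes[oob] += tree.predict(X[oob])
            counts[oob] += 1
        # permutation importance on this tree's OOB block
        for f in range(p):
            Xp = X[oob].copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            if task == "classification":
                proba = tree.predict_proba(Xp)
                for ci, c in enumerate(cats):
                    if c in tree.classes_:
                        perm_votes[f, oob, ci] += proba[:, list(tree.classes_).index(c)]
            else:
                perm_votes[f, oob] += tree.predict(Xp)
                perm_counts[f, oob] += 1

    seen = oob_counts > 0
    if task == "classification":
        oob_pred = cats[votes.argmax(axis=1)]
        kappa = cohens_kappa(oob_pred[seen], y[seen])
        r2 = None
        base_score = float((oob_pred[seen] == y[seen]).mean())
        imp = np.empty(p)
        for f in range(p):
            pred_f = cats[perm_votes[f].argmax(axis=1)]
            imp[f] = base_score - float((pred_f[seen] == y[seen]).mean())
        oob_series = pd.Series(oob_pred, index=common)
    else:
        oob_pred = np.where(seen, votes / np.maximum(counts, 1), np.nan)
        kappa = None
        r2 = pseudo_r2(oob_pred[seen], y[seen])
        base_err = float(((oob_pred[seen] - y[seen]) ** 2).mean())
        imp = np.empty(p)
        for f in range(p):
            pf = np.where(
                perm_counts[f] > 0, perm_votes[f] / np.maximum(perm_counts[f], 1), np.nan
            )
            ok = seen & (perm_counts[f] > 0)
            imp[f] = float(((pf[ok] - y[ok]) ** 2).mean()) - base_err
        oob_series = pd.Series(oob_pred, index=common)

    # fold indicator-column importances into their base trait
    imp_series = pd.Series(imp, index=feat_names)
    folded = pd.Series(0.0, index=base_traits)
    for fname, v in imp_series.items():
        folded[fname.replace("__missing", "")] += v

    return ForestResult(
        response=response.name or "response",
        task=task,
        kappa=kappa,
        pseudo_R2=r2,
        importances=folded.sort_values(ascending=False),
        oob_predictions=oob_series,
        hyperparams={
            "n_trees": n_trees,
            "max_features": mf,
            "min_samples_leaf": min_samples_leaf,
            "seed": seed,
        },
        n_species=len(common),
    )


def run_trait_analysis(
    dataset: Dataset,
    n_trees: int = 500,
    min_species: int = 30,
    seed: int | None = None,
    well_sampled_threshold: int = 200,
) -> dict:
    """The three-response trait analysis (plus the all-species variant).

    The main run uses well-sampled plant species only; the parallel run
    includes every species with total sample size appended as an extra
    predictor, as a check that trait effects are not artefacts of effort.
    Returns ``{"main": {response: ForestResult}, "all_species": {...}}``.
    """
    if dataset.traits is None:
        raise ValueError("dataset has no trait table")
    summaries = summarise_plants(dataset, well_sampled_threshold)
    traits = dataset.traits.set_index("plant_species")

    def one_pass(summary_subset: pd.DataFrame, extra_effort: bool, tag: str) -> dict:
        joined = traits.join(summary_subset, how="inner")
        if len(joined) < min_species:
            raise ValueError(
                f"{tag}: only {len(joined)} species join traits and summaries "
                f"(need >= {min_species})"
            )
        trait_cols = [c for c in traits.columns]
        X = joined[trait_cols].copy()
        if extra_effort:
            X["total_seeds"] = joined["total_seeds"]
        out = {}
        for i, (resp, task) in enumerate(
            [
                ("predator_incidence", "classification"),
                ("predator_richness", "regression"),
                ("predation_rate", "regression"),
            ]
        ):
            y = joined[resp]
            y.name = resp
            out[resp] = fit_trait_forest(
                X, y, task=task, n_trees=n_trees,
                seed=None if seed is None else seed + i,
            )
        return out

    return {
        "main": one_pass(summaries[summaries["well_sampled"]], False, "well-sampled run"),
        "all_species": one_pass(summaries, True, "all-species run"),
    }
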