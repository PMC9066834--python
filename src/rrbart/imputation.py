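"""Iterative random-forest ("missForest"-style) imputation for mixed data.

Missing cells are initialized with the column mean (continuous) or mode
(binary/categorical); columns are then visited in order of missingness
proportion and each incomplete column is regressed on all current columns
with a random forest fitted on its observed rows, its missing cells being
replaced by the forest's predictions.  Sweeps repeat until the change in
the imputed values first increases (the usual stopping criterion: the
normalized squared difference for continuous columns, the fraction of
changed entries for categorical ones), at which point the previous sweep's
values are returned, or until ``max_iter``.

Repeating the whole procedure M times with independent forest seeds gives
the multiple-imputation stack consumed by the Rubin's-rule pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._seeds import child_seed
from .simulation import IncompleteDataset

__all__ = ["CompletedDataset", "ImputationStack", "missforest_impute",
           "multiple_impute"]


@dataclass
class CompletedDataset:
    """One fully imputed copy of an incomplete dataset."""

    X: pd.DataFrame
    y: pd.Series
    truth: list[str] | None = None
    binary_cols: list[str] = field(default_factory=list)
    iterations_used: int = 0
    imputation_errors: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class ImputationStack:
    """M completed copies sharing all observed entries."""

    datasets: list[CompletedDataset]
    seeds: list[int]

    @property
    def M(self) -> int:
        return len(self.datasets)

    @property
    def iterations_used(self) -> list[int]:
        return [d.iterations_used for d in self.datasets]


_DEFAULT_RF = dict(n_estimators=100, n_jobs=1)


def _as_frame(data: IncompleteDataset) -> tuple[pd.DataFrame, list[str]]:
    frame = data.X.copy()
    frame["y"] = data.y.astype(float)
    cat = [c for c in data.binary_cols if c in frame.columns] + ["y"]
    return frame, cat


def missforest_impute(
    data: IncompleteDataset,
    max_iter: int = 10,
    rf_params: dict | None = None,
    seed: int = 0,
    order: str = "asc",
) -> CompletedDataset:
    """Single missForest-style imputation of predictors and outcome.

    ``order`` controls the visiting order within a sweep: ``"asc"`` imputes
    the least-missing column first (the original algorithm), ``"desc"`` the
    most-missing first.
    """
    if order not in ("asc", "desc"):
        raise ValueError("order must be 'asc' or 'desc'")
    rf = dict(_DEFAULT_RF)
    if rf_params:
        rf.update(rf_params)

    frame, cat_cols = _as_frame(data)
    mask = frame.isna()
    miss_cols = [c for c in frame.columns if mask[c].any()]
    if not mask.to_numpy().any():
        return CompletedDataset(
            X=frame.drop(columns="y"), y=frame["y"].rename("y"),
            truth=data.truth, binary_cols=data.binary_cols,
            iterations_used=0, meta=dict(data.meta),
        )
    full = [c for c in frame.columns if mask[c].all()]
    if full:
        raise ValueError(f"columns fully missing, cannot initialize: {full}")

    # initialization: mean / mode
    work = frame.copy()
    for c in miss_cols:
        obs = frame[c].dropna()
        fill = obs.mode().iloc[0] if c in cat_cols else obs.mean()
        work[c] = frame[c].fillna(fill)

    prop = mask[miss_cols].mean()
    visit = list(prop.sort_values(ascending=(order == "asc")).index)

    prev = work.copy()
    prev_crit_cont, prev_crit_cat = np.inf, np.inf
    it = 0
    while it < max_iter:
        it += 1
        for c in visit:
            obs_rows = ~mask[c].to_numpy()
            others = [col for col in work.columns if col != c]
            Xo = work.loc[obs_rows, others].to_numpy(float)
            Xm = work.loc[~obs_rows, others].to_numpy(float)
            yo = work.loc[obs_rows, c].to_numpy(float)
            s = child_seed(seed, "rf", it, c)
            if c in cat_cols:
                # mtry: sqrt(p) for classification (missForest default)
                model = RandomForestClassifier(
                    random_state=s, **{"max_features": "sqrt", **rf})
                model.fit(Xo, yo.astype(int))
                pred = model.predict(Xm).astype(float)
            else:
                # mtry: p/3 for regression (missForest default)
                model = RandomForestRegressor(
                    random_state=s, **{"max_features": 1 / 3, **rf})
                model.fit(Xo, yo)
                pred = model.predict(Xm)
            work.loc[~obs_rows, c] = pred

        # stopping criterion on the masked cells only
        cont = [c for c in miss_cols if c not in cat_cols]
        cats = [c for c in miss_cols if c in cat_cols]
        crit_cont = 0.0
        if cont:
            num = den = 0.0
            for c in cont:
                d = work.loc[mask[c], c] - prev.loc[mask[c], c]
                num += float((d**2).sum())
                den += float((work.loc[mask[c], c] ** 2).sum())
            crit_cont = num / den if den > 0 else 0.0
        crit_cat = 0.0
        if cats:
            changed = total = 0
            for c in cats:
                changed += int((work.loc[mask[c], c] != prev.loc[mask[c], c]).sum())
                total += int(mask[c].sum())
            crit_cat = changed / total if total else 0.0

        rose_cont = (not cont) or crit_cont > prev_crit_cont
        rose_cat = (not cats) or crit_cat > prev_crit_cat
        if rose_cont and rose_cat:
            work = prev          # criterion rose: return previous sweep
            it -= 1
            break
        prev = work.copy()
        prev_crit_cont, prev_crit_cat = crit_cont, crit_cat

    out = CompletedDataset(
        X=work.drop(columns="y"), y=work["y"].rename("y"),
        truth=data.truth, binary_cols=data.binary_cols,
        iterations_used=it, meta=dict(data.meta),
    )
    assert not out.X.isna().to_numpy().any() and not out.y.isna().any()
    return out


def multiple_impute(
    data: IncompleteDataset, M: int = 10, base_seed: int = 0, **kwargs
) -> ImputationStack:
    """Run M independent missForest imputations with derived seeds."""
    if M < 1:
        raise ValueError("M must be >= 1")
    seeds = [child_seed(base_seed, "copy", m) for m in range(M)]
    datasets = [missforest_impute(data, seed=s, **kwargs) for s in seeds]
    return ImputationStack(datasets=datasets, seeds=seeds)
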