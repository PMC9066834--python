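"""Benchmark selection methods for incomplete data.

* ``bi_select`` — bootstrap imputation ("BS-then-MI"): draw B bootstrap
  resamples of the incomplete data, single-impute each with the iterative
  random-forest imputer, run a complete-data selector on each (permutation
  -null BART or recursive-elimination XGBoost), and keep the variables
  voted for in at least ``ceil(pi * B)`` resamples.
* ``xgb_rfe`` — recursive feature elimination with gradient-boosted trees:
  drop zero-importance features, then peel off the least important one at
  a time, and return the subset on the elimination path with the best
  cross-validated AUC.
* ``mia_select`` — missingness incorporated in attributes: missing
  covariate values become routable in the splitting rules (native sparse
  routing for XGBoost, low/high sentinel duplicates for BART) and each
  incomplete covariate gains a missingness-indicator column, so all three
  MIA split rules are realizable.  Missing outcomes are either imputed or
  their rows dropped.
* ``complete_case_select`` — drop every row with any missing entry first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._seeds import child_seed
from .bart import BartParams, permutation_select
from .imputation import missforest_impute
from .simulation import IncompleteDataset

__all__ = ["BootstrapSelectionConfig", "bi_select", "xgb_rfe", "mia_select",
           "complete_case_select", "select_complete"]

_XGB_DEFAULTS = dict(
    n_estimators=100, max_depth=3, learning_rate=0.3, n_jobs=1,
    eval_metric="logloss", verbosity=0, tree_method="hist",
)


@dataclass
class BootstrapSelectionConfig:
    """Settings for bootstrap-imputation selection."""

    B: int = 100
    pi: float = 0.1
    alpha: float = 0.05
    method: str = "bart"                 # "bart" | "xgb"
    n_perm: int = 100                    # permutation count (bart only)
    bart_params: BartParams | None = None
    xgb_params: dict | None = None
    impute_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must be in (0, 1]")
        if self.method not in ("bart", "xgb"):
            raise ValueError("method must be 'bart' or 'xgb'")


def votes_to_selection(votes: dict[str, int], B: int, pi: float) -> list[str]:
    """Variables voted for in at least ceil(pi * B) resamples."""
    need = math.ceil(pi * B)
    return [v for v, c in votes.items() if c >= need]


def select_complete(
    X: pd.DataFrame,
    y: np.ndarray,
    method: str = "bart",
    alpha: float = 0.05,
    n_perm: int = 100,
    bart_params: BartParams | None = None,
    xgb_params: dict | None = None,
    seed: int = 0,
) -> list[str]:
    """Complete-data selection: permutation-null BART or XGBoost RFE."""
    names = list(X.columns)
    if method == "bart":
        sel, _, _ = permutation_select(
            X.to_numpy(float), np.asarray(y, float), params=bart_params,
            n_perm=n_perm, alpha=alpha, seed=seed, names=names)
        return sel
    if method == "xgb":
        return xgb_rfe(X, y, xgb_params=xgb_params, seed=seed)
    raise ValueError("method must be 'bart' or 'xgb'")


def bi_select(
    data: IncompleteDataset, cfg: BootstrapSelectionConfig
) -> tuple[list[str], dict[str, int]]:
    """Bootstrap-imputation selection; returns (selected, vote counts)."""
    n = len(data.y)
    votes = {c: 0 for c in data.X.columns}
    for b in range(cfg.B):
        rng = np.random.default_rng(child_seed(cfg.seed, "boot", b))
        rows = rng.integers(0, n, n)
        boot = IncompleteDataset(
            X=data.X.iloc[rows].reset_index(drop=True),
            y=data.y.iloc[rows].reset_index(drop=True),
            truth=data.truth, binary_cols=data.binary_cols,
        )
        comp = missforest_impute(boot, seed=child_seed(cfg.seed, "imp", b),
                                 **cfg.impute_params)
        sel = select_complete(
            comp.X, comp.y.to_numpy(float), method=cfg.method,
            alpha=cfg.alpha, n_perm=cfg.n_perm, bart_params=cfg.bart_params,
            xgb_params=cfg.xgb_params, seed=child_seed(cfg.seed, "sel", b))
        for v in sel:
            votes[v] += 1
    return votes_to_selection(votes, cfg.B, cfg.pi), votes


def _xgb_importance(X: np.ndarray, y: np.ndarray, cols: list[int],
                    params: dict, seed: int) -> np.ndarray:
    model = xgb.XGBClassifier(random_state=seed, **params)
    model.fit(X[:, cols], y)
    booster = model.get_booster()
    gain = booster.get_score(importance_type="gain")
    imp = np.zeros(len(cols))
    for key, v in gain.items():
        imp[int(key[1:])] = v
    return imp


def _cv_auc_subset(X: np.ndarray, y: np.ndarray, cols: list[int],
                   params: dict, n_folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        model = xgb.XGBClassifier(random_state=seed, **params)
        model.fit(X[tr][:, cols], y[tr])
        p = model.predict_proba(X[te][:, cols])[:, 1]
        if len(np.unique(y[te])) < 2:
            continue
        aucs.append(roc_auc_score(y[te], p))
    return float(np.mean(aucs)) if aucs else 0.5


def xgb_rfe(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    xgb_params: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """Recursive feature elimination by XGBoost gain importance.

    Zero-importance features are removed first, then the least important
    feature is eliminated one at a time with refitting; the subset on the
    path with the highest out-of-fold AUC is returned.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(float)
    else:
        Xa = np.asarray(X, float)
        names = [f"X{k + 1}" for k in range(Xa.shape[1])]
    y = np.asarray(y, float).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("y is constant")
    params = dict(_XGB_DEFAULTS)
    if xgb_params:
        params.update(xgb_params)

    cols = list(range(Xa.shape[1]))
    imp = _xgb_importance(Xa, y, cols, params, child_seed(seed, "init"))
    nz = [c for c, v in zip(cols, imp) if v > 0]
    cols = nz if nz else cols

    best_auc, best_cols = -np.inf, list(cols)
    step = 0
    while True:
        auc = _cv_auc_subset(Xa, y, cols, params, n_folds,
                             child_seed(seed, "cv", step))
        if auc > best_auc:
            best_auc, best_cols = auc, list(cols)
        if len(cols) == 1:
            break
        imp = _xgb_importance(Xa, y, cols, params, child_seed(seed, "imp", step))
        drop = int(np.argmin(imp))
        cols = cols[:drop] + cols[drop + 1:]
        step += 1
    return [names[c] for c in best_cols]


_SENTINEL_SPAN = 3.0


def _mia_encode(X: pd.DataFrame, for_bart: bool) -> tuple[pd.DataFrame, dict[str, str]]:
    """Encode missing covariates so a tree learner can realize the three
    MIA split rules.  Returns (encoded frame, child -> parent map)."""
    out = {}
    parent_of: dict[str, str] = {}
    for c in X.columns:
        col = X[c]
        if not col.isna().any():
            out[c] = col
            parent_of[c] = c
            continue
        ind = col.isna().astype(float)
        if for_bart:
            lo = col.min() - _SENTINEL_SPAN * (col.std() if col.std() > 0 else 1.0)
            hi = col.max() + _SENTINEL_SPAN * (col.std() if col.std() > 0 else 1.0)
            out[f"{c}__mlo"] = col.fillna(lo)   # missing routed left
            out[f"{c}__mhi"] = col.fillna(hi)   # missing routed right
            parent_of[f"{c}__mlo"] = c
            parent_of[f"{c}__mhi"] = c
        else:
            out[c] = col                        # XGBoost routes NaN natively
            parent_of[c] = c
        out[f"{c}__miss"] = ind                 # rule 3: missing vs observed
        parent_of[f"{c}__miss"] = c
    return pd.DataFrame(out), parent_of


def mia_select(
    data: IncompleteDataset,
    method: str = "bart",
    y_mode: str = "impute_y",
    alpha: float = 0.05,
    n_perm: int = 100,
    bart_params: BartParams | None = None,
    xgb_params: dict | None = None,
    impute_params: dict | None = None,
    seed: int = 0,
) -> list[str]:
    """MIA selection with missing outcomes imputed or excluded."""
    if y_mode not in ("impute_y", "exclude_missing_y"):
        raise ValueError("y_mode must be 'impute_y' or 'exclude_missing_y'")
    X, y = data.X, data.y
    if y.isna().any():
        if y_mode == "exclude_missing_y":
            keep = ~y.isna()
            X = X.loc[keep].reset_index(drop=True)
            y = y.loc[keep].reset_index(drop=True)
        else:
            # impute the outcome only; covariates keep their missingness
            comp = missforest_impute(data, seed=child_seed(seed, "y-imp"),
                                     **(impute_params or {}))
            y = comp.y
    enc, parent_of = _mia_encode(X, for_bart=(method == "bart"))
    sel = select_complete(enc, y.to_numpy(float), method=method, alpha=alpha,
                          n_perm=n_perm, bart_params=bart_params,
                          xgb_params=xgb_params, seed=child_seed(seed, "sel"))
    merged: list[str] = []
    for s in sel:
        p = parent_of[s]
        if p not in merged:
            merged.append(p)
    return merged


def complete_case_select(
    data: IncompleteDataset,
    method: str = "bart",
    alpha: float = 0.05,
    n_perm: int = 100,
    bart_params: BartParams | None = None,
    xgb_params: dict | None = None,
    seed: int = 0,
) -> list[str]:
    """Drop all rows with any missing entry, then select on the remainder."""
    keep = ~(data.X.isna().any(axis=1) | data.y.isna())
    if not keep.any():
        raise ValueError("no complete cases available")
    X = data.X.loc[keep].reset_index(drop=True)
    y = data.y.loc[keep].reset_index(drop=True)
    return select_complete(X, y.to_numpy(float), method=method, alpha=alpha,
                           n_perm=n_perm, bart_params=bart_params,
                           xgb_params=xgb_params, seed=seed)
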