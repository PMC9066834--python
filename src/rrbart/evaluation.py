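"""Variable-selection metrics and the replication driver.

Metrics follow the usual conventions for simulation studies of selection
methods: precision (share of selected predictors that are truly useful),
recall (share of useful predictors selected), their harmonic mean F1, and
the type-I error — the average, over noise predictors, of each noise
predictor's selection frequency across replications.

``cv_auc`` implements the split-half predictive assessment: select
variables on one random half of the incomplete data, single-impute the
other half, fit the method's model family (probit BART or XGBoost) on the
imputed half restricted to the selected variables, record its AUC, and
repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._seeds import child_seed
from .bart import BartParams, fit_probit_bart
from .imputation import missforest_impute
from .simulation import (
    AmputationConfig,
    IncompleteDataset,
    ScenarioConfig,
    ampute,
    default_amputation_config,
    generate_complete,
)

__all__ = ["selection_metrics", "type1_error", "cv_auc", "run_scenario",
           "scenario_grid"]


def selection_metrics(
    selected: Iterable[str], truth: Iterable[str], noise: Iterable[str]
) -> tuple[float | None, float, float, dict[str, int]]:
    """(precision, recall, F1, per-noise-predictor selection indicator).

    Precision is undefined (None) when nothing was selected; F1 is 0 by
    convention whenever precision + recall is 0 or precision is undefined.
    """
    sel, tr, nz = set(selected), set(truth), set(noise)
    if tr & nz:
        raise ValueError("truth and noise sets must be disjoint")
    extra = sel - tr - nz
    if extra:
        raise ValueError(f"selected contains unknown predictors: {sorted(extra)}")
    indicator = {z: int(z in sel) for z in sorted(nz)}
    recall = len(sel & tr) / len(tr) if tr else 0.0
    if not sel:
        return None, recall, 0.0, indicator
    precision = len(sel & tr) / len(sel)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1, indicator


def type1_error(indicators: pd.DataFrame | np.ndarray) -> float:
    """Mean over noise predictors of their selection frequency across
    replications.  ``indicators`` is replications x noise-predictors; with
    zero noise predictors the result is NaN (not applicable)."""
    arr = np.asarray(indicators, dtype=float)
    if arr.ndim != 2:
        raise ValueError("indicators must be replications x noise predictors")
    if arr.shape[0] < 1:
        raise ValueError("need at least one replication")
    if arr.shape[1] == 0:
        return float("nan")
    return float(arr.mean(axis=0).mean())


_XGB_FIT = dict(n_estimators=100, max_depth=3, learning_rate=0.3, n_jobs=1,
                eval_metric="logloss", verbosity=0, tree_method="hist")


def _family_auc(
    X_fit: pd.DataFrame, y_fit: np.ndarray,
    X_eval: pd.DataFrame, y_eval: np.ndarray,
    family: str, bart_params: BartParams | None, seed: int,
) -> float:
    """AUC on (X_eval, y_eval) of the family model fitted to (X_fit, y_fit)."""
    if X_fit.shape[1] == 0 or len(np.unique(y_fit)) < 2:
        return 0.5
    if family == "bart":
        bp = bart_params or BartParams(m=50, n_draws=200, burn_in=150)
        fit = fit_probit_bart(X_fit.to_numpy(float), y_fit, bp.with_seed(seed),
                              X_test=X_eval.to_numpy(float))
        pred = fit.predict()
    else:
        import xgboost as xgb

        model = xgb.XGBClassifier(random_state=seed, **_XGB_FIT)
        model.fit(X_fit.to_numpy(float), y_fit.astype(int))
        pred = model.predict_proba(X_eval.to_numpy(float))[:, 1]
    return float(roc_auc_score(y_eval, pred))


def cv_auc(
    data: IncompleteDataset,
    select_fn: Callable[[IncompleteDataset, int], list[str]],
    family: str = "bart",
    n_repeats: int = 100,
    seed: int = 0,
    bart_params: BartParams | None = None,
    impute_params: dict | None = None,
) -> dict:
    """Split-half cross-validated AUC of a selection method.

    Per repeat: split the rows in half; run ``select_fn`` on half A; fit
    the family model (probit BART or XGBoost) on single-imputed half A
    restricted to the selected variables; single-impute half B and score
    the fitted model's AUC on half B against its originally observed
    outcomes, so the AUC is out-of-sample.  Splits leaving either half
    without both outcome classes are redrawn (counted in ``resplits``);
    empty selections score 0.5 (intercept-only model).
    """
    n = len(data.y)
    aucs = []
    resplits = 0
    for rep in range(n_repeats):
        attempt = 0
        while True:
            rng = np.random.default_rng(child_seed(seed, "split", rep, attempt))
            perm = rng.permutation(n)
            a_rows, b_rows = perm[: n // 2], perm[n // 2:]
            ya = data.y.iloc[a_rows]
            yb = data.y.iloc[b_rows]
            if ya.dropna().nunique() == 2 and yb.dropna().nunique() == 2:
                break
            attempt += 1
            resplits += 1
            if attempt > 20:
                raise RuntimeError("could not find a half-split with both classes")
        half_a = IncompleteDataset(
            X=data.X.iloc[a_rows].reset_index(drop=True),
            y=data.y.iloc[a_rows].reset_index(drop=True),
            truth=data.truth, binary_cols=data.binary_cols)
        half_b = IncompleteDataset(
            X=data.X.iloc[b_rows].reset_index(drop=True),
            y=data.y.iloc[b_rows].reset_index(drop=True),
            truth=data.truth, binary_cols=data.binary_cols)
        selected = select_fn(half_a, child_seed(seed, "select", rep))
        if not selected:
            aucs.append(0.5)
            continue
        comp_a = missforest_impute(half_a, seed=child_seed(seed, "impA", rep),
                                   **(impute_params or {}))
        comp_b = missforest_impute(half_b, seed=child_seed(seed, "impB", rep),
                                   **(impute_params or {}))
        eval_rows = ~half_b.y.isna()
        cols = list(selected)
        aucs.append(_family_auc(
            comp_a.X[cols], comp_a.y.to_numpy(float),
            comp_b.X.loc[eval_rows, cols], half_b.y[eval_rows].to_numpy(float),
            family, bart_params, child_seed(seed, "fit", rep)))
    arr = np.asarray(aucs)
    return {
        "mean": float(arr.mean()),
        "q025": float(np.quantile(arr, 0.025)),
        "q975": float(np.quantile(arr, 0.975)),
        "aucs": arr,
        "resplits": resplits,
    }


@dataclass
class ReplicationResult:
    """Aggregated metrics plus per-replication raw records."""

    table: pd.DataFrame
    raw: pd.DataFrame
    indicators: dict[str, pd.DataFrame]
    failures: dict[str, int]


def scenario_grid() -> list[ScenarioConfig]:
    """The full study grid: 4 sample sizes x 3 noise ratios x 2 levels."""
    return [
        ScenarioConfig(n=n, n_noise=q, miss_level=lvl)
        for n in (300, 650, 1000, 5000)
        for q in (10, 20, 40)
        for lvl in ("low", "high")
    ]


def run_scenario(
    scenario: ScenarioConfig,
    methods: Mapping[str, Callable[[IncompleteDataset, int], list[str]]],
    n_reps: int = 25,
    seed: int = 0,
    amputation: AmputationConfig | None = None,
) -> ReplicationResult:
    """Replicate a scenario: generate, amputate, select with each method.

    Each method is a callable ``(incomplete_data, seed) -> selected names``.
    A method failing on a replication is logged and excluded from its
    aggregates.  The table reports per-method mean precision/recall/F1 with
    Monte-Carlo standard errors and the type-I error over noise predictors.
    """
    rows = []
    indicator_rows: dict[str, list[dict]] = {name: [] for name in methods}
    failures = {name: 0 for name in methods}
    for rep in range(n_reps):
        data = generate_complete(ScenarioConfig(
            n=scenario.n, n_noise=scenario.n_noise,
            miss_level=scenario.miss_level,
            seed=child_seed(seed, "gen", rep),
            allow_any_n_noise=True))
        acfg = amputation or default_amputation_config(scenario.miss_level)
        inc = ampute(data, acfg, seed=child_seed(seed, "amp", rep))
        for name, fn in methods.items():
            try:
                sel = fn(inc, child_seed(seed, "method", name, rep))
            except Exception:
                failures[name] += 1
                continue
            prec, rec, f1, ind = selection_metrics(sel, data.truth, data.noise)
            rows.append({"method": name, "rep": rep, "precision": prec,
                         "recall": rec, "f1": f1, "n_selected": len(sel)})
            indicator_rows[name].append(ind)
    raw = pd.DataFrame(rows, columns=["method", "rep", "precision", "recall",
                                      "f1", "n_selected"])
    agg = []
    indicators = {}
    for name in methods:
        sub = raw[raw["method"] == name]
        ind_df = pd.DataFrame(indicator_rows[name])
        indicators[name] = ind_df
        if sub.empty:
            continue
        rec = {
            "method": name,
            "scenario": f"n{scenario.n}_q{scenario.n_noise}_{scenario.miss_level}",
            "n_reps": len(sub),
            "failures": failures[name],
        }
        for mcol in ("precision", "recall", "f1"):
            vals = sub[mcol].dropna().astype(float)
            rec[mcol] = float(vals.mean()) if len(vals) else float("nan")
            rec[f"{mcol}_mcse"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        rec["type1_error"] = (
            type1_error(ind_df) if ind_df.shape[1] > 0 else float("nan")
        )
        agg.append(rec)
    return ReplicationResult(
        table=pd.DataFrame(agg), raw=raw, indicators=indicators, failures=failures
    )
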