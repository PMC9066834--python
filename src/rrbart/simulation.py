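"""Synthetic incomplete-data generator.

Emulates a mixed binary/continuous epidemiological dataset: ten useful
predictors feed a deliberately awkward binary-outcome model (nonlinear,
nonadditive, with interactions), optional pure-noise predictors are
appended, and missingness is then introduced into four covariates and the
outcome by multivariate amputation — per-subject weighted sum scores over
fully observed determinants pushed through a logistic function, so that
missingness depends only on observed values (missing at random).

Useful predictors:

* ``X1, X2 ~ Bernoulli(0.5)`` (binary; strong and moderate effects),
* ``X3, X4, X5 ~ N(0, 1)``,
* ``X6 ~ Gamma(shape=4, rate=6)`` (mean 2/3),
* ``X7..X10`` normal with means linear in ``X3..X6``, inducing pairwise
  correlations among ``X3..X10`` of roughly -0.03 to 0.41.

Outcome::

    logit Pr(y=1) = -2.7 + 1.8 x1 + 0.5 x2 + 1.1 x3 - 0.4 e^{x5}
                    - 0.4 (x6 - 3.5)^2 + 0.3 (x7 - 1)^3 + 1.1 x8
                    - 1.1 x10 + 5 sin(0.1 pi x4 x9) - 0.4 x5 x10^2
                    + 0.4 x3^2 x8

Noise predictors are half ``N(0,1)``, half ``Bernoulli(0.5)`` and named
``Z1..Zq``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

__all__ = [
    "ScenarioConfig",
    "CompleteDataset",
    "AmputationConfig",
    "IncompleteDataset",
    "generate_complete",
    "default_amputation_config",
    "ampute",
    "mar_strength",
    "linear_predictor",
]

USEFUL = [f"X{i}" for i in range(1, 11)]

#: stand-in linear mean structure for X7..X10 (coefficients on X3..X6),
#: calibrated so pairwise correlations among X3..X10 stay within [-0.03, 0.42];
#: intercepts keep the outcome prevalence near 1/3 without touching correlations
_DEP_COEF: dict[str, dict[str, float]] = {
    "X7": {"X3": 0.40, "X4": 0.30},
    "X8": {"X4": 0.30, "X5": 0.40},
    "X9": {"X3": 0.30, "X6": 0.90},
    "X10": {"X4": 0.35, "X5": 0.35},
}
_DEP_INTERCEPT: dict[str, float] = {"X7": 1.0, "X8": 1.5, "X9": 0.0, "X10": -1.0}

#: Gamma(shape=4, rate=6): mean 2/3.  Recorded in dataset metadata.
_GAMMA_SHAPE, _GAMMA_RATE = 4.0, 6.0

_VALID_N_NOISE = (0, 10, 20, 40)


@dataclass
class ScenarioConfig:
    """One simulation scenario: size, noise dimension, missingness level."""

    n: int
    n_noise: int = 40
    miss_level: str = "high"          # "low": 20% in y / 40% overall; "high": 40% / 60%
    seed: int = 0
    allow_any_n_noise: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.n_noise not in _VALID_N_NOISE and not self.allow_any_n_noise:
            raise ValueError(
                f"n_noise must be one of {_VALID_N_NOISE} "
                "(set allow_any_n_noise=True to override)"
            )
        if self.miss_level not in ("low", "high"):
            raise ValueError("miss_level must be 'low' or 'high'")


@dataclass
class CompleteDataset:
    """Fully observed predictors and outcome plus ground truth."""

    X: pd.DataFrame
    y: pd.Series
    truth: list[str]
    binary_cols: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def noise(self) -> list[str]:
        t = set(self.truth)
        return [c for c in self.X.columns if c not in t]


@dataclass
class IncompleteDataset:
    """Predictors/outcome with NaN-encoded missing entries."""

    X: pd.DataFrame
    y: pd.Series
    truth: list[str] | None = None
    binary_cols: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicators (True = missing), incl. column 'y'."""
        m = self.X.isna().copy()
        m["y"] = self.y.isna()
        return m

    @property
    def noise(self) -> list[str]:
        if self.truth is None:
            return []
        t = set(self.truth)
        return [c for c in self.X.columns if c not in t]

    def overall_missingness(self) -> float:
        """Fraction of rows with at least one missing entry (incl. y)."""
        return float(self.mask.any(axis=1).mean())


def linear_predictor(X: pd.DataFrame | Mapping[str, np.ndarray]) -> np.ndarray:
    """Logit of the outcome probability for the simulated model."""
    x = {k: np.asarray(X[k], dtype=float) for k in USEFUL}
    return (
        -2.7
        + 1.8 * x["X1"]
        + 0.5 * x["X2"]
        + 1.1 * x["X3"]
        - 0.4 * np.exp(x["X5"])
        - 0.4 * (x["X6"] - 3.5) ** 2
        + 0.3 * (x["X7"] - 1.0) ** 3
        + 1.1 * x["X8"]
        - 1.1 * x["X10"]
        + 5.0 * np.sin(0.1 * np.pi * x["X4"] * x["X9"])
        - 0.4 * x["X5"] * x["X10"] ** 2
        + 0.4 * x["X3"] ** 2 * x["X8"]
    )


def generate_complete(config: ScenarioConfig) -> CompleteDataset:
    """Draw a complete dataset for one scenario."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    cols: dict[str, np.ndarray] = {}
    cols["X1"] = rng.binomial(1, 0.5, n).astype(float)
    cols["X2"] = rng.binomial(1, 0.5, n).astype(float)
    for c in ("X3", "X4", "X5"):
        cols[c] = rng.standard_normal(n)
    cols["X6"] = rng.gamma(_GAMMA_SHAPE, 1.0 / _GAMMA_RATE, n)
    for c in ("X7", "X8", "X9", "X10"):
        mean = np.full(n, _DEP_INTERCEPT[c])
        for dep, a in _DEP_COEF[c].items():
            mean = mean + a * cols[dep]
        cols[c] = mean + rng.standard_normal(n)

    binary_cols = ["X1", "X2"]
    q = config.n_noise
    n_bin = q // 2
    for j in range(1, q + 1):
        name = f"Z{j}"
        if j <= q - n_bin:
            cols[name] = rng.standard_normal(n)
        else:
            cols[name] = rng.binomial(1, 0.5, n).astype(float)
            binary_cols.append(name)

    X = pd.DataFrame(cols)
    p = expit(linear_predictor(X))
    y = pd.Series(rng.binomial(1, p).astype(float), name="y")
    return CompleteDataset(
        X=X, y=y, truth=list(USEFUL), binary_cols=binary_cols,
        meta={
            "config": config,
            "gamma_parameterization": {"shape": _GAMMA_SHAPE, "rate": _GAMMA_RATE},
            "dependence_coefficients": _DEP_COEF,
        },
    )


# ---------------------------------------------------------------------------
# amputation


@dataclass
class AmputationConfig:
    """Multivariate-amputation plan.

    ``patterns`` maps each amputation target (a column name or ``"y"``) to a
    weight vector over its determinant columns; determinants must be fully
    observed, so missingness depends only on observed data (MAR).
    ``target_props`` gives the intended per-target missingness proportion;
    a covariate entry of ``None`` means "solve a common proportion so the
    expected overall missingness hits ``overall_target``".  ``steepness``
    is the slope of the logistic applied to the standardized weighted sum
    score; larger values give a stronger (higher-AUC) MAR mechanism.
    """

    patterns: dict[str, dict[str, float]]
    target_props: dict[str, float | None]
    overall_target: float | None = None
    steepness: float = 2.0

    def __post_init__(self) -> None:
        for tgt, w in self.patterns.items():
            if tgt in w:
                raise ValueError(f"pattern target {tgt!r} cannot be its own determinant")
            for v in w.values():
                if not np.isfinite(v):
                    raise ValueError("amputation weights must be finite")
        for tgt, p in self.target_props.items():
            if p is not None and not 0.0 <= p < 1.0:
                raise ValueError(f"target proportion for {tgt!r} must be in [0, 1)")


def default_amputation_config(
    miss_level: str = "high", overall_target: float | None = None
) -> AmputationConfig:
    """The study's default plan: amputate X7..X10 and y.

    Each target's missingness depends on two always-observed determinants
    from X1..X6 with unit weights.  High level: 40% missing y, 60% of rows
    incomplete; low level: 20% / 40%.
    """
    if miss_level not in ("low", "high"):
        raise ValueError("miss_level must be 'low' or 'high'")
    y_prop = 0.4 if miss_level == "high" else 0.2
    if overall_target is None:
        overall_target = 0.6 if miss_level == "high" else 0.4
    patterns = {
        "X7": {"X1": 1.0, "X3": 1.0},
        "X8": {"X2": 1.0, "X4": 1.0},
        "X9": {"X1": 1.0, "X5": 1.0},
        "X10": {"X2": 1.0, "X6": 1.0},
        "y": {"X3": 1.0, "X4": 1.0},
    }
    props: dict[str, float | None] = {"X7": None, "X8": None, "X9": None,
                                      "X10": None, "y": y_prop}
    return AmputationConfig(patterns=patterns, target_props=props,
                            overall_target=overall_target)


def _standardized_score(frame: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    s = np.zeros(len(frame))
    for col, w in weights.items():
        x = frame[col].to_numpy(float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        s = s + w * z
    sd = s.std()
    return s / sd if sd > 0 else s


def _solve_shift(score: np.ndarray, steepness: float, target: float) -> float:
    """Find intercept a with mean(expit(a + b*score)) == target."""
    if target <= 0.0:
        return -np.inf

    def f(a: float) -> float:
        return float(np.mean(expit(a + steepness * score))) - target

    return brentq(f, -60.0, 60.0, xtol=1e-10)


def _pattern_probs(
    data: CompleteDataset, acfg: AmputationConfig
) -> dict[str, np.ndarray]:
    """Per-target missingness probabilities, with covariate proportions
    solved (if requested) so expected overall missingness matches."""
    frame = data.X.copy()
    frame["y"] = data.y
    all_cols = set(frame.columns)
    scores: dict[str, np.ndarray] = {}
    for tgt, w in acfg.patterns.items():
        missing_cols = set(w) - all_cols
        if missing_cols:
            raise ValueError(f"unknown determinant columns: {sorted(missing_cols)}")
        det_targets = set(w) & set(acfg.patterns)
        if det_targets:
            raise ValueError(
                f"determinants of {tgt!r} include amputation targets "
                f"{sorted(det_targets)}; MAR requires fully observed determinants"
            )
        scores[tgt] = _standardized_score(frame, w)

    fixed = {t: p for t, p in acfg.target_props.items() if p is not None}
    free = [t for t, p in acfg.target_props.items() if p is None]

    def probs_for(q: float) -> dict[str, np.ndarray]:
        out = {}
        for tgt in acfg.patterns:
            p = fixed.get(tgt, q)
            if p == 0.0:
                out[tgt] = np.zeros(len(frame))
            else:
                a = _solve_shift(scores[tgt], acfg.steepness, p)
                out[tgt] = expit(a + acfg.steepness * scores[tgt])
        return out

    if free:
        if acfg.overall_target is None:
            raise ValueError("free covariate proportions need overall_target")

        def expected_overall(q: float) -> float:
            pr = probs_for(q)
            keep = np.ones(len(frame))
            for tgt in acfg.patterns:
                keep = keep * (1.0 - pr[tgt])
            return float(np.mean(1.0 - keep)) - acfg.overall_target

        lo, hi = 1e-6, 0.98
        if expected_overall(lo) > 0 or expected_overall(hi) < 0:
            raise ValueError("overall_target infeasible for this pattern set")
        q = brentq(expected_overall, lo, hi, xtol=1e-8)
        return probs_for(q)
    return probs_for(0.0)


def ampute(
    data: CompleteDataset, acfg: AmputationConfig | None = None, seed: int = 0
) -> IncompleteDataset:
    """Introduce MAR missingness into a complete dataset.

    For each pattern the per-subject weighted sum score over standardized
    determinants is pushed through a logistic function whose intercept is
    solved numerically so that the expected missingness proportion equals
    the target; cells then go missing by independent Bernoulli draws.
    """
    if acfg is None:
        acfg = default_amputation_config(data.meta.get("config").miss_level
                                         if data.meta.get("config") else "high")
    probs = _pattern_probs(data, acfg)
    rng = np.random.default_rng(seed)
    X = data.X.copy()
    y = data.y.copy().astype(float)
    realized = {}
    for tgt in acfg.patterns:
        miss = rng.random(len(X)) < probs[tgt]
        realized[tgt] = float(miss.mean())
        if tgt == "y":
            y[miss] = np.nan
        else:
            X.loc[miss, tgt] = np.nan
    out = IncompleteDataset(
        X=X, y=y, truth=data.truth, binary_cols=data.binary_cols,
        meta={**data.meta, "amputation": acfg, "seed": seed,
              "realized_missingness": realized},
    )
    out.meta["realized_overall"] = out.overall_missingness()
    return out


def mar_strength(
    data: IncompleteDataset, acfg: AmputationConfig | None = None
) -> dict[str, float]:
    """Per-variable AUC of a logistic model for the missingness indicator.

    Regresses each amputated variable's missingness indicator on its
    determinants (from ``acfg``, falling back to the config stored in the
    dataset's metadata, else on all fully observed columns) and reports the
    in-sample AUC.  Fully observed variables map to ``nan`` (not applicable).
    """
    if acfg is None:
        acfg = data.meta.get("amputation")
    frame = data.X.copy()
    frame["y"] = data.y
    mask = frame.isna()
    if not mask.to_numpy().any():
        raise ValueError("dataset has no missing values")
    fully_observed = [c for c in frame.columns if not mask[c].any()]
    out: dict[str, float] = {}
    for col in frame.columns:
        ind = mask[col].to_numpy()
        if not ind.any():
            continue
        if ind.all():
            out[col] = float("nan")
            continue
        if acfg is not None and col in acfg.patterns:
            dets = list(acfg.patterns[col])
        else:
            dets = fully_observed
        Xd = frame[dets].to_numpy(float)
        clf = LogisticRegression(max_iter=1000)
        clf.fit(Xd, ind.astype(int))
        out[col] = float(roc_auc_score(ind.astype(int),
                                       clf.predict_proba(Xd)[:, 1]))
    return out
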