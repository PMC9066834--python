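"""Rubin's-rule pooling of BART variable-inclusion proportions (RR-BART).

The selection algorithm pools, across ``M`` imputed datasets and ``P``
posterior draws each, the distribution of per-predictor variable-inclusion
proportions (VIPs).  Writing ``VIP_kmp`` for predictor ``k``, imputation
``m`` and draw ``p``:

1. average the VIPs over ``(m, p)`` to get ``mean_vip[k]``;
2. locate the predictor ``k'`` with the smallest average; if that minimum
   exceeds ``1/(2K)`` no selection is warranted (every candidate looks
   useful) and all predictors are retained;
3. otherwise form distance scores ``delta_kmp = VIP_kmp - mean_vip[k']``
   and combine them with Rubin's rules into a pooled mean, a
   within-imputation variance, a between-imputation variance and a
   t-reference confidence interval per predictor;
4. select the predictors whose interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VIPDistribution",
    "PooledScore",
    "SelectionResult",
    "average_vip",
    "min_vip_gate",
    "distance_scores",
    "rubins_pool",
    "select",
    "rr_bart",
    "median_baseline_select",
    "pooled_posterior_select",
]


#: endpoints this close to zero count as touching zero in the CI rule
_ZERO_ATOL = 1e-12


@dataclass
class VIPDistribution:
    """K x M x P array of per-draw variable-inclusion proportions.

    ``vip[k, m, p]`` is predictor ``k``'s share of the splitting rules in
    posterior draw ``p`` of the model fitted to imputed dataset ``m``; for
    every ``(m, p)`` the entries over ``k`` form a probability vector.
    """

    vip: np.ndarray
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.vip = np.asarray(self.vip, dtype=float)
        if self.vip.ndim != 3:
            raise ValueError("vip must be a K x M x P array")
        if np.any(self.vip < 0) or np.any(self.vip > 1):
            raise ValueError("VIP entries must lie in [0, 1]")
        sums = self.vip.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("VIPs must sum to 1 over predictors for every (m, p)")
        if self.names is not None and len(self.names) != self.K:
            raise ValueError("names length must equal K")

    @property
    def K(self) -> int:
        return self.vip.shape[0]

    @property
    def M(self) -> int:
        return self.vip.shape[1]

    @property
    def P(self) -> int:
        return self.vip.shape[2]


@dataclass
class PooledScore:
    """Per-predictor pooled distance-score statistics (arrays of length K)."""

    qbar: np.ndarray          # pooled mean distance
    within: np.ndarray        # within-imputation variance W
    between: np.ndarray       # between-imputation variance B
    total: np.ndarray         # total variance T = W + (1 + 1/M) B
    df: np.ndarray            # t-reference degrees of freedom (inf when B = 0)
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    alpha: float
    M: int
    n: int

    def to_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        idx = list(names) if names is not None else list(range(len(self.qbar)))
        return pd.DataFrame(
            {
                "qbar": self.qbar,
                "within_var": self.within,
                "between_var": self.between,
                "total_var": self.total,
                "df": self.df,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            },
            index=idx,
        )


@dataclass
class SelectionResult:
    """Outcome of a variable-selection run.

    ``selected`` holds predictor names; ``gate_triggered`` records whether
    the minimum-VIP stopping rule fired (in which case every predictor is
    retained and no pooled scores are produced).
    """

    selected: list[str]
    gate_triggered: bool
    names: list[str]
    scores: pd.DataFrame | None = None
    mean_vip: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    @property
    def selected_mask(self) -> np.ndarray:
        sel = set(self.selected)
        return np.array([c in sel for c in self.names])


def average_vip(v: VIPDistribution) -> np.ndarray:
    """Average VIP over all M imputations and P draws, per predictor."""
    return v.vip.mean(axis=(1, 2))


def min_vip_gate(means: np.ndarray) -> tuple[bool, int]:
    """Minimum-VIP stopping rule.

    Returns ``(gate_triggered, k_min)`` where ``k_min`` is the argmin of the
    average VIPs (lowest index on ties) and the gate fires iff that minimum
    is strictly greater than ``1/(2K)`` — i.e. even the least-used predictor
    claims more than half its equal share of splitting rules, so no
    predictor looks dispensable.
    """
    means = np.asarray(means, dtype=float)
    K = means.shape[0]
    k_min = int(np.argmin(means))
    return bool(means[k_min] > 1.0 / (2 * K)), k_min


def distance_scores(v: VIPDistribution, min_mean: float) -> np.ndarray:
    """Elementwise distances ``delta_kmp = VIP_kmp - min_mean``."""
    return v.vip - float(min_mean)


def rubins_pool(
    delta: np.ndarray,
    n: int,
    alpha: float = 0.05,
    within_var: Literal["paper", "mcse"] = "paper",
    tail: Literal["two", "one"] = "two",
) -> PooledScore:
    """Pool distance scores across imputations with Rubin's rules.

    Parameters
    ----------
    delta : K x M x P array of distance scores.
    n : analysis sample size. In the default ``within_var="paper"`` mode the
        within-imputation variance divides each imputation's across-draw
        variance by ``n``; ``"mcse"`` divides by ``P`` instead (the Monte
        Carlo standard error of the per-imputation mean).
    alpha : interval level ``1 - alpha``.
    tail : ``"two"`` uses the ``1 - alpha/2`` t-quantile (standard two-sided
        Rubin interval); ``"one"`` uses ``1 - alpha``.

    Notes
    -----
    Per predictor ``k``: ``qbar = mean(delta)``;
    ``W = mean_m( var_p(delta[k,m,:]) / n )``;
    ``B = sum_m (dbar_km - dbar_k)^2 / (M-1)``;
    ``T = W + (1 + 1/M) B``;
    ``df = (M-1) / ((B + B/M) / T)^2`` (infinite when ``B = 0``, in which
    case the normal quantile is used).
    """
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 3:
        raise ValueError("delta must be K x M x P")
    K, M, P = delta.shape
    if M < 2:
        raise ValueError("Rubin's rules need M >= 2 imputations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    dbar_km = delta.mean(axis=2)                       # K x M
    qbar = dbar_km.mean(axis=1)                        # K
    var_p = delta.var(axis=2, ddof=1)                  # K x M, across-draw variance
    divisor = float(n) if within_var == "paper" else float(P)
    W = (var_p / divisor).mean(axis=1)
    B = ((dbar_km - qbar[:, None]) ** 2).sum(axis=1) / (M - 1)
    T = W + (1.0 + 1.0 / M) * B

    df = np.full(K, np.inf)
    q = 1.0 - alpha / 2.0 if tail == "two" else 1.0 - alpha
    tcrit = np.empty(K)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (B + B / M) / T
    for k in range(K):
        if T[k] == 0.0:
            # fully degenerate draws: zero-width interval at qbar
            df[k] = np.inf
            tcrit[k] = 0.0 if B[k] == 0.0 else stats.norm.ppf(q)
            continue
        if B[k] == 0.0:
            df[k] = np.inf
            tcrit[k] = stats.norm.ppf(q)
        else:
            df[k] = (M - 1) / rel[k] ** 2
            tcrit[k] = stats.t.ppf(q, df[k])

    half = tcrit * np.sqrt(T)
    # zero-variance predictors get a degenerate [qbar, qbar] interval
    half = np.where(T == 0.0, 0.0, half)
    return PooledScore(
        qbar=qbar, within=W, between=B, total=T, df=df,
        ci_lo=qbar - half, ci_hi=qbar + half,
        alpha=alpha, M=M, n=n,
    )


def select(
    pooled: PooledScore,
    names: Sequence[str] | None = None,
    mean_vip: np.ndarray | None = None,
) -> SelectionResult:
    """Select predictors whose pooled distance-score CI excludes zero.

    An endpoint exactly at zero counts as containing zero (not selected);
    endpoints within 1e-12 of zero are snapped to zero so floating-point
    residue from the distance subtraction cannot flip the boundary rule.
    """
    K = len(pooled.qbar)
    nm = list(names) if names is not None else [f"X{k + 1}" for k in range(K)]
    keep = (pooled.ci_lo > _ZERO_ATOL) | (pooled.ci_hi < -_ZERO_ATOL)
    mv = pd.Series(mean_vip, index=nm) if mean_vip is not None else None
    return SelectionResult(
        selected=[nm[k] for k in range(K) if keep[k]],
        gate_triggered=False,
        names=nm,
        scores=pooled.to_frame(nm),
        mean_vip=mv,
        meta={"alpha": pooled.alpha, "M": pooled.M, "n": pooled.n},
    )


def select_from_vip(
    v: VIPDistribution,
    n: int,
    alpha: float = 0.05,
    names: Sequence[str] | None = None,
    within_var: Literal["paper", "mcse"] = "paper",
) -> SelectionResult:
    """Run gate -> distances -> Rubin pooling -> CI selection on a VIP array."""
    nm = list(names) if names is not None else (
        list(v.names) if v.names is not None else [f"X{k + 1}" for k in range(v.K)]
    )
    means = average_vip(v)
    gate, k_min = min_vip_gate(means)
    mv = pd.Series(means, index=nm)
    if gate:
        return SelectionResult(
            selected=list(nm), gate_triggered=True, names=nm,
            scores=None, mean_vip=mv,
            meta={"alpha": alpha, "M": v.M, "n": n, "k_min": nm[k_min]},
        )
    delta = distance_scores(v, means[k_min])
    pooled = rubins_pool(delta, n=n, alpha=alpha, within_var=within_var)
    res = select(pooled, names=nm, mean_vip=means)
    res.meta["k_min"] = nm[k_min]
    return res


def median_baseline_select(v: VIPDistribution, names: Sequence[str] | None = None) -> list[str]:
    """Baseline rule: keep predictors whose mean VIP strictly exceeds the
    median of the mean VIPs."""
    means = average_vip(v)
    nm = list(names) if names is not None else [f"X{k + 1}" for k in range(v.K)]
    med = float(np.median(means))
    return [nm[k] for k in range(v.K) if means[k] > med]


def pooled_posterior_select(
    v: VIPDistribution,
    n: int = 0,
    alpha: float = 0.05,
    names: Sequence[str] | None = None,
) -> list[str]:
    """Alternative pooling: concatenate all M*P distance draws per predictor
    and select when the empirical (alpha/2, 1-alpha/2) interval excludes 0.

    ``n`` is accepted for interface parity and unused.
    """
    nm = list(names) if names is not None else [f"X{k + 1}" for k in range(v.K)]
    means = average_vip(v)
    gate, k_min = min_vip_gate(means)
    if gate:
        return list(nm)
    delta = distance_scores(v, means[k_min]).reshape(v.K, -1)
    lo = np.quantile(delta, alpha / 2.0, axis=1)
    hi = np.quantile(delta, 1.0 - alpha / 2.0, axis=1)
    keep = (lo > _ZERO_ATOL) | (hi < -_ZERO_ATOL)
    return [nm[k] for k in range(v.K) if keep[k]]


def rr_bart(
    data,
    M: int = 10,
    alpha: float = 0.05,
    bart_params=None,
    seed: int = 0,
    within_var: Literal["paper", "mcse"] = "paper",
    return_vip: bool = False,
    impute_params: dict | None = None,
):
    """End-to-end RR-BART on an incomplete dataset.

    Imputes ``data`` M times with the iterative random-forest imputer, fits
    a probit BART to each completed copy, stacks the per-draw VIPs into a
    K x M x P array and applies the gate / Rubin-pooling selection.
    """
    from .bart import BartParams, fit_probit_bart
    from .imputation import multiple_impute
    from ._seeds import child_seed

    if bart_params is None:
        # selection-calibrated ensemble: small m sharpens the VIP contrast
        # between useful and useless predictors (see docs/methods.md)
        bart_params = BartParams(m=20, n_draws=500, burn_in=300)
    stack = multiple_impute(data, M=M, base_seed=child_seed(seed, "impute"),
                            **(impute_params or {}))
    names = list(stack.datasets[0].X.columns)
    vips = []
    for m, comp in enumerate(stack.datasets):
        params = bart_params.with_seed(child_seed(seed, "bart", m))
        fit = fit_probit_bart(comp.X.to_numpy(float), comp.y.to_numpy(float), params)
        vips.append(fit.vip_draws)                     # P x K
    vip = np.stack(vips, axis=0).transpose(2, 0, 1)    # K x M x P
    v = VIPDistribution(vip, names=names)
    res = select_from_vip(v, n=len(stack.datasets[0].y), alpha=alpha,
                          names=names, within_var=within_var)
    res.meta.update({"M": M, "seed": seed, "P": v.P})
    if return_vip:
        return res, v
    return res
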