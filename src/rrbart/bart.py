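"""Probit BART: public fitting interface and the permutation-null selector.

The model for a binary outcome is

    Pr(Y = 1 | x) = Phi( f(x) ),      f = sum of m regression trees,

with the regularizing Chipman-style tree prior and conjugate leaf values;
see :mod:`rrbart._bart_mcmc` for the sampler.  A fit exposes the per-draw
variable-inclusion proportions (VIPs): for each retained posterior draw,
each predictor's share of all splitting rules in the ensemble.  The VIPs
of one draw always sum to one.

``permutation_select`` is the complete-data selection primitive used by
the bootstrap-imputation comparator: the outcome vector is permuted
``n_perm`` times, BART is refitted to each permuted outcome, and a
predictor is kept when its observed posterior-mean VIP exceeds the
``1 - alpha`` empirical quantile of its own null distribution (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._bart_mcmc import run_probit_bart
from ._seeds import child_seed

__all__ = ["BartParams", "BartFit", "fit_probit_bart", "vip_samples",
           "permutation_select"]

_EMPTY = np.zeros((0, 1))


@dataclass(frozen=True)
class BartParams:
    """Sampler settings.

    ``m``: trees in the ensemble (50 for inference-style fits; 20 is the
    usual recommendation when the VIPs are used for variable selection).
    ``n_draws``: retained posterior draws P; ``burn_in``: discarded draws.
    ``base``/``power``: depth-penalty prior, P(split at depth d) =
    base/(1+d)^power.  ``k``: leaf-value prior scale, sd = 3/(k sqrt(m)).
    """

    m: int = 50
    n_draws: int = 1000
    burn_in: int = 250
    base: float = 0.95
    power: float = 2.0
    k: float = 2.0
    p_grow: float = 0.28
    p_prune: float = 0.28
    max_depth: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n_draws < 1 or self.burn_in < 0:
            raise ValueError("m and n_draws must be >= 1, burn_in >= 0")
        if not (0 < self.base < 1) or self.power <= 0 or self.k <= 0:
            raise ValueError("tree-prior hyperparameters must be positive (base in (0,1))")

    def with_seed(self, seed: int) -> "BartParams":
        return replace(self, seed=seed)

    @property
    def s2mu(self) -> float:
        return (3.0 / (self.k * np.sqrt(self.m))) ** 2


@dataclass
class BartFit:
    """Posterior summaries of one probit BART chain."""

    vip_draws: np.ndarray          # P x K
    uniform_flag: np.ndarray       # per-draw: 1 if ensemble had zero splits
    train_prob: np.ndarray         # posterior mean Phi(f(x)) on training rows
    test_prob: np.ndarray | None
    params: BartParams
    names: list[str] | None = None

    @property
    def mean_vip(self) -> np.ndarray:
        return self.vip_draws.mean(axis=0)

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean event probabilities for the test rows passed to
        :func:`fit_probit_bart` (or the training rows when none were)."""
        if X is not None:
            raise NotImplementedError(
                "pass X_test to fit_probit_bart; draws are not retained for re-prediction"
            )
        return self.test_prob if self.test_prob is not None else self.train_prob


def _validate(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be n x K with len(y) == n")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values; impute or encode first")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("y is constant; both classes must be present")
    return X, y


def fit_probit_bart(
    X: np.ndarray,
    y: np.ndarray,
    params: BartParams | None = None,
    X_test: np.ndarray | None = None,
    names: Sequence[str] | None = None,
) -> BartFit:
    """Fit the probit sum-of-trees model by MCMC."""
    if params is None:
        params = BartParams()
    X, y = _validate(X, y)
    Xt = _EMPTY if X_test is None else np.ascontiguousarray(np.asarray(X_test, float))
    if Xt.size and Xt.shape[1] != X.shape[1]:
        raise ValueError("X_test has wrong number of columns")
    if Xt.size == 0:
        Xt = np.zeros((0, X.shape[1]))
    vip, flag, ptrain, ptest = run_probit_bart(
        X, y, Xt, params.m, params.n_draws, params.burn_in,
        params.p_grow, params.p_prune, params.base, params.power,
        params.s2mu, params.max_depth, int(params.seed) % (2**31 - 1),
    )
    return BartFit(
        vip_draws=vip, uniform_flag=flag, train_prob=ptrain,
        test_prob=ptest if X_test is not None else None,
        params=params, names=list(names) if names is not None else None,
    )


def vip_samples(fit: BartFit) -> np.ndarray:
    """P x K matrix of per-draw variable-inclusion proportions."""
    return fit.vip_draws


def permutation_select(
    X: np.ndarray,
    y: np.ndarray,
    params: BartParams | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> tuple[list, np.ndarray, np.ndarray]:
    """Permutation-null VIP selection on complete data.

    Returns ``(selected, observed_mean_vip, null_matrix)`` where
    ``null_matrix`` is ``n_perm x K``.  Selection requires the observed
    mean VIP to exceed the ``1 - alpha`` quantile of that predictor's own
    null distribution strictly.
    """
    if params is None:
        params = BartParams(m=20, n_draws=300, burn_in=150)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, y = _validate(X, y)
    K = X.shape[1]
    nm = list(names) if names is not None else list(range(K))
    obs = fit_probit_bart(X, y, params.with_seed(child_seed(seed, "obs"))).mean_vip
    null = np.empty((n_perm, K))
    for b in range(n_perm):
        rng = np.random.default_rng(child_seed(seed, "perm", b))
        yp = rng.permutation(y)
        if yp.min() == yp.max():        # pathological tiny-n case
            yp[0] = 1.0 - yp[0]
        null[b] = fit_probit_bart(
            X, yp, params.with_seed(child_seed(seed, "permfit", b))
        ).mean_vip
    thr = np.quantile(null, 1.0 - alpha, axis=0)
    selected = [nm[k] for k in range(K) if obs[k] > thr[k]]
    return selected, obs, null
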