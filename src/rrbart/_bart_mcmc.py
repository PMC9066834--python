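"""Numba kernel for the probit sum-of-trees sampler.

Implements a lean Chipman-style BART for binary outcomes:

* Albert–Chib data augmentation — latent ``z_i ~ N(f(x_i), 1)`` truncated
  to the side given by ``y_i``; the probit link is exact, no logit
  approximation.
* ``f`` is an offset plus a sum of ``m`` regression trees updated one at a
  time by Bayesian backfitting; each tree update proposes a GROW, PRUNE or
  CHANGE move accepted by Metropolis–Hastings with the conjugate leaf
  values integrated out.
* The regularizing tree prior: a node at depth ``d`` splits with
  probability ``alpha / (1 + d)^beta``; leaf values are a priori
  ``N(0, s2mu)`` with ``s2mu = (3 / (k sqrt(m)))^2`` so the sum of trees
  stays in a plausible probit range.
* Split rules are drawn uniformly: variable uniform over the ``K``
  candidates, cutpoint uniform over the distinct observed values in the
  node (excluding the maximum so both children are nonempty).  The rule
  prior matches the proposal, so rule-selection terms cancel in the MH
  ratio; the CHANGE move is accepted on the likelihood ratio alone.

Trees are stored in flat preallocated arrays (slot 0 is the root; a free
stack recycles slots), and each observation's leaf assignment per tree is
maintained incrementally, so a move only touches the observations in the
affected node.

Per retained draw the kernel records each predictor's share of all
splitting rules in the ensemble (the VIP vector).  Draws in which the
ensemble holds no splitting rule at all get the uniform vector ``1/K`` and
are flagged.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_MAXN = 512          # tree-slot capacity; depth prior keeps trees far smaller


@njit(cache=True)
def _ndtri(p):
    """Inverse standard-normal CDF (Acklam's rational approximation with a
    Halley refinement in the bulk; ~1e-9 relative accuracy in deep tails)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a0, a1, a2 = -3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02
    a3, a4, a5 = 1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00
    b0, b1, b2 = -5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02
    b3, b4 = 6.680131188771972e+01, -1.328068155288572e+01
    c0, c1, c2 = -7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00
    c3, c4, c5 = -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00
    d0, d1, d2, d3 = 7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00, 3.754408661907416e+00
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / \
            ((((d0 * q + d1) * q + d2) * q + d3) * q + 1.0)
    elif p <= 1.0 - plow:
        q = p - 0.5
        r = q * q
        x = (((((a0 * r + a1) * r + a2) * r + a3) * r + a4) * r + a5) * q / \
            (((((b0 * r + b1) * r + b2) * r + b3) * r + b4) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / \
            ((((d0 * q + d1) * q + d2) * q + d3) * q + 1.0)
    if -6.0 < x < 6.0:  # Halley step (erf-based CDF is accurate in the bulk)
        e = 0.5 * (1.0 + math.erf(x / _SQRT2)) - p
        u = e * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
        x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def _rtnorm_lower(a, u):
    """Draw t ~ N(0,1) conditional on t > a via the inverse CDF, using the
    upper-tail parameterization for a >= 0 to avoid cancellation."""
    if a >= 0.0:
        tail = 0.5 * math.erfc(a / _SQRT2)      # P(t > a), computed stably
        p = tail * (1.0 - u)
        if p < 1e-300:
            p = 1e-300
        t = -_ndtri(p)
    else:
        lo = 0.5 * math.erfc(-a / _SQRT2)       # P(t <= a) <= 0.5
        t = _ndtri(lo + u * (1.0 - lo))
    if t < a:                                    # numerical guard
        t = a
    return t


@njit(cache=True)
def _leaf_loglik(n, s, s2mu):
    """Log marginal likelihood of a leaf's residuals with the N(0, s2mu)
    leaf-value prior integrated out (terms common to split/merge omitted)."""
    d = 1.0 + n * s2mu
    return -0.5 * math.log(d) + 0.5 * s2mu * s * s / d


@njit(cache=True)
def _distinct_cutpoint(vals, nv, r):
    """r-th distinct value (ascending) of vals[:nv] excluding the maximum;
    returns (count_of_candidates, chosen_value). vals is sorted in place."""
    v = np.sort(vals[:nv])
    d = 0
    for i in range(nv - 1):          # a distinct value that is not the max
        if i == 0 or v[i] != v[i - 1]:
            if v[i] != v[nv - 1]:
                d += 1
    if d == 0:
        return 0, 0.0
    k = r % d
    c = v[0]
    j = -1
    for i in range(nv - 1):
        if i == 0 or v[i] != v[i - 1]:
            if v[i] != v[nv - 1]:
                j += 1
                if j == k:
                    c = v[i]
                    break
    return d, c


@njit(cache=True)
def run_probit_bart(X, y, Xtest, m, n_draws, burn, p_grow, p_prune,
                    alpha_split, beta_split, s2mu, max_depth, seed):
    """Run one MCMC chain; see module docstring.

    Returns (vip_draws[P,K], uniform_flag[P], ptrain[n], ptest[nt]) where
    ptrain/ptest are posterior means of Phi(f(x)) over retained draws.
    """
    np.random.seed(seed)
    n, K = X.shape
    nt = Xtest.shape[0]

    # tree arrays --------------------------------------------------------
    used = np.zeros((m, _MAXN), np.bool_)
    var = np.full((m, _MAXN), -1, np.int32)       # -1 = leaf
    split = np.zeros((m, _MAXN))
    left = np.full((m, _MAXN), -1, np.int32)
    right = np.full((m, _MAXN), -1, np.int32)
    parent = np.full((m, _MAXN), -1, np.int32)
    depth = np.zeros((m, _MAXN), np.int32)
    value = np.zeros((m, _MAXN))
    freestack = np.zeros((m, _MAXN), np.int32)
    freecount = np.zeros(m, np.int32)
    for j in range(m):
        used[j, 0] = True
        for s in range(_MAXN - 1, 0, -1):
            freestack[j, freecount[j]] = s
            freecount[j] += 1

    A = np.zeros((m, n), np.int32)                # leaf assignment, train
    At = np.zeros((m, nt), np.int32)              # leaf assignment, test

    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    if ybar < 1.0 / (n + 2.0):
        ybar = 1.0 / (n + 2.0)
    if ybar > 1.0 - 1.0 / (n + 2.0):
        ybar = 1.0 - 1.0 / (n + 2.0)
    offset = _ndtri(ybar)

    f = np.full(n, offset)
    ftest = np.full(nt, offset)
    z = np.zeros(n)
    g = np.zeros(n)
    resid = np.zeros(n)

    idx = np.zeros(n, np.int32)
    vals = np.zeros(n)
    leaves_buf = np.zeros(_MAXN, np.int32)
    nodes_buf = np.zeros(_MAXN, np.int32)
    leaf_n = np.zeros(_MAXN)
    leaf_s = np.zeros(_MAXN)

    vip_draws = np.zeros((n_draws, K))
    uniform_flag = np.zeros(n_draws, np.uint8)
    ptrain = np.zeros(n)
    ptest = np.zeros(nt)

    for it in range(burn + n_draws):
        # -- latent probit draw -----------------------------------------
        for i in range(n):
            u = np.random.random()
            if u >= 1.0:
                u = 0.9999999999999999
            if y[i] > 0.5:
                z[i] = f[i] + _rtnorm_lower(-f[i], u)
            else:
                z[i] = f[i] - _rtnorm_lower(f[i], u)

        # -- backfit each tree ------------------------------------------
        for j in range(m):
            for i in range(n):
                g[i] = value[j, A[j, i]]
                resid[i] = z[i] - f[i] + g[i]

            mu = np.random.random()
            root_only = var[j, 0] == -1 and used[j, 0]
            # count leaves and singly-internal nodes
            n_leaves = 0
            w2 = 0
            for s in range(_MAXN):
                if used[j, s]:
                    if var[j, s] == -1:
                        leaves_buf[n_leaves] = s
                        n_leaves += 1
                    elif var[j, left[j, s]] == -1 and var[j, right[j, s]] == -1:
                        nodes_buf[w2] = s
                        w2 += 1

            if mu < p_grow:
                # ---------------- GROW --------------------------------
                L = leaves_buf[int(np.random.random() * n_leaves) % n_leaves]
                if depth[j, L] < max_depth and freecount[j] >= 2:
                    cnt = 0
                    for i in range(n):
                        if A[j, i] == L:
                            idx[cnt] = i
                            cnt += 1
                    if cnt >= 2:
                        v = int(np.random.random() * K) % K
                        for t in range(cnt):
                            vals[t] = X[idx[t], v]
                        r = int(np.random.random() * n)
                        d, c = _distinct_cutpoint(vals, cnt, r)
                        if d > 0:
                            nlft = 0
                            slft = 0.0
                            stot = 0.0
                            for t in range(cnt):
                                ri = resid[idx[t]]
                                stot += ri
                                if X[idx[t], v] <= c:
                                    nlft += 1
                                    slft += ri
                            nrt = cnt - nlft
                            srt = stot - slft
                            ll = (_leaf_loglik(nlft, slft, s2mu)
                                  + _leaf_loglik(nrt, srt, s2mu)
                                  - _leaf_loglik(cnt, stot, s2mu))
                            d0 = depth[j, L]
                            ps0 = alpha_split / (1.0 + d0) ** beta_split
                            ps1 = alpha_split / (2.0 + d0) ** beta_split
                            lprior = (math.log(ps0) + 2.0 * math.log(1.0 - ps1)
                                      - math.log(1.0 - ps0))
                            w2_after = w2 + 1
                            pL = parent[j, L]
                            if pL >= 0 and var[j, left[j, pL]] == -1 and var[j, right[j, pL]] == -1:
                                w2_after -= 1
                            lprop = (math.log(p_prune) - math.log(p_grow)
                                     + math.log(n_leaves) - math.log(w2_after))
                            if math.log(np.random.random() + 1e-300) < ll + lprior + lprop:
                                cl = freestack[j, freecount[j] - 1]
                                cr = freestack[j, freecount[j] - 2]
                                freecount[j] -= 2
                                var[j, L] = v
                                split[j, L] = c
                                left[j, L] = cl
                                right[j, L] = cr
                                for ch in (cl, cr):
                                    used[j, ch] = True
                                    var[j, ch] = -1
                                    parent[j, ch] = L
                                    depth[j, ch] = d0 + 1
                                    value[j, ch] = value[j, L]
                                for t in range(cnt):
                                    i = idx[t]
                                    A[j, i] = cl if X[i, v] <= c else cr
                                for i in range(nt):
                                    if At[j, i] == L:
                                        At[j, i] = cl if Xtest[i, v] <= c else cr
            elif mu < p_grow + p_prune:
                # ---------------- PRUNE -------------------------------
                if w2 > 0 and not root_only:
                    N = nodes_buf[int(np.random.random() * w2) % w2]
                    cl = left[j, N]
                    cr = right[j, N]
                    nl_ = 0
                    sl_ = 0.0
                    nr_ = 0
                    sr_ = 0.0
                    for i in range(n):
                        a = A[j, i]
                        if a == cl:
                            nl_ += 1
                            sl_ += resid[i]
                        elif a == cr:
                            nr_ += 1
                            sr_ += resid[i]
                    ll = (_leaf_loglik(nl_ + nr_, sl_ + sr_, s2mu)
                          - _leaf_loglik(nl_, sl_, s2mu)
                          - _leaf_loglik(nr_, sr_, s2mu))
                    d0 = depth[j, N]
                    ps0 = alpha_split / (1.0 + d0) ** beta_split
                    ps1 = alpha_split / (2.0 + d0) ** beta_split
                    lprior = -(math.log(ps0) + 2.0 * math.log(1.0 - ps1)
                               - math.log(1.0 - ps0))
                    lprop = (math.log(p_grow) - math.log(p_prune)
                             + math.log(w2) - math.log(n_leaves - 1))
                    if math.log(np.random.random() + 1e-300) < ll + lprior + lprop:
                        for ch in (cl, cr):
                            used[j, ch] = False
                            var[j, ch] = -1
                            parent[j, ch] = -1
                            freestack[j, freecount[j]] = ch
                            freecount[j] += 1
                        var[j, N] = -1
                        for i in range(n):
                            if A[j, i] == cl or A[j, i] == cr:
                                A[j, i] = N
                        for i in range(nt):
                            if At[j, i] == cl or At[j, i] == cr:
                                At[j, i] = N
            else:
                # ---------------- CHANGE ------------------------------
                if w2 > 0 and not root_only:
                    N = nodes_buf[int(np.random.random() * w2) % w2]
                    cl = left[j, N]
                    cr = right[j, N]
                    cnt = 0
                    for i in range(n):
                        if A[j, i] == cl or A[j, i] == cr:
                            idx[cnt] = i
                            cnt += 1
                    if cnt >= 2:
                        v = int(np.random.random() * K) % K
                        for t in range(cnt):
                            vals[t] = X[idx[t], v]
                        r = int(np.random.random() * n)
                        d, c = _distinct_cutpoint(vals, cnt, r)
                        if d > 0:
                            nlo = 0
                            slo = 0.0
                            stot = 0.0
                            nln = 0
                            sln = 0.0
                            for t in range(cnt):
                                i = idx[t]
                                ri = resid[i]
                                stot += ri
                                if A[j, i] == cl:
                                    nlo += 1
                                    slo += ri
                                if X[i, v] <= c:
                                    nln += 1
                                    sln += ri
                            ll = (_leaf_loglik(nln, sln, s2mu)
                                  + _leaf_loglik(cnt - nln, stot - sln, s2mu)
                                  - _leaf_loglik(nlo, slo, s2mu)
                                  - _leaf_loglik(cnt - nlo, stot - slo, s2mu))
                            if math.log(np.random.random() + 1e-300) < ll:
                                var[j, N] = v
                                split[j, N] = c
                                for t in range(cnt):
                                    i = idx[t]
                                    A[j, i] = cl if X[i, v] <= c else cr
                                for i in range(nt):
                                    if At[j, i] == cl or At[j, i] == cr:
                                        At[j, i] = cl if Xtest[i, v] <= c else cr

            # -- conjugate leaf-value draws for tree j ------------------
            n_leaves = 0
            for s in range(_MAXN):
                if used[j, s] and var[j, s] == -1:
                    leaves_buf[n_leaves] = s
                    n_leaves += 1
                    leaf_n[s] = 0.0
                    leaf_s[s] = 0.0
            for i in range(n):
                a = A[j, i]
                leaf_n[a] += 1.0
                leaf_s[a] += resid[i]
            for t in range(n_leaves):
                s = leaves_buf[t]
                post_var = 1.0 / (leaf_n[s] + 1.0 / s2mu)
                post_mean = post_var * leaf_s[s]
                value[j, s] = post_mean + math.sqrt(post_var) * np.random.standard_normal()
            for i in range(n):
                f[i] += value[j, A[j, i]] - g[i]

        # test-set fit rebuilt once per iteration from the leaf assignments
        for i in range(nt):
            s = offset
            for j in range(m):
                s += value[j, At[j, i]]
            ftest[i] = s

        # -- record draw -------------------------------------------------
        if it >= burn:
            p = it - burn
            tot = 0
            for j in range(m):
                for s in range(_MAXN):
                    if used[j, s] and var[j, s] >= 0:
                        vip_draws[p, var[j, s]] += 1.0
                        tot += 1
            if tot == 0:
                for k in range(K):
                    vip_draws[p, k] = 1.0 / K
                uniform_flag[p] = 1
            else:
                for k in range(K):
                    vip_draws[p, k] /= tot
            for i in range(n):
                ptrain[i] += 0.5 * (1.0 + math.erf(f[i] / _SQRT2))
            for i in range(nt):
                ptest[i] += 0.5 * (1.0 + math.erf(ftest[i] / _SQRT2))

    for i in range(n):
        ptrain[i] /= n_draws
    for i in range(nt):
        ptest[i] /= n_draws
    return vip_draws, uniform_flag, ptrain, ptest
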