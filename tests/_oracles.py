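"""Independent brute-force oracles used by the test suite.

Everything here works from explicit dense matrices (explicit V inverses,
explicit determinants, generic numerical optimizers, numerical
quadrature) and never calls the rotated/whitened code paths it is used
to check.
"""

import numpy as np
from scipy import integrate, optimize, stats


def assemble_V(h2_list, covs, n):
    V = (1.0 - sum(h2_list)) * np.eye(n)
    for h, C in zip(h2_list, covs):
        V = V + h * C
    return V


def gls_direct(y, Xt, V):
    """Explicit-inverse GLS: theta, RSS, (Xt' V^-1 Xt)^-1."""
    Vi = np.linalg.inv(V)
    G = Xt.T @ Vi @ Xt
    Gi = np.linalg.inv(G)
    theta = Gi @ (Xt.T @ Vi @ y)
    r = y - Xt @ theta
    RSS = float(r @ Vi @ r)
    return theta, RSS, Gi


def ml_profile_direct(y, Xt, V):
    n = len(y)
    _, RSS, _ = gls_direct(y, Xt, V)
    _, ldV = np.linalg.slogdet(V)
    s2 = RSS / n
    return -(n / 2) * np.log(2 * np.pi * s2) - RSS / (2 * s2) - 0.5 * ldV


def reml_profile_direct(y, Xt, V):
    n, k = Xt.shape
    _, RSS, _ = gls_direct(y, Xt, V)
    _, ldV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    _, ldG = np.linalg.slogdet(Xt.T @ Vi @ Xt)
    _, ldGr = np.linalg.slogdet(Xt.T @ Xt)
    d = n - k
    s2 = RSS / d
    return (
        -(d / 2) * np.log(2 * np.pi * s2)
        - RSS / (2 * s2)
        - 0.5 * ldV
        + 0.5 * (ldGr - ldG)
    )


def continuous_reml_max(y, Xt, covs, kind="REML"):
    """Continuous optimum of the profile likelihood over the simplex.

    Returns (h2_opt array, max value).  Uses a generic optimizer from
    several starts; L = 1 uses bounded scalar search.
    """
    n = len(y)
    fun = reml_profile_direct if kind == "REML" else ml_profile_direct

    def value(h2_list):
        if any(h < 0 for h in h2_list) or sum(h2_list) >= 1 - 1e-9:
            return -np.inf
        return fun(y, Xt, assemble_V(h2_list, covs, n))

    L = len(covs)
    if L == 1:
        res = optimize.minimize_scalar(
            lambda h: -value([h]), bounds=(0.0, 1 - 1e-6), method="bounded",
            options={"xatol": 1e-10},
        )
        return np.array([res.x]), -res.fun
    best = (None, -np.inf)
    for start in _simplex_starts(L):
        res = optimize.minimize(
            lambda h: -value(list(h)), start, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
        )
        if -res.fun > best[1]:
            best = (np.clip(res.x, 0, 1), -res.fun)
    return best


def _simplex_starts(L):
    starts = [np.full(L, 0.8 / L), np.full(L, 0.3 / L), np.full(L, 0.05)]
    for i in range(L):
        e = np.full(L, 0.05)
        e[i] = 0.6
        starts.append(e)
    return starts


def exact_lmm_wald_p(y, W, block, covs, contrast_col=0):
    """Exact-LMM oracle: continuous REML fit per marker, then the Wald test."""
    Xt = np.hstack([W, block])
    h2, _ = continuous_reml_max(y, Xt, covs, kind="REML")
    n, k = Xt.shape
    V = assemble_V(list(h2), covs, n)
    theta, RSS, Gi = gls_direct(y, Xt, V)
    d = n - k
    s2 = RSS / d
    j = W.shape[1] + contrast_col
    F = theta[j] ** 2 / (s2 * Gi[j, j])
    return float(stats.f.sf(F, 1, d)), float(F)


def nig_quadrature(y, x, V, psi, a0, b0, theta_lim=30.0, s2_lo=1e-6, s2_hi=60.0):
    """2-D quadrature of the NIG marginal for a single-coefficient design.

    Limits must generously cover the posterior bulk; a sharp posterior
    inside very wide limits defeats the adaptive subdivision.
    """

    def integrand(th, s2):
        lik = stats.multivariate_normal.logpdf(y, mean=x * th, cov=s2 * V)
        pth = stats.norm.logpdf(th, 0.0, np.sqrt(psi * s2))
        ps2 = stats.invgamma.logpdf(s2, a0, scale=b0)
        return np.exp(lik + pth + ps2)

    val, _ = integrate.dblquad(
        integrand, s2_lo, s2_hi, lambda s: -theta_lim, lambda s: theta_lim,
        epsabs=1e-14, epsrel=1e-11,
    )
    return np.log(val)


def enumerate_grid(L, m):
    """Exhaustive lattice enumeration: step-1/m vectors, sum < 1, origin included."""
    import itertools

    count = 0
    vertices = []
    for combo in itertools.product(range(m), repeat=L):
        if sum(combo) <= m - 1:
            count += 1
            vertices.append(tuple(c / m for c in combo))
    return count, vertices
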