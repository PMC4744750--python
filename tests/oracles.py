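"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: exact posteriors by
2-D quadrature over variance components (fixed effects integrated
analytically), a brute-force shortest-interval search, and a brute-force
record filter.
"""

from __future__ import annotations

import numpy as np


def brute_force_hpd(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """O(n^2)-style exhaustive shortest interval containing ``prob`` mass."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    k = int(np.ceil(prob * n))
    best = (np.inf, x[0], x[-1])
    for i in range(n - k + 1):
        w = x[i + k - 1] - x[i]
        if w < best[0]:
            best = (w, x[i], x[i + k - 1])
    return best[1], best[2]


def brute_force_sufficiency(records, min_positive_visits, min_span_days):
    """Row-by-row scan mirroring the filter definition."""
    keep = []
    for _, r in records.iterrows():
        span = r["last_positive_day"] - r["first_positive_day"]
        keep.append(r["n_positive_visits"] >= min_positive_visits and span >= min_span_days)
    return records[np.asarray(keep, dtype=bool)]


def _log_prior(sigma2: np.ndarray, nu: float, V: float) -> np.ndarray:
    # inverse-Wishart IW(nu*V, nu) density of sigma2, expressed on the
    # log-sigma2 grid (Jacobian included)
    return -(nu / 2.0) * np.log(sigma2) - nu * V / (2.0 * sigma2)


def exact_balanced_oneway_posterior(y: np.ndarray, groups: np.ndarray,
                                    nu: float = 0.002, V: float = 1.0,
                                    grid: int = 400):
    """Exact posterior of (between, within) variances for a balanced
    one-way random-intercept model, flat prior on the mean.

    Returns posterior means of the two variance components by quadrature on
    a log-spaced grid.  Marginal likelihood in terms of the sufficient
    statistics SSW (within) and SSB (between):

        -2 logL = m(r-1) log sw2 + SSW/sw2 + (m-1) log tau + SSB/tau
                  + log(N/tau),  tau = sw2 + r*sb2.
    """
    labels, codes = np.unique(groups, return_inverse=True)
    m = labels.size
    r = y.size // m
    assert m * r == y.size, "design must be balanced"
    gmeans = np.array([y[codes == g].mean() for g in range(m)])
    ssw = float(((y - gmeans[codes]) ** 2).sum())
    ssb = float(r * ((gmeans - y.mean()) ** 2).sum())
    N = y.size

    lg = np.linspace(np.log(1e-5), np.log(1e3), grid)
    sb2 = np.exp(lg)[:, None]
    sw2 = np.exp(lg)[None, :]
    tau = sw2 + r * sb2
    ll = -0.5 * (m * (r - 1) * np.log(sw2) + ssw / sw2
                 + (m - 1) * np.log(tau) + ssb / tau + np.log(N / tau))
    lp = ll + _log_prior(sb2, nu, V) + _log_prior(sw2, nu, V)
    p = np.exp(lp - lp.max())
    p /= p.sum()
    return {
        "between_mean": float((sb2 * p).sum()),
        "within_mean": float((sw2 * p).sum()),
    }


def exact_meta_posterior(y: np.ndarray, A: np.ndarray, m0: float,
                         nu: float = 0.002, V: float = 1.0, grid: int = 350):
    """Exact posterior of (sigma_a2, sigma_e2, H2) for the intercept-only
    phylogenetic meta-model with constant measurement-error variance ``m0``.

    V(sa2, se2) = sa2*A + (se2 + m0)*I diagonalizes in A's eigenbasis, so
    the marginal likelihood (intercept integrated under a flat prior) is a
    cheap function on a 2-D grid.  Returns posterior means and the H2 HPD.
    """
    n = y.size
    w, Q = np.linalg.eigh(A)
    yt = Q.T @ y
    ot = Q.T @ np.ones(n)
    lg = np.linspace(np.log(1e-4), np.log(200), grid)
    se_grid = np.exp(lg)
    lp = np.empty((grid, grid))
    for i, sa in enumerate(np.exp(lg)):
        d = sa * w[None, :] + se_grid[:, None] + m0
        wv = 1.0 / d
        otVo = (wv * ot[None, :] ** 2).sum(1)
        quad = (wv * yt[None, :] ** 2).sum(1) - (wv * yt[None, :] * ot[None, :]).sum(1) ** 2 / otVo
        ll = -0.5 * (np.log(d).sum(1) + np.log(otVo) + quad)
        lp[i] = ll + _log_prior(np.exp(lg[i]), nu, V) + _log_prior(se_grid, nu, V)
    p = np.exp(lp - lp.max())
    p /= p.sum()
    SA = np.exp(lg)[:, None]
    SE = np.exp(lg)[None, :]
    h2 = SA / (SA + SE)

    hv = h2.ravel()
    pv = p.ravel()
    order = np.argsort(hv)
    hv, pv = hv[order], pv[order]
    cdf = np.cumsum(pv)
    best = (np.inf, 0.0, 1.0)
    for q0 in np.arange(0.0, 0.0501, 0.001):
        i0 = int(np.searchsorted(cdf, q0))
        i1 = min(int(np.searchsorted(cdf, q0 + 0.95)), hv.size - 1)
        if hv[i1] - hv[i0] < best[0]:
            best = (hv[i1] - hv[i0], hv[i0], hv[i1])
    return {
        "sigma_a2_mean": float((SA * p).sum()),
        "sigma_e2_mean": float((SE * p).sum()),
        "h2_mean": float((h2 * p).sum()),
        "h2_hpd": (best[1], best[2]),
    }
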