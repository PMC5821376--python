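"""Independent brute-force oracles, deliberately separate from the
implementation paths they check."""

import itertools

import numpy as np
from scipy import stats


def ols_normal_equations(exog: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS coefficients by solving X'X b = X'y directly."""
    xtx = exog.T @ exog
    return np.linalg.solve(xtx, exog.T @ y)


def ros_roots_grid(b2, b3, v22, v33, v23, t_crit, lo, hi, step=1e-4):
    """Boundaries of the significant region by scanning x and t-testing the
    group difference pointwise; returns crossings of |t| = t_crit."""
    xs = np.arange(lo, hi + step, step)
    diff = b2 + b3 * xs
    se = np.sqrt(v22 + xs**2 * v33 + 2 * xs * v23)
    sig = np.abs(diff) > t_crit * se
    changes = np.nonzero(np.diff(sig.astype(int)))[0]
    return [0.5 * (xs[i] + xs[i + 1]) for i in changes]


def poi_numeric(b2, b3, xc, lo, hi, n_points=100_000):
    """Right-of-crossover share of the between-line area by trapezoid
    integration of |b2 + b3 x|."""
    gap = lambda xs: np.abs(b2 + b3 * xs)
    if xc <= lo:
        return 1.0
    if xc >= hi:
        return 0.0
    xs_r = np.linspace(xc, hi, n_points)
    xs_l = np.linspace(lo, xc, n_points)
    right = np.trapezoid(gap(xs_r), xs_r)
    left = np.trapezoid(gap(xs_l), xs_l)
    return right / (right + left)


def two_snp_loglik(freqs, genotype_rows):
    """Multinomial log-likelihood of two-SNP dosage rows given haplotype
    frequencies ordered (ab, aB, Ab, AB) = dosage patterns (00, 01, 10, 11)."""
    hap_bits = [(0, 0), (0, 1), (1, 0), (1, 1)]
    total = 0.0
    for g in genotype_rows:
        p = 0.0
        for i, hi_ in enumerate(hap_bits):
            for j, hj in enumerate(hap_bits):
                if (hi_[0] + hj[0], hi_[1] + hj[1]) == tuple(g):
                    p += freqs[i] * freqs[j]
        if p <= 0:
            return -np.inf
        total += np.log(p)
    return total


def two_snp_mle_grid(genotype_rows, coarse=0.02):
    """Exhaustive maximization of the two-SNP haplotype likelihood on the
    3-simplex: coarse grid scan followed by Nelder-Mead refinement in a
    softmax parameterization."""
    best = (-np.inf, None)
    steps = int(round(1 / coarse))
    for i in range(steps + 1):
        for j in range(steps + 1 - i):
            for k in range(steps + 1 - i - j):
                f = np.array([i, j, k, steps - i - j - k], float) / steps
                ll = two_snp_loglik(f, genotype_rows)
                if ll > best[0]:
                    best = (ll, f)
    from scipy.optimize import minimize

    def neg(theta):
        w = np.exp(theta - theta.max())
        return -two_snp_loglik(w / w.sum(), genotype_rows)

    f0 = np.clip(best[1], 1e-6, None)
    res = minimize(neg, np.log(f0), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    w = np.exp(res.x - res.x.max())
    f = w / w.sum()
    return f if two_snp_loglik(f, genotype_rows) >= best[0] else best[1]


def cronbach_alpha_from_cov(cov: np.ndarray) -> float:
    """Alpha from an item covariance matrix: (k/(k-1)) (1 - tr(C)/sum(C))."""
    k = cov.shape[0]
    return k / (k - 1) * (1 - np.trace(cov) / cov.sum())
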