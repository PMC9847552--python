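"""Genetic correlation from summary statistics via a block-eigen full likelihood.

The model is a full-likelihood extension of LD-score regression on a
block-diagonal LD reference.  Under standardized genotypes with per-SNP causal
variance h_t^2 / m and no sample overlap between the two GWAS, the z-scores of
a block with correlation matrix R satisfy

    cov(z_t)      = (n_t h_t^2 / m) R^2 + R
    cov(z_1, z_2) = (sqrt(n_1 n_2) r_g sqrt(h_1^2 h_2^2) / m) R^2 .

Rotating each block into the eigenbasis of R (R = U diag(lambda) U^T,
w_t = U^T z_t) decouples the components: (w1_i, w2_i) is bivariate normal with
covariance

    [[a_1 lambda_i^2 + lambda_i,  c lambda_i^2],
     [c lambda_i^2,               a_2 lambda_i^2 + lambda_i]]

where a_t = n_t h_t^2 / m and c = sqrt(n_1 n_2) r_g sqrt(h_1^2 h_2^2) / m.
The cross term carries no +lambda noise contribution because the samples do
not overlap; intercepts are fixed at one (a free-intercept variant is a
config option).  (h_1^2, h_2^2, r_g) is estimated by bounded quasi-Newton
minimization of the negative log-likelihood, initialized from LD-score
moment regressions; the standard error of r_g comes from the numerically
differentiated observed information, and the p-value is a two-sided Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .sumstats import HarmonizedPair, LDReference

__all__ = [
    "BlockEigen",
    "RgEstimate",
    "transform_to_eigenbasis",
    "negative_log_likelihood",
    "ldsc_moment_estimate",
    "fit_genetic_correlation",
]

_EIG_FLOOR = 1e-8


@dataclass
class BlockEigen:
    """Eigencomponents of all LD blocks, flattened.

    lam[i] are eigenvalues of the per-block LD matrices (clipped from below);
    w1/w2 are the orthogonally transformed z-scores.  The rotation preserves
    per-block sums of squares.
    """

    lam: np.ndarray
    w1: np.ndarray
    w2: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.lam)


def transform_to_eigenbasis(pair: HarmonizedPair, ld: LDReference) -> BlockEigen:
    """Eigendecompose each block (restricted to unmasked pair SNPs) and rotate z.

    Masked (extended-LD region) variants are excluded.  Raises if any variant
    of the pair is absent from the LD reference.
    """
    tab = pair.table
    unmasked = tab.loc[tab["masked_region"] == "none"]
    missing = [s for s in unmasked["snp_id"] if s not in ld]
    if missing:
        raise ValueError(
            f"{len(missing)} variants missing from LD reference, e.g. {missing[:5]}"
        )
    z1 = dict(zip(unmasked["snp_id"], unmasked["z1"]))
    z2 = dict(zip(unmasked["snp_id"], unmasked["z2"]))
    lams, w1s, w2s = [], [], []
    for bi, (_, snps, _) in enumerate(ld.blocks):
        keep = np.array([s in z1 for s in snps], dtype=bool)
        if not keep.any():
            continue
        kept = [s for s in snps if s in z1]
        R = ld.submatrix(bi, keep)
        lam, U = np.linalg.eigh(R)
        lam = np.clip(lam, _EIG_FLOOR, None)
        zb1 = np.array([z1[s] for s in kept])
        zb2 = np.array([z2[s] for s in kept])
        lams.append(lam)
        w1s.append(U.T @ zb1)
        w2s.append(U.T @ zb2)
    if not lams:
        raise ValueError("no unmasked variants shared with the LD reference")
    return BlockEigen(np.concatenate(lams), np.concatenate(w1s), np.concatenate(w2s))


def negative_log_likelihood(
    eig: BlockEigen,
    theta: tuple[float, float, float],
    n1: float,
    n2: float,
    m: int,
) -> float:
    """Negative log-likelihood of (h1sq, h2sq, rg) over all eigencomponents.

    Returns +inf (optimizer-safe) when any per-component 2x2 covariance is not
    positive definite.
    """
    h1sq, h2sq, rg = theta
    lam = eig.lam
    a1 = n1 * h1sq / m
    a2 = n2 * h2sq / m
    c = np.sqrt(n1 * n2 * max(h1sq, 0.0) * max(h2sq, 0.0)) * rg / m
    lam2 = lam * lam
    v1 = a1 * lam2 + lam
    v2 = a2 * lam2 + lam
    cv = c * lam2
    det = v1 * v2 - cv * cv
    if np.any(v1 <= 0) or np.any(det <= 0):
        return np.inf
    quad = (v2 * eig.w1**2 - 2.0 * cv * eig.w1 * eig.w2 + v1 * eig.w2**2) / det
    nll = 0.5 * np.sum(np.log(det) + quad) + eig.n_components * np.log(2.0 * np.pi)
    return float(nll)


def ldsc_moment_estimate(
    pair: HarmonizedPair, ld: LDReference
) -> tuple[float, float, float]:
    """LD-score regression moment estimates of (h1sq, h2sq, rg), as initializer.

    Per trait, OLS of z^2 on the LD score l gives slope n h^2 / m; the
    cross-trait regression of z1 z2 on l gives sqrt(n1 n2) rho_g / m.  With a
    degenerate (constant) LD score the slope is undefined and an
    intercept-free mean-based fallback is used: h^2 = (mean(z^2) - 1) m /
    (n mean(l)).
    """
    tab = pair.table
    unmasked = tab.loc[tab["masked_region"] == "none"]
    unmasked = unmasked.loc[[s in ld for s in unmasked["snp_id"]]]
    if len(unmasked) < 50:
        raise ValueError("need at least 50 unmasked variants for the moment estimate")
    ell = np.array([ld.ld_score[s] for s in unmasked["snp_id"]])
    z1 = unmasked["z1"].to_numpy()
    z2 = unmasked["z2"].to_numpy()
    m = len(unmasked)
    n1, n2 = pair.n1, pair.n2

    def _slope(y: np.ndarray) -> float:
        var = np.var(ell)
        if var < 1e-12:
            return (np.mean(y) - 1.0) / np.mean(ell)
        return float(np.cov(ell, y)[0, 1] / var)

    h1 = _slope(z1**2) * m / n1
    h2 = _slope(z2**2) * m / n2
    var = np.var(ell)
    if var < 1e-12:
        rho = np.mean(z1 * z2) / np.mean(ell) * m / np.sqrt(n1 * n2)
    else:
        rho = float(np.cov(ell, z1 * z2)[0, 1] / var) * m / np.sqrt(n1 * n2)
    h1 = float(np.clip(h1, 1e-4, 1.0))
    h2 = float(np.clip(h2, 1e-4, 1.0))
    rg = float(np.clip(rho / np.sqrt(h1 * h2), -0.99, 0.99))
    return h1, h2, rg


@dataclass
class RgEstimate:
    """Fitted genetic correlation with Wald inference and fit diagnostics."""

    rg: float
    se: float
    pval: float
    h1sq: float
    h2sq: float
    loglik: float
    n_snps: int
    at_boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "rg": self.rg, "se": self.se, "pval": self.pval,
            "h1sq": self.h1sq, "h2sq": self.h2sq,
            "loglik": self.loglik, "n_snps": self.n_snps,
            "at_boundary": self.at_boundary,
        }


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


def fit_genetic_correlation(pair: HarmonizedPair, ld: LDReference) -> RgEstimate:
    """Maximum-likelihood (h1sq, h2sq, rg) with Wald se/p for rg.

    Bounded L-BFGS-B from the moment-estimate start plus two deterministic
    perturbed restarts; the best converged optimum wins.  A boundary optimum
    (|rg| ~ 1 or h^2 ~ 0) is flagged, not rejected.
    """
    eig = transform_to_eigenbasis(pair, ld)
    m = eig.n_components
    n1, n2 = pair.n1, pair.n2

    def nll(x: np.ndarray) -> float:
        return negative_log_likelihood(eig, (x[0], x[1], x[2]), n1, n2, m)

    h1_0, h2_0, rg_0 = ldsc_moment_estimate(pair, ld)
    starts = [
        np.array([h1_0, h2_0, rg_0]),
        np.array([min(1.0, h1_0 * 1.5 + 0.01), min(1.0, h2_0 * 1.5 + 0.01), rg_0 * 0.5]),
        np.array([max(1e-3, h1_0 * 0.5), max(1e-3, h2_0 * 0.5), 0.0]),
    ]
    bounds = [(1e-6, 1.0), (1e-6, 1.0), (-1.0, 1.0)]
    best = None
    diagnostics = []
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-8, "gtol": 1e-8, "maxiter": 500},
        )
        diagnostics.append(res.message)
        if res.success and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(f"genetic-correlation fit failed to converge: {diagnostics}")

    h1, h2, rg = best.x
    at_boundary = bool(abs(rg) > 0.999 or min(h1, h2) < 1e-5)
    H = _numeric_hessian(nll, best.x)
    se = np.nan
    try:
        cov = np.linalg.inv(H)
        var_rg = cov[2, 2]
        if var_rg > 0:
            se = float(np.sqrt(var_rg))
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(se):
        cov = np.linalg.pinv(H)
        se = float(np.sqrt(abs(cov[2, 2]))) or 1e-12
        at_boundary = True
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(rg) / se))) if se > 0 else 1.0
    pval = max(pval, np.nextafter(0.0, 1.0))
    return RgEstimate(
        rg=float(rg), se=se, pval=pval, h1sq=float(h1), h2sq=float(h2),
        loglik=-float(best.fun), n_snps=m, at_boundary=at_boundary,
    )
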