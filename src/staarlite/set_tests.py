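"""Component association tests on a rare-variant set.

Given per-variant score statistics S = G'(y - mu) and their null covariance
Sigma = G'PG, this module provides the three component tests of the
annotation-weighted omnibus framework — weighted burden, weighted SKAT
(quadratic form in the scores) and ACAT-V (Cauchy combination of
single-variant p-values with a pooled burden component for ultra-rare
variants) — plus the Cauchy combination primitive itself.

All tests are score tests: they only need (S, Sigma) from the fitted null
model, never a per-set refit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from ._davies import DaviesError, davies_qf

__all__ = [
    "WeightSetting",
    "QuadFormPvalue",
    "beta_maf_weight",
    "burden_test",
    "quadform_pvalue",
    "skat_test",
    "cauchy_combine",
    "acatv_test",
]

#: relative cutoff below which trailing eigenvalues are discarded
EIGEN_RTOL = 1e-12
#: p-values below this use the 1/(p*pi) tangent tail substitution
CAUCHY_TINY = 1e-16


@dataclass(frozen=True)
class WeightSetting:
    """Beta(a1, a2) density parameters for MAF-based variant weighting.

    The two conventional settings are (1, 25), which upweights the rarest
    variants, and (1, 1), which weights all variants equally.
    """

    a1: float = 1.0
    a2: float = 25.0

    def __post_init__(self):
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("Beta parameters must be positive")


#: the two weight settings run by default in the omnibus grid
DEFAULT_SETTINGS = (WeightSetting(1.0, 25.0), WeightSetting(1.0, 1.0))


class QuadFormPvalue(NamedTuple):
    p: float
    method: str  # "davies" or "liu"


def beta_maf_weight(maf, setting: WeightSetting = WeightSetting()):
    """Beta-density weight w(maf) = dbeta(maf; a1, a2)."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    return stats.beta.pdf(maf, setting.a1, setting.a2)


def _chi2_sf1(x: float) -> float:
    return float(stats.chi2.sf(x, 1))


def burden_test(S, Sigma, w) -> float:
    """Weighted burden score test p-value.

    Q_B = (w'S)^2 / (w'Sigma w), compared to chi-square(1). Returns 1.0
    when the weighted variance is zero (no information).
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    w = np.asarray(w, dtype=float)
    if not np.any(w != 0):
        raise ValueError("burden test needs at least one nonzero weight")
    denom = float(w @ Sigma @ w)
    if denom <= 0:
        return 1.0
    q = float(w @ S) ** 2 / denom
    return _chi2_sf1(q)


def _liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(sum lam_j chi2_1 > q)."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    tstar = (q - mu_q) / sigma_q
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        dof = a**2 - 2.0 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        dof = c2**3 / c3**2
    mu_x = dof + delta
    sigma_x = np.sqrt(2.0) * a
    x = tstar * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, dof, delta))
    return float(stats.chi2.sf(x, dof))


def quadform_pvalue(q: float, lambdas: Sequence[float]) -> QuadFormPvalue:
    """P(sum_i lambda_i chi2_1 > q) via Davies' method with a Liu fallback.

    Eigenvalues below EIGEN_RTOL times the largest are truncated; Davies
    results outside (0, 1] (including exact zeros, which signal that the
    requested accuracy could not bracket the tail) fall back to the Liu
    moment-matching approximation. The method actually used is recorded.
    """
    lambdas = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    if lambdas.size == 0 or lambdas[0] <= 0:
        raise ValueError("quadform_pvalue needs at least one positive eigenvalue")
    lambdas = lambdas[lambdas > EIGEN_RTOL * lambdas[0]]
    if lambdas.size == 1:
        # a single eigenvalue is exactly a scaled chi-square(1)
        return QuadFormPvalue(float(stats.chi2.sf(q / lambdas[0], 1)), "exact_chi2")
    # coarse pass first, refined pass only when the p-value is small enough
    # for absolute accuracy 1e-6 to matter; the refined accuracy resolves
    # p down to ~1e-9
    try:
        p = davies_qf(q, lambdas, lim=1_000_000, acc=1e-6)
        if p < 1e-5:
            p = davies_qf(q, lambdas, lim=1_000_000, acc=1e-9)
        if 0.0 < p <= 1.0:
            return QuadFormPvalue(float(p), "davies")
    except DaviesError:
        pass
    # the moment-matching tail can underflow; a p of exactly 0 is never
    # emitted because downstream Cauchy combination needs p > 0
    return QuadFormPvalue(float(np.clip(_liu_pvalue(q, lambdas), 1e-300, 1.0)), "liu")


def skat_test(S, Sigma, w) -> float:
    """Weighted SKAT p-value: Q_S = sum_j (w_j S_j)^2 against the eigenvalues
    of diag(w) Sigma diag(w)."""
    S = np.asarray(S, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    w = np.asarray(w, dtype=float)
    if not np.any(w != 0):
        raise ValueError("SKAT needs at least one nonzero weight")
    q = float(((w * S) ** 2).sum())
    K = (w[:, None] * Sigma) * w[None, :]
    lambdas = np.linalg.eigvalsh(K)
    lambdas = lambdas[lambdas > 0]
    if lambdas.size == 0:
        return 1.0
    return quadform_pvalue(q, lambdas).p


def cauchy_combine(pvals, weights=None) -> float:
    """Cauchy combination (ACAT) of p-values.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i;  p = 0.5 - arctan(T)/pi.
    p_i below 1e-16 use the tail substitution tan((0.5-p)pi) ~ 1/(p pi);
    p_i = 1 is clipped to 1 - 1e-16 so the tangent stays finite.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("cauchy_combine needs at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative, not all zero")
    p = np.minimum(p, 1.0 - CAUCHY_TINY)
    t = np.where(p < CAUCHY_TINY, 1.0 / (p * np.pi), np.tan((0.5 - p) * np.pi))
    tstat = float((w * t).sum() / w.sum())
    if tstat > 1e15:  # deep tail: arctan cancels catastrophically
        return 1.0 / (tstat * np.pi)
    return 0.5 - np.arctan(tstat) / np.pi


def _single_variant_p(S, Sigma_diag):
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(Sigma_diag > 0, S**2 / np.where(Sigma_diag > 0, Sigma_diag, 1.0), 0.0)
    return stats.chi2.sf(z2, 1)


def acatv_test(
    S,
    Sigma,
    maf,
    mac,
    setting: WeightSetting = WeightSetting(),
    annotation=None,
    mac_threshold: int = 10,
) -> float:
    """ACAT-V: Cauchy combination of single-variant p-values (MAC >= threshold)
    with one pooled burden p-value for the ultra-rare remainder (MAC < threshold).

    Per-variant test weight u_j = dbeta(maf_j; a1, a2) * annotation_j (the
    annotation factor defaults to 1, the MAF-only channel). Cauchy weights
    are w_j = u_j^2 * maf_j (1 - maf_j); the pooled burden component runs
    with weights u_j on the ultra-rare subset and enters the combination at
    the mean of that subset's w_j. When every variant is ultra-rare the
    result is exactly the burden p-value of the whole set — the degeneracy
    the omnibus safeguards target.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    maf = np.asarray(maf, dtype=float)
    mac = np.asarray(mac)
    if S.size == 0:
        raise ValueError("empty variant set")
    u = beta_maf_weight(maf, setting)
    if annotation is not None:
        u = u * np.asarray(annotation, dtype=float)
    if not np.any(u != 0):
        return 1.0
    w_cauchy = u**2 * maf * (1.0 - maf)
    rare = mac < mac_threshold
    pvals, weights = [], []
    if np.any(~rare):
        idx = np.flatnonzero(~rare)
        p_single = _single_variant_p(S[idx], np.diag(Sigma)[idx])
        pvals.extend(p_single.tolist())
        weights.extend(w_cauchy[idx].tolist())
    if np.any(rare):
        idx = np.flatnonzero(rare)
        if not np.any(u[idx] != 0):
            p_burden = 1.0
        else:
            p_burden = burden_test(S[idx], Sigma[np.ix_(idx, idx)], u[idx])
        if not np.any(~rare):
            return p_burden
        pvals.append(p_burden)
        weights.append(float(np.mean(w_cauchy[idx])))
    return cauchy_combine(pvals, weights)
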