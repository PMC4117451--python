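"""Variance-based parent-of-origin test for unrelated individuals.

Model: with paternal and maternal coded-allele effects beta_pat and beta_mat,
the heterozygous group is a 50/50 mixture of two sub-populations with means
separated by delta = beta_pat - beta_mat, so its variance exceeds the
homozygous variance by delta^2 / 4.  The test is a Brown-Forsythe-type
regression: phenotypes are centred at their genotype-group medians (which
removes any marginal/mean effect), and the absolute deviations are regressed
on a heterozygosity covariate.  For hard genotype calls the covariate is the
0/1 heterozygote indicator and the slope is exactly the difference in mean
absolute deviation between heterozygotes and homozygotes; for imputed data
the covariate is the per-individual heterozygote probability p(AB) and
medians/deviations are probability-weighted, so degenerate probability
triples reproduce the hard-call test to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupMedians",
    "PoeTestResult",
    "SkipSnp",
    "group_medians",
    "abs_deviations",
    "poe_brown_forsythe",
    "variance_by_group",
]


class SkipSnp(Exception):
    """Raised when a SNP fails QC; ``.code`` is a machine-readable reason."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(message or code)


@dataclass(frozen=True)
class GroupMedians:
    """Median phenotype per genotype group (SD units)."""

    m_AA: float
    m_AB: float
    m_BB: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m_AA, self.m_AB, self.m_BB])


@dataclass
class PoeTestResult:
    """Result of the variance-based POE test at one SNP.

    ``b`` is the slope of the absolute-deviation regression (mean absolute
    deviation of heterozygotes minus homozygotes, phenotype-SD units);
    ``stat = b/se`` is referred to Student t with n-2 df, two-sided.
    """

    snp_id: str
    b: float
    se: float
    stat: float
    p: float
    n_het_eff: float
    n_hom_eff: float
    var_AA: float
    var_AB: float
    var_BB: float
    maf: float
    chrom: str = "."
    pos: int = 1
    allele_A: str = "A"
    allele_B: str = "B"


def _validate(y: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 3:
        raise ValueError("probs must have shape (n, 3)")
    if y.shape[0] != probs.shape[0]:
        raise ValueError("residuals and probs length mismatch")
    keep = ~np.isnan(y) & ~np.isnan(probs).any(axis=1)
    return y[keep], probs[keep]


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median; equal weights reproduce the mean-of-middle-two rule."""
    pos = weights > 0
    values, weights = values[pos], weights[pos]
    if values.size == 0:
        raise ValueError("empty group")
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    half = 0.5 * cw[-1]
    k = int(np.searchsorted(cw, half))
    if abs(cw[k] - half) <= 1e-12 * cw[-1] and k + 1 < v.size:
        return 0.5 * (v[k] + v[k + 1])
    return float(v[k])


def group_medians(
    residuals: np.ndarray,
    probs: np.ndarray,
    weighting: str = "weighted",
    allow_empty: bool = False,
) -> GroupMedians:
    """Median phenotype in each genotype group.

    ``weighting='hard'`` uses max-probability calls; ``'weighted'`` computes
    the weighted median with per-individual genotype probabilities as weights
    (identical to hard for degenerate triples).  With ``allow_empty`` a group
    carrying zero probability mass gets a placeholder median of 0.0 -- safe
    because such a group contributes nothing to any weighted deviation.
    """
    y, p = _validate(residuals, probs)
    if weighting not in ("hard", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    meds = []
    names = ("AA", "AB", "BB")
    hard = np.argmax(p, axis=1)
    for g in range(3):
        sel = y[hard == g] if weighting == "hard" else None
        empty = sel.size == 0 if weighting == "hard" else not (p[:, g] > 0).any()
        if empty:
            if allow_empty:
                meds.append(0.0)
                continue
            raise ValueError(f"genotype group {names[g]} is empty")
        if weighting == "hard":
            meds.append(float(np.median(sel)))
        else:
            meds.append(_weighted_median(y, p[:, g]))
    return GroupMedians(*meds)


def abs_deviations(
    residuals: np.ndarray, probs: np.ndarray, medians: GroupMedians
) -> np.ndarray:
    """Expected absolute deviation from the group median under genotype
    uncertainty: z_i = sum_g p_ig |y_i - m_g|."""
    y, p = _validate(residuals, probs)
    m = medians.as_array()
    return (p * np.abs(y[:, None] - m[None, :])).sum(axis=1)


def variance_by_group(
    residuals: np.ndarray, probs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased phenotype variance and count per hard-called genotype group.

    Returns ``(variances, counts)``; groups with fewer than 2 members have
    NaN variance.
    """
    y, p = _validate(residuals, probs)
    hard = np.argmax(p, axis=1)
    out = np.full(3, np.nan)
    counts = np.zeros(3, dtype=int)
    for g in range(3):
        sel = y[hard == g]
        counts[g] = sel.size
        if sel.size >= 2:
            out[g] = float(np.var(sel, ddof=1))
    return out, counts


def poe_brown_forsythe(
    residuals: np.ndarray,
    probs: np.ndarray,
    min_het_eff: float = 50.0,
    min_n: int = 30,
    snp_id: str = ".",
) -> PoeTestResult:
    """Brown-Forsythe POE test: regress median-centred absolute deviations on
    the heterozygote probability.

    Raises :class:`SkipSnp` when the SNP fails sample-size QC (reason codes
    ``n_too_small``, ``n_het_eff``, ``monomorphic``).
    """
    y, p = _validate(residuals, probs)
    n = y.size
    if n < min_n:
        raise SkipSnp("n_too_small", f"{snp_id}: n={n} < {min_n}")
    x = p[:, 1]
    n_het_eff = float(x.sum())
    n_hom_eff = float(n - n_het_eff)
    if n_het_eff < min_het_eff or n_hom_eff < 2:
        raise SkipSnp(
            "n_het_eff", f"{snp_id}: effective het count {n_het_eff:.1f} < {min_het_eff}"
        )
    if np.ptp(x) == 0:
        raise SkipSnp("monomorphic", f"{snp_id}: heterozygosity covariate constant")

    meds = group_medians(y, p, weighting="weighted", allow_empty=True)
    z = abs_deviations(y, p, meds)

    xc = x - x.mean()
    sxx = float(xc @ xc)
    b = float(xc @ z) / sxx
    resid = z - z.mean() - b * xc
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0:
        raise ValueError(f"{snp_id}: zero residual variance in deviation regression")
    se = float(np.sqrt(sigma2 / sxx))
    t = b / se
    pval = float(2.0 * stats.t.sf(abs(t), dof))
    pval = max(pval, np.finfo(float).tiny)

    variances, _counts = variance_by_group(y, p)
    dose = p[:, 1] + 2.0 * p[:, 2]
    freq_B = float(dose.mean() / 2.0)
    maf = min(freq_B, 1.0 - freq_B)
    return PoeTestResult(
        snp_id=snp_id,
        b=b,
        se=se,
        stat=float(t),
        p=pval,
        n_het_eff=n_het_eff,
        n_hom_eff=n_hom_eff,
        var_AA=float(variances[0]),
        var_AB=float(variances[1]),
        var_BB=float(variances[2]),
        maf=maf,
    )
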