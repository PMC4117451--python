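"""Artefact diagnostics for variance-based POE hits.

An inflated heterozygote variance is not proof of a parent-of-origin effect:
it can also arise from (a) overdominance combined with interactions or
non-linear trait scales, (b) a gene-environment interaction that scales the
phenotypic variance with the allelic dosage, or (c) a strong marginal effect
pushed through a non-linear transformation whose curvature peaks near the
heterozygote mean.  This module implements the corresponding checks:

* ``overdominance_test`` -- het-vs-hom mean comparison;
* ``variance_dosage_test`` -- absolute deviations regressed on additively /
  dominantly / recessively coded dosage instead of the het indicator;
* ``transform_robustness`` -- rerun the POE test after log and
  inverse-normal-quantile re-expression of the trait;
* ``taylor_inflation`` -- the second-order Taylor prediction of how much a
  smooth transformation inflates the heterozygote variance given a marginal
  effect, which shows the inflation is unbounded in the steepness of an
  S-shaped transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from poescan.poe_test import PoeTestResult, abs_deviations, group_medians, poe_brown_forsythe
from poescan.scan_meta import prepare_phenotype

__all__ = [
    "DiagnosticsReport",
    "SigmoidTransform",
    "overdominance_test",
    "variance_dosage_test",
    "transform_robustness",
    "taylor_inflation",
    "inverse_normal_transform",
    "diagnose_snp",
]

CODINGS = {
    "additive": np.array([0.0, 1.0, 2.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "recessive": np.array([0.0, 0.0, 1.0]),
}


def _ols_slope_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value for the slope of y on x (t reference, n-2 df)."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant regressor")
    b = float(xc @ y) / sxx
    resid = y - y.mean() - b * xc
    sigma2 = float(resid @ resid) / (n - 2)
    if sigma2 <= 0:
        raise ValueError("zero residual variance")
    t = b / np.sqrt(sigma2 / sxx)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def overdominance_test(residuals: np.ndarray, probs: np.ndarray) -> float:
    """Two-sided p for a heterozygote mean shift relative to the pooled
    homozygote mean.

    Implemented as the regression of the phenotype on the heterozygote
    probability, which for hard calls is exactly the pooled two-sample
    t-test of het vs hom means and extends it with probability weights for
    imputed genotypes.
    """
    y = np.asarray(residuals, dtype=float)
    p = np.asarray(probs, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(p).any(axis=1)
    return _ols_slope_p(p[keep, 1], y[keep])


def variance_dosage_test(
    residuals: np.ndarray, probs: np.ndarray, coding: str = "additive"
) -> float:
    """Variance-vs-dosage check: regress median-centred absolute deviations
    on the coded dosage (additive 0/1/2, dominant 0/1/1, recessive 0/0/1).

    A smaller p here than in the POE test suggests the variance signal
    tracks dosage (a GxE-type pattern) rather than heterozygosity.
    """
    if coding not in CODINGS:
        raise ValueError(f"coding must be one of {sorted(CODINGS)}")
    y = np.asarray(residuals, dtype=float)
    p = np.asarray(probs, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(p).any(axis=1)
    y, p = y[keep], p[keep]
    x = p @ CODINGS[coding]
    if np.ptp(x) == 0:
        raise ValueError("monomorphic coding; test skipped")
    meds = group_medians(y, p, weighting="weighted", allow_empty=True)
    z = abs_deviations(y, p, meds)
    return _ols_slope_p(x, z)


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal-quantile transform using Blom plotting
    positions (rank - 3/8)/(n + 1/4); ties get the average rank."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = ndtri((ranks - 0.375) / (ok.sum() + 0.25))
    return out


def _apply_transform(trait: np.ndarray, transform: str, log_shift: float) -> np.ndarray:
    if transform == "identity":
        return trait
    if transform == "log":
        shifted = trait + log_shift
        if np.nanmin(shifted) <= 0:
            raise ValueError(
                "log transform requires positive trait values; set log_shift"
            )
        return np.log(shifted)
    if transform == "inqt":
        return inverse_normal_transform(trait)
    raise ValueError(f"unknown transform {transform!r}")


def transform_robustness(
    pheno: pd.DataFrame,
    probs: np.ndarray,
    transforms: tuple[str, ...] = ("identity", "log", "inqt"),
    log_shift: float = 0.0,
    min_het_eff: float = 50.0,
    min_n: int = 30,
    snp_id: str = ".",
) -> dict[str, PoeTestResult]:
    """Re-run the POE test after re-expressing the raw trait.

    Each transform is applied to the raw trait, then the phenotype is
    re-residualised on age/age^2 within sex and re-standardised before
    testing; ``probs`` must align row-wise with ``pheno``.
    """
    out: dict[str, PoeTestResult] = {}
    for tr in transforms:
        tab = pheno.copy()
        tab["trait"] = _apply_transform(tab["trait"].to_numpy(float), tr, log_shift)
        prepared = prepare_phenotype(tab)
        out[tr] = poe_brown_forsythe(
            prepared["residual"].to_numpy(float), probs,
            min_het_eff=min_het_eff, min_n=min_n, snp_id=snp_id,
        )
    return out


@dataclass
class SigmoidTransform:
    """Logistic-sigmoid trait transform scale / (1 + exp(-steepness*(y - location))).

    Strictly increasing and twice differentiable, the prototypical S-shaped
    re-expression whose curvature can concentrate near any trait value.
    """

    location: float = 0.0
    steepness: float = 1.0
    scale: float = 1.0

    def __call__(self, y):
        return self.scale / (1.0 + np.exp(-self.steepness * (y - self.location)))

    def deriv(self, y):
        s = self(y) / self.scale
        return self.scale * self.steepness * s * (1.0 - s)

    def deriv2(self, y):
        s = self(y) / self.scale
        return self.scale * self.steepness**2 * s * (1.0 - s) * (1.0 - 2.0 * s)


def taylor_inflation(transform, mu_AB: float, a: float, sigma: float) -> float:
    """Predicted heterozygote-minus-homozygote variance difference on the
    transformed scale, for a purely additive marginal effect ``a``.

    For Gaussian Y with group mean m the second-order expansion gives
    Var f(Y) ~ f'(m)^2 sigma^2 + f''(m)^2 sigma^4 / 2.  The heterozygote
    group sits at ``mu_AB`` and the reference homozygote group at
    ``mu_AB - a``; the returned difference shows how a non-linear scale can
    mimic a POE variance signal.
    """
    def approx_var(m: float) -> float:
        d1 = float(transform.deriv(m))
        d2 = float(transform.deriv2(m))
        return d1**2 * sigma**2 + 0.5 * d2**2 * sigma**4

    return approx_var(mu_AB) - approx_var(mu_AB - a)


@dataclass
class DiagnosticsReport:
    """Per-SNP artefact screen.

    ``GXE_DRIVEN`` fires when any dosage-coded variance test beats the POE
    test's p-value; ``TRANSFORM_FRAGILE`` when -log10 POE p varies by more
    than ``fragile_factor`` across trait transforms; ``OVERDOMINANT`` when
    the het mean shift is significant at ``overdominance_alpha``.
    """

    snp_id: str
    p_overdominance: float
    p_gxe: dict[str, float]
    p_poe: dict[str, float]
    flags: set[str] = field(default_factory=set)


def diagnose_snp(
    pheno: pd.DataFrame,
    probs: np.ndarray,
    snp_id: str = ".",
    transforms: tuple[str, ...] = ("identity", "log", "inqt"),
    log_shift: float = 0.0,
    fragile_factor: float = 10.0,
    overdominance_alpha: float = 0.05,
    min_het_eff: float = 50.0,
    min_n: int = 30,
) -> DiagnosticsReport:
    """Run the full artefact screen for one SNP and set the flags."""
    prepared = prepare_phenotype(pheno.copy())
    resid = prepared["residual"].to_numpy(float)
    p_over = overdominance_test(resid, probs)
    p_gxe = {c: variance_dosage_test(resid, probs, c) for c in CODINGS}
    poe = transform_robustness(
        pheno, probs, transforms=transforms, log_shift=log_shift,
        min_het_eff=min_het_eff, min_n=min_n, snp_id=snp_id,
    )
    p_poe = {tr: r.p for tr, r in poe.items()}
    flags: set[str] = set()
    if p_over < overdominance_alpha:
        flags.add("OVERDOMINANT")
    if min(p_gxe.values()) < p_poe.get("identity", 1.0):
        flags.add("GXE_DRIVEN")
    neglog = [-np.log10(max(v, np.finfo(float).tiny)) for v in p_poe.values()]
    if len(neglog) > 1 and min(neglog) > 0 and max(neglog) / min(neglog) > fragile_factor:
        flags.add("TRANSFORM_FRAGILE")
    return DiagnosticsReport(
        snp_id=snp_id, p_overdominance=p_over, p_gxe=p_gxe, p_poe=p_poe, flags=flags
    )
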