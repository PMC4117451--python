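"""Paternal/maternal effect decomposition and explained variance.

With paternal and maternal coded-allele effects beta_pat and beta_mat, two
quantities determine both: their difference delta = beta_pat - beta_mat
(estimable from families, or from group variances via the T statistic) and
their mean mu = (beta_pat + beta_mat) / 2 (the ordinary additive GWAS
effect, supplied externally).  On a unit-variance phenotype, knowing the
parental origin of the alleles the SNP explains
2 p (1-p) (beta_pat^2 + beta_mat^2) of the phenotypic variance, where p is
the allele frequency.

The variance-based route T = var_AB - (var_AA + var_BB)/2 has expectation
delta^2 / 4 under the mixture model, so 2*sqrt(max(T, 0)) estimates |delta|;
this estimate is strongly affected by the winner's curse when the same data
selected the SNP, which is why family-based delta estimates are preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VarianceDelta",
    "EffectDecomposition",
    "t_statistic",
    "decompose",
    "explained_variance",
]


@dataclass
class VarianceDelta:
    """Variance-contrast statistic T and the |delta| estimate it implies."""

    T: float
    var_T: float
    delta_abs_hat: float


@dataclass
class EffectDecomposition:
    delta: float
    mu: float
    beta_pat: float
    beta_mat: float
    maf: float | None = None
    explained_variance: float | None = None


def t_statistic(
    var_AA: float, var_AB: float, var_BB: float,
    n_AA: int, n_AB: int, n_BB: int,
) -> VarianceDelta:
    """T = var_AB - (var_AA + var_BB)/2, an unbiased estimate of delta^2/4.

    Its sampling variance uses the Gaussian approximation
    Var(s^2) ~ 2 sigma^4 / (n - 1) with the three groups independent.
    """
    for name, v in (("var_AA", var_AA), ("var_AB", var_AB), ("var_BB", var_BB)):
        if v is None or not np.isfinite(v):
            raise ValueError(f"{name} is missing")
    for name, n in (("n_AA", n_AA), ("n_AB", n_AB), ("n_BB", n_BB)):
        if n < 2:
            raise ValueError(f"{name} must be >= 2")
    T = var_AB - 0.5 * (var_AA + var_BB)
    var_T = 2.0 * var_AB**2 / (n_AB - 1) + 0.5 * (
        var_AA**2 / (n_AA - 1) + var_BB**2 / (n_BB - 1)
    )
    return VarianceDelta(T=float(T), var_T=float(var_T),
                         delta_abs_hat=float(2.0 * np.sqrt(max(T, 0.0))))


def decompose(delta: float, mu: float, maf: float | None = None) -> EffectDecomposition:
    """Recover beta_pat = mu + delta/2 and beta_mat = mu - delta/2.

    When ``maf`` is given the explained variance is filled in as well.
    """
    beta_pat = mu + delta / 2.0
    beta_mat = mu - delta / 2.0
    ev = explained_variance(maf, beta_pat, beta_mat) if maf is not None else None
    return EffectDecomposition(
        delta=float(delta), mu=float(mu),
        beta_pat=float(beta_pat), beta_mat=float(beta_mat),
        maf=maf, explained_variance=ev,
    )


def explained_variance(p: float, beta_pat: float, beta_mat: float) -> float:
    """Fraction of (unit) phenotypic variance explained when parental origin
    is known: 2 p (1-p) (beta_pat^2 + beta_mat^2)."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must be in (0, 1)")
    return float(2.0 * p * (1.0 - p) * (beta_pat**2 + beta_mat**2))
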