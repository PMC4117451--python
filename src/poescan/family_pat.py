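"""Parental-origin assignment in trios and the simplified parental
asymmetry test (PAT).

Only heterozygous offspring are informative for a parent-of-origin effect,
and only when at least one parent genotype forces the origin of the coded
(B) allele.  Informative offspring (at most one per family) are grouped by
the parental origin of B and the equality of group phenotype means is tested
with a Student t-test; the mean difference (paternal minus maternal, SD
units) and its standard error feed the inverse-variance meta-analysis for
multi-study replication.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from poescan.io_formats import GenotypePanel

__all__ = [
    "Origin",
    "PatResult",
    "assign_origin",
    "assign_origin_panel",
    "collect_informative",
    "pat_test",
    "replication_decision",
]


class Origin(enum.Enum):
    PATERNAL_B = "PATERNAL_B"
    MATERNAL_B = "MATERNAL_B"
    AMBIGUOUS = "AMBIGUOUS"
    NOT_HET = "NOT_HET"
    MENDEL_ERROR = "MENDEL_ERROR"
    MISSING = "MISSING"


def _can_transmit(gt: int | None, allele: int) -> bool:
    """Can a parent with genotype ``gt`` (B-allele count, None = missing)
    transmit ``allele`` (0 = A, 1 = B)?"""
    if gt is None:
        return True
    return (allele == 1 and gt >= 1) or (allele == 0 and gt <= 1)


def assign_origin(
    offspring_gt: int | None, father_gt: int | None, mother_gt: int | None
) -> Origin:
    """Determine the parental origin of the coded (B) allele in a
    heterozygous offspring from (possibly missing) parental hard calls.

    The offspring's B allele came either from the father (with the mother
    supplying A) or from the mother (father supplying A); each scenario is
    checked for compatibility with the observed parental genotypes.
    """
    if offspring_gt is None:
        return Origin.MISSING
    if offspring_gt != 1:
        return Origin.NOT_HET
    paternal_b = _can_transmit(father_gt, 1) and _can_transmit(mother_gt, 0)
    maternal_b = _can_transmit(mother_gt, 1) and _can_transmit(father_gt, 0)
    if paternal_b and maternal_b:
        return Origin.AMBIGUOUS
    if paternal_b:
        return Origin.PATERNAL_B
    if maternal_b:
        return Origin.MATERNAL_B
    return Origin.MENDEL_ERROR


def assign_origin_panel(
    panel: GenotypePanel,
    pedigree: pd.DataFrame,
    snp_id: str,
    hard_call_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-offspring origin assignment at one SNP.

    Genotype probability triples are hard-called at ``hard_call_threshold``
    max-probability (below it the genotype counts as missing).  Returns one
    row per pedigree entry that has at least one recorded parent.
    """
    rec = panel.get(snp_id)
    calls = rec.hard_calls(threshold=hard_call_threshold)
    by_iid = {s: int(c) for s, c in zip(panel.samples, calls)}

    has_parent = pedigree["father_iid"].notna() | pedigree["mother_iid"].notna()
    ped = pedigree[has_parent]

    def gts(col: pd.Series) -> np.ndarray:
        return col.map(lambda i: by_iid.get(i, -1) if pd.notna(i) else -1
                       ).to_numpy(dtype=int)

    off, fa, mo = gts(ped["iid"]), gts(ped["father_iid"]), gts(ped["mother_iid"])
    # vectorised transmission compatibility (missing parent = unconstrained)
    fa_can_B, fa_can_A = (fa == -1) | (fa >= 1), (fa == -1) | (fa <= 1)
    mo_can_B, mo_can_A = (mo == -1) | (mo >= 1), (mo == -1) | (mo <= 1)
    pat_ok = fa_can_B & mo_can_A
    mat_ok = mo_can_B & fa_can_A
    codes = np.select(
        [off == -1, off != 1, pat_ok & mat_ok, pat_ok, mat_ok],
        [0, 1, 2, 3, 4],
        default=5,
    )
    by_code = [Origin.MISSING, Origin.NOT_HET, Origin.AMBIGUOUS,
               Origin.PATERNAL_B, Origin.MATERNAL_B, Origin.MENDEL_ERROR]
    status = [by_code[c] for c in codes]
    return pd.DataFrame(
        {"fid": ped["fid"].to_numpy(), "iid": ped["iid"].to_numpy(),
         "status": status},
        columns=["fid", "iid", "status"],
    )


def collect_informative(
    assignments: pd.DataFrame, pheno: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Collect at most one informative offspring per family and split their
    prepared phenotype residuals by parental origin of the B allele.

    Within a family the eligible offspring with the smallest iid is taken
    (a deterministic rule so reruns are reproducible).  Returns
    ``(paternal_residuals, maternal_residuals, counts)`` where ``counts``
    reports eligible/contributed/Mendelian-error tallies.
    """
    if "residual" not in pheno.columns:
        raise ValueError("phenotypes must be prepared first (no residual column)")
    resid = dict(zip(pheno["iid"], pheno["residual"]))
    counts = {
        "n_families": assignments["fid"].nunique(),
        "n_mendel_errors": int((assignments["status"] == Origin.MENDEL_ERROR).sum()),
        "n_contributed": 0,
    }
    pat, mat = [], []
    for _fid, grp in assignments.groupby("fid", sort=True):
        eligible = grp[
            grp["status"].isin([Origin.PATERNAL_B, Origin.MATERNAL_B])
            & grp["iid"].map(lambda i: i in resid and np.isfinite(resid[i]))
        ]
        if eligible.empty:
            continue
        pick = eligible.sort_values("iid", kind="mergesort").iloc[0]
        counts["n_contributed"] += 1
        (pat if pick["status"] == Origin.PATERNAL_B else mat).append(resid[pick["iid"]])
    return np.asarray(pat, dtype=float), np.asarray(mat, dtype=float), counts


@dataclass
class PatResult:
    """Simplified parental asymmetry test at one SNP.

    ``diff`` = mean phenotype of paternal-B carriers minus maternal-B
    carriers (SD units) = beta(coded paternal) - beta(coded maternal).
    """

    snp_id: str
    mean_pat: float
    mean_mat: float
    diff: float
    se: float
    t: float
    p: float
    n_pat: int
    n_mat: int


def pat_test(
    group_pat: np.ndarray, group_mat: np.ndarray,
    snp_id: str = ".", welch: bool = False,
) -> PatResult:
    """Student t-test (pooled variance by default, Welch by flag) of the
    phenotype means of paternal-B vs maternal-B heterozygous offspring."""
    a = np.asarray(group_pat, dtype=float)
    b = np.asarray(group_mat, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both origin groups need at least 2 offspring")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero within-group variance in both groups")
    diff = float(a.mean() - b.mean())
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se = float(np.sqrt(va + vb))
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        se = float(np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size)))
    return PatResult(
        snp_id=snp_id,
        mean_pat=float(a.mean()),
        mean_mat=float(b.mean()),
        diff=diff,
        se=se,
        t=float(t),
        p=float(p),
        n_pat=int(a.size),
        n_mat=int(b.size),
    )


def replication_decision(
    p_values, m: int | None = None, fwe: float = 0.05
) -> np.ndarray:
    """Bonferroni replication call: pass iff p < fwe / m (strict).

    ``m`` defaults to the number of tested SNPs.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < fwe / m
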