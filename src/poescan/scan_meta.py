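"""Phenotype preparation, sex-stratified genome scan, fixed-effect
meta-analysis, candidate selection and lead pruning.

The scan follows the two-stage GWAS design: the trait is residualised on age
and age^2 within each sex stratum and standardised to zero mean / unit
variance, the variance-based POE test is run per (SNP, stratum), and
per-stratum slopes are combined with inverse-variance fixed-effect
meta-analysis.  Candidates are SNPs below a genome-wide threshold, or below a
relaxed threshold when within a flank of known imprinted regions; lead SNPs
are greedily pruned so that no two survivors are within a distance window or
in LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from poescan.io_formats import GenotypePanel
from poescan.poe_test import SkipSnp, poe_brown_forsythe

__all__ = [
    "MetaResult",
    "prepare_phenotype",
    "run_scan",
    "meta_fixed",
    "meta_scan",
    "se_from_beta_p",
    "select_candidates",
    "prune_leads",
    "effective_tests",
]


@dataclass
class MetaResult:
    """Inverse-variance fixed-effect combination of per-stratum estimates."""

    snp_id: str
    beta: float
    se: float
    p: float
    n_strata: int
    betas: np.ndarray
    ses: np.ndarray


def prepare_phenotype(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "age2"),
    min_stratum: int = 10,
) -> pd.DataFrame:
    """Residualise the trait on age and age^2 within each sex stratum and
    standardise the residuals (mean 0, unit variance).

    Returns a copy with a ``residual`` column; strata smaller than
    ``min_stratum`` are dropped with a warning-level record (residual NaN).
    """
    out = table.copy()
    out["residual"] = np.nan
    for _sex, idx in out.groupby("sex", observed=True).groups.items():
        sub = out.loc[idx]
        ok = sub["trait"].notna() & sub["age"].notna()
        sub = sub[ok]
        if len(sub) < min_stratum:
            continue
        age = sub["age"].to_numpy(float)
        cols = [np.ones_like(age)]
        if "age" in covariates:
            cols.append(age)
        if "age2" in covariates:
            cols.append(age**2)
        X = np.column_stack(cols)
        y = sub["trait"].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            raise ValueError("trait residuals are constant within a stratum")
        out.loc[sub.index, "residual"] = resid / sd
    return out


def run_scan(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    min_het_eff: float = 50.0,
    min_n: int = 30,
    stratify_by: str = "sex",
) -> pd.DataFrame:
    """Run the POE test for every SNP within every stratum.

    Returns a tidy frame with one row per (SNP, stratum); skipped tests keep
    their reason code in the ``reason`` column.  Sample order never matters:
    genotype columns are matched to phenotype rows by sample id.
    """
    if "residual" not in pheno.columns:
        raise ValueError("phenotypes must be prepared first (no residual column)")
    iid_to_row = {iid: i for i, iid in enumerate(pheno["iid"])}
    g_idx = np.array(
        [i for i, s in enumerate(panel.samples) if s in iid_to_row], dtype=int
    )
    if g_idx.size == 0:
        raise ValueError("no overlap between genotype samples and phenotype iids")
    p_idx = np.array([iid_to_row[panel.samples[i]] for i in g_idx])
    resid_all = pheno["residual"].to_numpy(float)[p_idx]
    strata = pheno[stratify_by].astype(str).to_numpy()[p_idx]

    rows = []
    for rec in panel:
        probs = rec.probs[g_idx]
        for stratum in sorted(set(strata)):
            sel = (strata == stratum) & ~np.isnan(resid_all)
            row = {
                "snp_id": rec.snp_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "allele_A": rec.allele_A,
                "allele_B": rec.allele_B,
                "stratum": stratum,
            }
            try:
                res = poe_brown_forsythe(
                    resid_all[sel], probs[sel],
                    min_het_eff=min_het_eff, min_n=min_n, snp_id=rec.snp_id,
                )
            except SkipSnp as exc:
                row.update({"b": np.nan, "se": np.nan, "p": np.nan,
                            "n_het_eff": np.nan, "maf": np.nan,
                            "var_AA": np.nan, "var_AB": np.nan, "var_BB": np.nan,
                            "reason": exc.code})
            else:
                row.update({"b": res.b, "se": res.se, "p": res.p,
                            "n_het_eff": res.n_het_eff, "maf": res.maf,
                            "var_AA": res.var_AA, "var_AB": res.var_AB,
                            "var_BB": res.var_BB, "reason": "ok"})
            rows.append(row)
    return pd.DataFrame(rows)


def meta_fixed(betas, ses, snp_id: str = ".") -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis.

    beta = sum(b_k / se_k^2) / sum(1 / se_k^2); se = sqrt(1 / sum(1/se_k^2));
    two-sided p from beta/se against the standard normal.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape:
        raise ValueError("betas and ses must have matching lengths")
    if betas.size == 0:
        raise ValueError("at least one study required")
    if not (ses > 0).all():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)
    return MetaResult(snp_id, beta, se, p, betas.size, betas, ses)


def meta_scan(scan: pd.DataFrame) -> pd.DataFrame:
    """Combine per-stratum scan rows into one meta row per SNP."""
    rows = []
    for snp_id, grp in scan[scan["reason"] == "ok"].groupby("snp_id", sort=False):
        m = meta_fixed(grp["b"].to_numpy(), grp["se"].to_numpy(), snp_id=snp_id)
        first = grp.iloc[0]
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": first["chrom"],
                "pos": first["pos"],
                "beta": m.beta,
                "se": m.se,
                "p": m.p,
                "n_strata": m.n_strata,
                "maf": float(grp["maf"].mean()),
            }
        )
    return pd.DataFrame(rows)


def se_from_beta_p(beta: float, p: float) -> float:
    """Back-derive a standard error from a printed (beta, two-sided P) pair
    via the normal quantile: se = |beta| / Phi^-1(1 - P/2)."""
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    z = ndtri(1.0 - p / 2.0)
    if z <= 0:
        raise ValueError("p too close to 1 to recover a standard error")
    return abs(beta) / z


def _near_imprinted(
    chrom: str, pos: int, regions: dict[str, list[tuple[int, int]]], flank: int
) -> bool:
    # pos is 1-based; regions are 0-based half-open
    p0 = pos - 1
    for start, end in regions.get(str(chrom).removeprefix("chr"), []):
        if start - flank <= p0 < end + flank:
            return True
    return False


def select_candidates(
    meta: pd.DataFrame,
    imprinted_regions: dict[str, list[tuple[int, int]]] | None = None,
    p_genomewide: float = 5e-6,
    p_imprinted: float = 5e-4,
    flank: int = 500_000,
) -> pd.DataFrame:
    """Select replication candidates.

    A SNP qualifies when (1) its POE P is strictly below the genome-wide
    threshold, or (2) strictly below the relaxed threshold while lying within
    ``flank`` bp of a known imprinted region; criterion 'both' when both hold.
    """
    regions = imprinted_regions or {}
    rows = []
    for _, r in meta.iterrows():
        gw = r["p"] < p_genomewide
        imp = r["p"] < p_imprinted and _near_imprinted(
            r["chrom"], int(r["pos"]), regions, flank
        )
        if not (gw or imp):
            continue
        criterion = "both" if (gw and imp) else ("genomewide" if gw else "imprinted")
        row = dict(r)
        row["criterion"] = criterion
        rows.append(row)
    cols = list(meta.columns) + ["criterion"]
    return pd.DataFrame(rows, columns=cols)


def _r2(dose_a: np.ndarray, dose_b: np.ndarray) -> float:
    ok = ~np.isnan(dose_a) & ~np.isnan(dose_b)
    a, b = dose_a[ok], dose_b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def prune_leads(
    candidates: pd.DataFrame,
    panel: GenotypePanel | None = None,
    window_bp: int = 1_000_000,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Greedy lead pruning: visit candidates by ascending P (snp_id
    tie-break) and keep a SNP only if it is more than ``window_bp`` away
    from, and has r^2 <= ``r2_max`` with, every already-kept SNP.

    r^2 is the squared Pearson correlation of expected coded-allele dosages;
    without a genotype panel only the distance rule applies.
    """
    if candidates.empty:
        out = candidates.copy()
        out["lead"] = pd.Series(dtype=bool)
        return out
    ordered = candidates.sort_values(
        ["p", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    doses = {}
    if panel is not None:
        for rec in panel:
            if rec.snp_id in set(ordered["snp_id"]):
                doses[rec.snp_id] = rec.dosage()
    kept: list[dict] = []
    lead_flags = []
    for _, r in ordered.iterrows():
        ok = True
        for k in kept:
            same_chrom = str(r["chrom"]) == str(k["chrom"])
            if same_chrom and abs(int(r["pos"]) - int(k["pos"])) <= window_bp:
                ok = False
                break
            if (
                r["snp_id"] in doses
                and k["snp_id"] in doses
                and _r2(doses[r["snp_id"]], doses[k["snp_id"]]) > r2_max
            ):
                ok = False
                break
        lead_flags.append(ok)
        if ok:
            kept.append(r)
    ordered["lead"] = lead_flags
    return ordered


def effective_tests(R: np.ndarray, var_explained: float = 0.995) -> int:
    """Effective number of independent tests: the smallest k such that the
    top-k eigenvalues of the correlation matrix explain ``var_explained`` of
    its trace (the simpleM procedure)."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    eig = np.linalg.eigvalsh(R)[::-1]
    eig = np.clip(eig, 0.0, None)
    trace = np.trace(R)
    # relative tolerance so exact-boundary cases (cumsum == target in real
    # arithmetic) are not pushed one eigenvalue further by rounding
    target = var_explained * trace - 1e-9 * trace
    cum = np.cumsum(eig)
    return int(np.searchsorted(cum, target) + 1)
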