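"""Readers and writers for the external file formats.

Canonical in-memory containers:

* genotypes -- :class:`GenotypePanel`, a sample list plus a sequence of
  :class:`GenotypeRecord`; each record stores per-individual genotype
  probability triples ``(pAA, pAB, pBB)`` aligned to the sample list.
  Hard calls are degenerate triples; missing genotypes are NaN rows.
* phenotypes -- a :class:`pandas.DataFrame` with columns
  ``iid, sex, age, trait`` (plus ``residual`` once prepared).
* pedigrees -- a :class:`pandas.DataFrame` with columns
  ``fid, iid, father_iid, mother_iid, sex`` (missing parents as NA).

Coordinates are 1-based as in VCF; imprinted-region intervals are read from
BED (0-based, half-open) and kept in that convention internally.
The coded allele is always ``allele_B`` (the VCF ALT / TSV A2 column);
all effect signs refer to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeRecord",
    "GenotypePanel",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "read_phenotypes",
    "read_pedigree",
    "read_intervals",
    "write_summary_stats",
    "read_summary_stats",
]

_PROB_SUM_TOL = 1e-3

DEFAULT_SEX_MAP = {
    "male": "male",
    "female": "female",
    "m": "male",
    "f": "female",
    "1": "male",
    "2": "female",
}


@dataclass
class GenotypeRecord:
    """One bi-allelic SNP with per-individual genotype probability triples.

    ``probs`` has shape ``(n_samples, 3)`` holding ``(pAA, pAB, pBB)`` for the
    reference allele A and coded allele B.  Missing genotypes are rows of NaN,
    never silent ``(0, 0, 0)``.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_A: str
    allele_B: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError(f"{self.snp_id}: probs must have shape (n, 3)")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        ok = ~np.isnan(self.probs).any(axis=1)
        sums = self.probs[ok].sum(axis=1)
        if ok.any() and np.abs(sums - 1.0).max() > 1e-6 + _PROB_SUM_TOL:
            raise ValueError(f"{self.snp_id}: probability triples do not sum to 1")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.probs).any(axis=1)

    def dosage(self) -> np.ndarray:
        """Expected coded-allele dosage pAB + 2*pBB (NaN where missing)."""
        return self.probs[:, 1] + 2.0 * self.probs[:, 2]

    def hard_calls(self, threshold: float = 0.0) -> np.ndarray:
        """Max-probability genotype (0/1/2 coded-allele count), -1 = missing.

        With ``threshold`` > 0 a call is made only when the winning
        probability reaches the threshold (used for trio genotypes).
        """
        calls = np.full(self.probs.shape[0], -1, dtype=int)
        ok = ~self.missing
        if ok.any():
            best = np.argmax(self.probs[ok], axis=1)
            pbest = self.probs[ok][np.arange(best.size), best]
            best = np.where(pbest >= threshold, best, -1)
            calls[ok] = best
        return calls


@dataclass
class GenotypePanel:
    """Sample list plus SNP records, preserving input sample order."""

    samples: list[str]
    records: list[GenotypeRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, snp_id: str) -> GenotypeRecord:
        for rec in self.records:
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypePanel":
        idx = [self.samples.index(s) for s in keep]
        recs = [
            GenotypeRecord(r.snp_id, r.chrom, r.pos, r.allele_A, r.allele_B,
                           r.probs[idx])
            for r in self.records
        ]
        return GenotypePanel(list(keep), recs)


def _triple_from_gt(a0: int, a1: int) -> np.ndarray:
    if a0 < 0 or a1 < 0:
        return np.full(3, np.nan)
    n_alt = int(a0 > 0) + int(a1 > 0)
    t = np.zeros(3)
    t[n_alt] = 1.0
    return t


def _read_vcf(path: str | Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[GenotypeRecord] = []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        alt = var.ALT[0] if var.ALT else "."
        gp = var.format("GP")
        if gp is not None:
            probs = np.asarray(gp, dtype=float)
            bad = ~np.isnan(probs).any(axis=1) & (
                np.abs(probs.sum(axis=1) - 1.0) > _PROB_SUM_TOL
            )
            if bad.any():
                warnings.warn(
                    f"{snp_id}: {int(bad.sum())} GP triple(s) do not sum to 1; "
                    "flagged missing"
                )
                probs[bad] = np.nan
        else:
            try:
                gts = var.genotypes  # [a0, a1, phased] per sample
            except Exception:  # GT absent from FORMAT
                gts = None
            ds = var.format("DS")
            if gts is not None:
                probs = np.vstack([_triple_from_gt(g[0], g[1]) for g in gts])
            else:
                probs = np.full((len(samples), 3), np.nan)
            if ds is not None and np.isnan(probs).any():
                # DS-only entries: p(AB) is unrecoverable from dosage unless
                # the dosage is a hard 0/1/2; anything else stays missing.
                ds = np.asarray(ds, dtype=float).ravel()
                miss = np.isnan(probs).any(axis=1)
                for i in np.where(miss)[0]:
                    d = ds[i]
                    if np.isfinite(d) and float(d) in (0.0, 1.0, 2.0):
                        t = np.zeros(3)
                        t[int(d)] = 1.0
                        probs[i] = t
                    elif np.isfinite(d):
                        warnings.warn(
                            f"{snp_id}: non-integer DS without GP/GT left missing"
                        )
        records.append(
            GenotypeRecord(snp_id, str(var.CHROM), int(var.POS), var.REF, alt, probs)
        )
    return GenotypePanel(samples, records)


def _parse_triple(tok: str, path: str, lineno: int) -> np.ndarray:
    if tok in (".", "NA", ""):
        return np.full(3, np.nan)
    parts = tok.split(",")
    if len(parts) != 3:
        raise ValueError(
            f"{path}, line {lineno}: expected 'pAA,pAB,pBB' or '.', got {tok!r}"
        )
    try:
        t = np.array([float(p) for p in parts])
    except ValueError as exc:
        raise ValueError(f"{path}, line {lineno}: unparseable triple {tok!r}") from exc
    if abs(t.sum() - 1.0) > _PROB_SUM_TOL:
        warnings.warn(f"{path}, line {lineno}: triple sums to {t.sum():g}; flagged missing")
        return np.full(3, np.nan)
    return t


def _read_dosage_tsv(path: str | Path) -> GenotypePanel:
    path = str(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["SNP", "CHR", "POS", "A1", "A2"]:
            raise ValueError(
                f"{path}, line 1: header must start with SNP CHR POS A1 A2"
            )
        samples = header[5:]
        records = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != 5 + len(samples):
                raise ValueError(
                    f"{path}, line {lineno}: expected {5 + len(samples)} fields, "
                    f"got {len(toks)}"
                )
            probs = np.vstack(
                [_parse_triple(t, path, lineno) for t in toks[5:]]
            )
            records.append(
                GenotypeRecord(toks[0], toks[1], int(toks[2]), toks[3], toks[4], probs)
            )
    return GenotypePanel(samples, records)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypePanel:
    """Read genotypes from a VCF (GT/GP/DS FORMAT fields) or a dosage TSV.

    ``format`` is inferred from the filename when not given (``.vcf``/
    ``.vcf.gz`` -> vcf, otherwise dosage_tsv).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if ".vcf" in path.name else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as a probability TSV; round-trips bitwise via repr()."""
    with open(path, "w") as fh:
        fh.write("\t".join(["SNP", "CHR", "POS", "A1", "A2"] + panel.samples) + "\n")
        for rec in panel:
            cells = []
            for row in rec.probs:
                if np.isnan(row).any():
                    cells.append(".")
                else:
                    cells.append(",".join(repr(float(v)) for v in row))
            fh.write(
                "\t".join(
                    [rec.snp_id, rec.chrom, str(rec.pos), rec.allele_A, rec.allele_B]
                    + cells
                )
                + "\n"
            )


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed VCF 4.2 with GT:GP per sample."""
    chroms = []
    for rec in panel:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description='
            '"Genotype probabilities">\n'
        )
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples) + "\n"
        )
        for rec in panel:
            cells = []
            for row in rec.probs:
                if np.isnan(row).any():
                    cells.append("./.:.,.,.")
                    continue
                gt = ("0/0", "0/1", "1/1")[int(np.argmax(row))]
                cells.append(gt + ":" + ",".join(f"{v:.6f}" for v in row))
            fh.write(
                "\t".join(
                    [rec.chrom, str(rec.pos), rec.snp_id, rec.allele_A,
                     rec.allele_B, ".", "PASS", ".", "GT:GP"] + cells
                )
                + "\n"
            )


def read_phenotypes(
    path: str | Path,
    iid_col: str = "iid",
    sex_col: str = "sex",
    age_col: str = "age",
    trait_col: str = "trait",
    sex_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a phenotype TSV into the canonical iid/sex/age/trait table.

    Rows with missing trait are retained (NaN) so downstream steps can decide;
    duplicate iids and unmappable sex codes are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={iid_col: str})
    for col in (iid_col, sex_col, age_col, trait_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.rename(
        columns={iid_col: "iid", sex_col: "sex", age_col: "age", trait_col: "trait"}
    )
    dup = df["iid"][df["iid"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicated iid(s): {sorted(set(dup))}")
    mapping = {k.lower(): v for k, v in (sex_map or DEFAULT_SEX_MAP).items()}
    raw_sex = df["sex"].astype(str).str.strip().str.lower()
    # integer-valued floats like "1.0" map through their integer code
    raw_sex = raw_sex.str.replace(r"\.0$", "", regex=True)
    mapped = raw_sex.map(mapping)
    bad = sorted(set(raw_sex[mapped.isna() & raw_sex.notna()]))
    if bad:
        raise ValueError(f"{path}: unparseable sex value(s): {bad}")
    df["sex"] = pd.Categorical(mapped, categories=["male", "female"])
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["trait"] = pd.to_numeric(df["trait"], errors="coerce")
    if ((df["age"] <= 0) & df["age"].notna()).any():
        raise ValueError(f"{path}: ages must be positive where present")
    df["trait_missing"] = df["trait"].isna()
    return df.reset_index(drop=True)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a FAM-style pedigree: FID IID PAT MAT SEX [PHENO], whitespace-split.

    '0', '.', 'NA' parent ids are treated as missing.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 5:
                raise ValueError(f"{path}, line {lineno}: expected >= 5 fields")
            fid, iid, pat, mat, sex = toks[:5]
            rows.append(
                {
                    "fid": fid,
                    "iid": iid,
                    "father_iid": None if pat in ("0", ".", "NA") else pat,
                    "mother_iid": None if mat in ("0", ".", "NA") else mat,
                    "sex": {"1": "male", "2": "female"}.get(sex, None),
                }
            )
    ped = pd.DataFrame(rows)
    if ped["iid"].duplicated().any():
        raise ValueError(f"{path}: duplicated individual ids in pedigree")
    self_parent = (ped["iid"] == ped["father_iid"]) | (ped["iid"] == ped["mother_iid"])
    if self_parent.any():
        raise ValueError(f"{path}: individual listed as its own parent")
    return ped


def read_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read BED intervals (0-based, half-open) into chrom -> [(start, end)]."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise ValueError(f"{path}, line {lineno}: expected chrom start end")
            try:
                start, end = int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}, line {lineno}: end < start")
            out.setdefault(toks[0].removeprefix("chr"), []).append((start, end))
    return out


_SUMMARY_COLS = [
    "SNP", "CHR", "POS", "A1", "A2", "MAF", "N_HOM", "N_HET",
    "VAR_AA", "VAR_AB", "VAR_BB", "BETA_BF", "SE_BF", "P_POE",
]


def write_summary_stats(results: Iterable, path: str | Path) -> None:
    """Write per-SNP variance-test summary statistics as TSV (6 sig. digits)."""
    rows = []
    for r in results:
        rows.append(
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "POS": r.pos,
                "A1": r.allele_A,
                "A2": r.allele_B,
                "MAF": r.maf,
                "N_HOM": r.n_hom_eff,
                "N_HET": r.n_het_eff,
                "VAR_AA": r.var_AA,
                "VAR_AB": r.var_AB,
                "VAR_BB": r.var_BB,
                "BETA_BF": r.b,
                "SE_BF": r.se,
                "P_POE": r.p,
            }
        )
    if not rows:
        raise ValueError("no results to write")
    df = pd.DataFrame(rows, columns=_SUMMARY_COLS)
    float_cols = df.columns.difference(["SNP", "CHR", "POS", "A1", "A2"])
    for c in float_cols:
        df[c] = df[c].map(lambda v: f"{v:.6g}" if pd.notna(v) else "NA")
    df.to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in _SUMMARY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    return df
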