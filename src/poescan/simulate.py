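"""Synthetic cohorts and trio panels under the parent-of-origin model.

The generative model mirrors the mixture interpretation of the POE test:
paternal and maternal alleles are drawn independently Bernoulli(p) (HWE),
and the phenotype is

    y = mu_AA + beta_pat * X_pat + beta_mat * X_mat
        + beta_age * age + beta_age2 * age^2 + beta_sex * 1[male]
        + Normal(0, sigma^2),

where X_pat/X_mat are the paternal/maternal coded-allele counts.  When
beta_pat = -beta_mat the homozygote means coincide (polar overdominance) and
the only footprint of the SNP is the inflated heterozygote variance
(beta_pat - beta_mat)^2 / 4.

Imputation uncertainty is emulated by blending the true genotype's
degenerate probability triple with the HWE prior at weight (1 - info); this
keeps E[p(AB)] calibrated and lets tests sweep imputation quality.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from poescan.io_formats import (
    GenotypePanel,
    GenotypeRecord,
    write_vcf,
)

__all__ = [
    "CohortSimConfig",
    "SimTruth",
    "TrioPanel",
    "simulate_cohort",
    "simulate_null_record",
    "build_suite",
    "simulate_trios",
    "make_fixtures",
]


@dataclass
class CohortSimConfig:
    """Study conditions for one simulated cohort of unrelated individuals.

    Defaults describe a mid-sized GWAS cohort with a polar-overdominant SNP
    whose parental-effect difference matches the variance signal seen at the
    discovery stage of a BMI-scale trait (delta ~ 0.6 SD, i.e. a het-hom
    variance excess of ~0.09 on a unit-variance phenotype); covariate
    coefficients add the mild age/sex structure the preparation step is
    expected to remove.
    """

    n: int = 20_000
    maf: float = 0.3
    beta_pat: float = 0.31
    beta_mat: float = -0.31
    sigma: float = 1.0
    mu_AA: float = 0.0
    beta_age: float = 0.02
    beta_age2: float = -0.0002
    beta_sex: float = 0.1
    age_range: tuple[float, float] = (30.0, 70.0)
    info: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.info <= 1.0:
            raise ValueError("info must be in (0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated SNP: per-individual parental alleles."""

    paternal: np.ndarray
    maternal: np.ndarray
    config: CohortSimConfig

    @property
    def genotype(self) -> np.ndarray:
        return self.paternal + self.maternal


def _blend_probs(genotype: np.ndarray, maf: float, info: float) -> np.ndarray:
    onehot = np.zeros((genotype.size, 3))
    onehot[np.arange(genotype.size), genotype] = 1.0
    q = 1.0 - maf
    prior = np.array([q**2, 2 * maf * q, maf**2])
    return info * onehot + (1.0 - info) * prior[None, :]


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[GenotypeRecord, pd.DataFrame, SimTruth]:
    """Simulate one SNP and the phenotype it influences in an unrelated
    cohort; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pat = (rng.random(config.n) < config.maf).astype(int)
    mat = (rng.random(config.n) < config.maf).astype(int)
    age = rng.uniform(*config.age_range, size=config.n)
    male = rng.random(config.n) < 0.5
    noise = rng.normal(0.0, config.sigma, size=config.n)
    trait = (
        config.mu_AA
        + config.beta_pat * pat
        + config.beta_mat * mat
        + config.beta_age * age
        + config.beta_age2 * age**2
        + config.beta_sex * male
        + noise
    )
    genotype = pat + mat
    probs = _blend_probs(genotype, config.maf, config.info)
    rec = GenotypeRecord(
        snp_id="snp_causal", chrom="1", pos=1_000_000,
        allele_A="A", allele_B="B", probs=probs,
    )
    pheno = pd.DataFrame(
        {
            "iid": [f"I{i:06d}" for i in range(config.n)],
            "sex": pd.Categorical(
                np.where(male, "male", "female"), categories=["male", "female"]
            ),
            "age": age,
            "trait": trait,
        }
    )
    return rec, pheno, SimTruth(paternal=pat, maternal=mat, config=config)


def simulate_null_record(
    n: int, maf: float, rng: np.random.Generator,
    snp_id: str, chrom: str = "2", pos: int = 1, info: float = 1.0,
) -> GenotypeRecord:
    """A genotype record with no phenotype effect (HWE at ``maf``)."""
    g = rng.binomial(2, maf, size=n)
    return GenotypeRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, allele_A="A", allele_B="B",
        probs=_blend_probs(g, maf, info),
    )


@dataclass
class TrioPanel:
    """Pedigree-linked genotypes and offspring phenotypes for PAT testing."""

    panel: GenotypePanel
    pedigree: pd.DataFrame
    pheno: pd.DataFrame
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_trios(
    n_families: int,
    maf: float = 0.3,
    beta_pat: float = 0.055,
    beta_mat: float = -0.055,
    sigma: float = 1.0,
    seed: int = 0,
    snp_id: str = "snp_trio",
    mu_AA: float = 0.0,
    beta_age: float = 0.02,
    beta_age2: float = -0.0002,
    beta_sex: float = 0.1,
    age_range: tuple[float, float] = (20.0, 50.0),
) -> TrioPanel:
    """Simulate trios: HWE parents, uniform transmission, POE phenotype.

    All randomness comes from one uniform block with a fixed per-family
    layout, so growing ``n_families`` never reshuffles earlier families.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n_families, 9))
    fa = (u[:, 0:2] < maf).astype(int)  # father's two alleles (B=1)
    mo = (u[:, 2:4] < maf).astype(int)
    t_fa = (u[:, 4] < 0.5).astype(int)  # which paternal allele is transmitted
    t_mo = (u[:, 5] < 0.5).astype(int)
    x_pat = fa[np.arange(n_families), t_fa]
    x_mat = mo[np.arange(n_families), t_mo]
    male = u[:, 6] < 0.5
    age = age_range[0] + u[:, 7] * (age_range[1] - age_range[0])
    noise = ndtri(np.clip(u[:, 8], 1e-12, 1 - 1e-12)) * sigma
    trait = (
        mu_AA + beta_pat * x_pat + beta_mat * x_mat
        + beta_age * age + beta_age2 * age**2 + beta_sex * male + noise
    )

    fids = [f"F{i:05d}" for i in range(n_families)]
    off_iid = [f"{f}_o" for f in fids]
    fa_iid = [f"{f}_f" for f in fids]
    mo_iid = [f"{f}_m" for f in fids]
    samples = fa_iid + mo_iid + off_iid
    geno = np.concatenate([fa.sum(axis=1), mo.sum(axis=1), x_pat + x_mat])
    probs = np.zeros((geno.size, 3))
    probs[np.arange(geno.size), geno] = 1.0
    panel = GenotypePanel(
        samples,
        [GenotypeRecord(snp_id, "1", 1_000_000, "A", "B", probs)],
    )
    pedigree = pd.DataFrame(
        {
            "fid": fids,
            "iid": off_iid,
            "father_iid": fa_iid,
            "mother_iid": mo_iid,
            "sex": np.where(male, "male", "female"),
        }
    )
    pheno = pd.DataFrame(
        {
            "iid": off_iid,
            "sex": pd.Categorical(
                np.where(male, "male", "female"), categories=["male", "female"]
            ),
            "age": age,
            "trait": trait,
        }
    )
    truth = pd.DataFrame(
        {"fid": fids, "iid": off_iid, "x_pat": x_pat, "x_mat": x_mat}
    )
    return TrioPanel(panel=panel, pedigree=pedigree, pheno=pheno, truth=truth)


def _write_pheno(pheno: pd.DataFrame, path: Path) -> None:
    pheno[["iid", "sex", "age", "trait"]].to_csv(path, sep="\t", index=False)


def _write_fam(pedigree: pd.DataFrame, parents: list[str], path: Path) -> None:
    with open(path, "w") as fh:
        for _, r in pedigree.iterrows():
            sex_code = {"male": "1", "female": "2"}.get(r["sex"], "0")
            fh.write(
                f"{r['fid']} {r['iid']} {r['father_iid'] or '0'} "
                f"{r['mother_iid'] or '0'} {sex_code} -9\n"
            )
        for p in parents:
            fid = p.rsplit("_", 1)[0]
            sex_code = "1" if p.endswith("_f") else "2"
            fh.write(f"{fid} {p} 0 0 {sex_code} -9\n")


_SUITES = ("tiny", "null", "poe", "gxe", "transform")


def build_suite(
    suite: str, seed: int = 0
) -> tuple[GenotypePanel, pd.DataFrame, CohortSimConfig]:
    """Build one named test scenario in memory.

    * ``tiny``  -- 50 individuals, 3 SNPs; exercises the parsers.
    * ``null``  -- no genetic effect; for calibration checks.
    * ``poe``   -- one planted polar-overdominant SNP among null SNPs.
    * ``gxe``   -- phenotypic variance scales with allelic dosage.
    * ``transform`` -- additive SNP observed on an exponentiated scale.

    Returns ``(panel, phenotypes, config)``; the planted SNP is always
    ``snp_causal``.
    """
    if suite not in _SUITES:
        raise ValueError(f"suite must be one of {_SUITES}")
    rng = np.random.default_rng(seed + 1)

    if suite == "tiny":
        cfg = CohortSimConfig(n=50, maf=0.4, beta_pat=0.3, beta_mat=-0.3, seed=seed)
    elif suite == "null":
        cfg = CohortSimConfig(n=2_000, beta_pat=0.0, beta_mat=0.0, seed=seed)
    elif suite == "poe":
        cfg = CohortSimConfig(n=20_000, seed=seed)
    elif suite == "gxe":
        cfg = CohortSimConfig(n=10_000, beta_pat=0.0, beta_mat=0.0, seed=seed)
    else:  # transform
        cfg = CohortSimConfig(
            n=10_000, beta_pat=0.25, beta_mat=0.25, sigma=0.5, mu_AA=1.0, seed=seed
        )

    rec, pheno, truth = simulate_cohort(cfg)
    if suite == "gxe":
        # variance grows with dosage: sd = sqrt(1 + 0.3 * dose)
        dose = truth.genotype
        resid = pheno["trait"] - pheno["trait"].mean()
        pheno = pheno.copy()
        pheno["trait"] = (
            pheno["trait"].mean() + resid * np.sqrt(1.0 + 0.3 * dose)
        )
    if suite == "transform":
        pheno = pheno.copy()
        pheno["trait"] = np.exp(pheno["trait"])

    n_null = {"tiny": 2, "null": 10, "poe": 50, "gxe": 5, "transform": 5}[suite]
    records = [rec]
    for j in range(n_null):
        records.append(
            simulate_null_record(
                cfg.n, maf=float(rng.uniform(0.1, 0.5)), rng=rng,
                snp_id=f"snp_null{j:03d}", chrom=str(2 + j % 10),
                pos=1_000_000 + 10_000_000 * (j // 10),
            )
        )
    panel = GenotypePanel([f"I{i:06d}" for i in range(cfg.n)], records)
    return panel, pheno, cfg


def make_fixtures(out_dir: str | Path, suite: str = "tiny", seed: int = 0) -> dict:
    """Write a self-describing fixture set (VCF + phenotype TSV + FAM +
    key:value truth sidecar) for one of the :func:`build_suite` scenarios."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, pheno, cfg = build_suite(suite, seed=seed)
    n_null = len(panel) - 1

    vcf_path = out / "cohort.vcf"
    pheno_path = out / "pheno.tsv"
    write_vcf(panel, vcf_path)
    _write_pheno(pheno, pheno_path)

    paths = {"vcf": str(vcf_path), "pheno": str(pheno_path)}
    if suite == "tiny":
        trios = simulate_trios(10, maf=0.4, seed=seed)
        write_vcf(trios.panel, out / "trios.vcf")
        _write_pheno(trios.pheno, out / "trios_pheno.tsv")
        parents = [s for s in trios.panel.samples if not s.endswith("_o")]
        _write_fam(trios.pedigree, parents, out / "trios.fam")
        paths.update(
            {
                "trios_vcf": str(out / "trios.vcf"),
                "trios_pheno": str(out / "trios_pheno.tsv"),
                "fam": str(out / "trios.fam"),
            }
        )

    with open(out / "truth.txt", "w") as fh:
        fh.write(f"suite: {suite}\n")
        for k, v in asdict(cfg).items():
            fh.write(f"{k}: {json.dumps(v)}\n")
        fh.write(f"n_null_snps: {n_null}\n")
        fh.write("causal_snp: snp_causal\n")
    paths["truth"] = str(out / "truth.txt")
    return paths
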