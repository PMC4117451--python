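import numpy as np
import pandas as pd
import pytest

from poescan.io_formats import GenotypePanel, GenotypeRecord
from poescan.scan_meta import (
    effective_tests,
    meta_fixed,
    meta_scan,
    prepare_phenotype,
    prune_leads,
    run_scan,
    se_from_beta_p,
    select_candidates,
)
from poescan.simulate import CohortSimConfig, simulate_cohort

from conftest import hwe_probs


def _pheno(n, rng, trait=None, age=None):
    age = rng.uniform(30, 70, n) if age is None else age
    trait = rng.normal(size=n) if trait is None else trait
    return pd.DataFrame(
        {
            "iid": [f"I{i}" for i in range(n)],
            "sex": pd.Categorical(
                np.where(rng.random(n) < 0.5, "male", "female"),
                categories=["male", "female"],
            ),
            "age": age,
            "trait": trait,
        }
    )


class TestPreparePhenotype:
    def test_age_independent_trait_left_nearly_unchanged(self, rng):
        df = _pheno(2000, rng)
        out = prepare_phenotype(df)
        for _, grp in out.groupby("sex", observed=True):
            r = np.corrcoef(grp["trait"], grp["residual"])[0, 1]
            assert r > 0.999

    def test_residuals_orthogonal_to_age_terms(self, rng):
        n = 1500
        age = rng.uniform(30, 70, n)
        trait = 2 + 0.1 * age + 0.01 * age**2 + rng.normal(size=n)
        out = prepare_phenotype(_pheno(n, rng, trait=trait, age=age))
        for _, grp in out.groupby("sex", observed=True):
            a = grp["age"].to_numpy()
            res = grp["residual"].to_numpy()
            assert abs(np.corrcoef(a, res)[0, 1]) < 1e-10
            assert abs(np.corrcoef(a**2, res)[0, 1]) < 1e-10

    def test_standardisation_contract(self, rng):
        out = prepare_phenotype(_pheno(800, rng))
        for _, grp in out.groupby("sex", observed=True):
            res = grp["residual"].to_numpy()
            assert abs(res.mean()) < 1e-12
            assert abs(res.var(ddof=1) - 1.0) < 1e-12

    def test_small_stratum_dropped(self, rng):
        df = _pheno(200, rng)
        df.loc[df["sex"] == "male", "sex"] = "female"
        df.iloc[0, df.columns.get_loc("sex")] = "male"
        out = prepare_phenotype(df)
        assert out.loc[out["sex"] == "male", "residual"].isna().all()


class TestRunScan:
    def _panel(self, rng, n=600, n_snps=4):
        recs = [
            GenotypeRecord(
                f"s{j}", "1", 1000 * (j + 1), "A", "B",
                hwe_probs(rng.binomial(2, 0.3, size=n)),
            )
            for j in range(n_snps)
        ]
        return GenotypePanel([f"I{i}" for i in range(n)], recs)

    def test_row_bookkeeping_and_reasons(self, rng):
        panel = self._panel(rng)
        # one monomorphic SNP should be skipped with a reason
        panel.records[0].probs[:] = [1.0, 0.0, 0.0]
        prep = prepare_phenotype(_pheno(600, rng))
        scan = run_scan(panel, prep, min_het_eff=10)
        assert len(scan) == 4 * 2
        assert set(scan.loc[scan["snp_id"] == "s0", "reason"]) == {"n_het_eff"}
        assert (scan.loc[scan["snp_id"] != "s0", "reason"] == "ok").all()

    def test_sample_order_invariance(self, rng):
        panel = self._panel(rng)
        prep = prepare_phenotype(_pheno(600, rng))
        scan1 = run_scan(panel, prep, min_het_eff=10)
        perm = rng.permutation(len(prep))
        scan2 = run_scan(panel, prep.iloc[perm].reset_index(drop=True),
                         min_het_eff=10)
        pd.testing.assert_frame_equal(
            scan1.sort_values(["snp_id", "stratum"]).reset_index(drop=True),
            scan2.sort_values(["snp_id", "stratum"]).reset_index(drop=True),
        )

    def test_no_overlap_is_an_error(self, rng):
        panel = self._panel(rng)
        prep = prepare_phenotype(_pheno(600, rng))
        prep["iid"] = "X" + prep["iid"]
        with pytest.raises(ValueError, match="no overlap"):
            run_scan(panel, prep)

    def test_sex_combined_meta_beats_single_stratum(self):
        """Combining the two sex strata of the same POE signal gives a
        smaller median P than either stratum alone."""
        ps_meta, ps_single = [], []
        for seed in range(16):
            cfg = CohortSimConfig(n=8000, beta_pat=0.31, beta_mat=-0.31,
                                  seed=seed)
            rec, pheno, _ = simulate_cohort(cfg)
            panel = GenotypePanel(list(pheno["iid"]), [rec])
            prep = prepare_phenotype(pheno)
            scan = run_scan(panel, prep, min_het_eff=10)
            meta = meta_scan(scan)
            ps_meta.append(meta["p"].iloc[0])
            ps_single.append(
                scan.loc[scan["stratum"] == "female", "p"].iloc[0]
            )
        assert np.median(ps_meta) < np.median(ps_single)


class TestMetaFixed:
    def test_single_study_identity(self):
        m = meta_fixed([0.2], [0.05])
        assert m.beta == pytest.approx(0.2, rel=1e-12)
        assert m.se == pytest.approx(0.05, rel=1e-12)

    def test_equal_ses_give_arithmetic_mean(self):
        m = meta_fixed([0.1, 0.3, 0.2], [0.05, 0.05, 0.05])
        assert m.beta == pytest.approx(0.2)

    def test_k_identical_studies_shrink_se_by_sqrt_k(self):
        k = 7
        m = meta_fixed([0.2] * k, [0.06] * k)
        assert m.se == pytest.approx(0.06 / np.sqrt(k), rel=1e-12)

    def test_replicated_snp_per_study_rows_combine_to_0_11(self):
        """Published per-study paternal-minus-maternal differences combine
        to the 0.11 SD replication estimate."""
        betas = [0.012, 0.064, 0.24, 0.007, 0.135]
        pvals = [8.81e-1, 5.62e-1, 1.48e-4, 9.31e-1, 1.89e-1]
        ses = [se_from_beta_p(b, p) for b, p in zip(betas, pvals)]
        m = meta_fixed(betas, ses)
        assert m.beta == pytest.approx(0.11, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="matching lengths"):
            meta_fixed([0.1, 0.2], [0.1])


class TestSelectCandidates:
    REGIONS = {"8": [(140_400_000, 140_700_000)], "16": [(3_000_000, 3_500_000)]}

    def _meta(self):
        return pd.DataFrame(
            {
                "snp_id": ["gw_hit", "imp_hit", "both_hit", "null"],
                "chrom": ["20", "16", "8", "3"],
                "pos": [44_859_324, 3_686_241, 140_588_522, 1_000],
                "p": [4.70e-6, 1.69e-4, 9.34e-7, 0.2],
            }
        )

    def test_paper_style_criteria(self):
        cand = select_candidates(self._meta(), self.REGIONS)
        crit = dict(zip(cand["snp_id"], cand["criterion"]))
        assert crit == {"gw_hit": "genomewide", "imp_hit": "imprinted",
                        "both_hit": "both"}

    def test_strict_inequality_at_threshold(self):
        meta = self._meta()
        meta.loc[0, "p"] = 5e-6  # exactly at the boundary
        cand = select_candidates(meta, self.REGIONS)
        assert "gw_hit" not in set(cand["snp_id"])

    def test_monotone_in_p(self):
        meta = self._meta()
        base = set(select_candidates(meta, self.REGIONS)["snp_id"])
        meta["p"] = meta["p"] / 10
        lowered = set(select_candidates(meta, self.REGIONS)["snp_id"])
        assert base <= lowered


class TestPruneLeads:
    def _cand(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "p"])

    def test_single_candidate_survives(self):
        out = prune_leads(self._cand([("a", "1", 100, 1e-8)]))
        assert out["lead"].tolist() == [True]

    def test_window_rule(self):
        out = prune_leads(
            self._cand([("a", "1", 1_000_000, 1e-8), ("b", "1", 1_500_000, 1e-6)])
        )
        assert dict(zip(out["snp_id"], out["lead"])) == {"a": True, "b": False}

    def test_distant_uncorrelated_snps_both_survive(self, rng):
        n = 500
        g1 = rng.binomial(2, 0.3, size=n)
        g2 = rng.binomial(2, 0.3, size=n)
        panel = GenotypePanel(
            [f"I{i}" for i in range(n)],
            [
                GenotypeRecord("a", "1", 1_000_000, "A", "B", hwe_probs(g1)),
                GenotypeRecord("b", "1", 3_000_000, "A", "B", hwe_probs(g2)),
            ],
        )
        r2 = np.corrcoef(g1, g2)[0, 1] ** 2
        assert r2 < 0.1  # independent draws
        out = prune_leads(
            self._cand([("a", "1", 1_000_000, 1e-8), ("b", "1", 3_000_000, 1e-6)]),
            panel,
        )
        assert out["lead"].all()

    def test_ld_rule_drops_correlated_snp(self, rng):
        n = 500
        g1 = rng.binomial(2, 0.3, size=n)
        g2 = g1.copy()
        flip = rng.random(n) < 0.02
        g2[flip] = rng.binomial(2, 0.3, size=flip.sum())
        panel = GenotypePanel(
            [f"I{i}" for i in range(n)],
            [
                GenotypeRecord("a", "1", 1_000_000, "A", "B", hwe_probs(g1)),
                GenotypeRecord("b", "2", 1_000_000, "A", "B", hwe_probs(g2)),
            ],
        )
        out = prune_leads(
            self._cand([("a", "1", 1_000_000, 1e-8), ("b", "2", 1_000_000, 1e-6)]),
            panel,
        )
        assert dict(zip(out["snp_id"], out["lead"])) == {"a": True, "b": False}

    def test_input_order_does_not_matter(self):
        rows = [("b", "1", 1_500_000, 1e-6), ("a", "1", 1_000_000, 1e-8),
                ("c", "2", 1_000_000, 1e-7)]
        out1 = prune_leads(self._cand(rows))
        out2 = prune_leads(self._cand(rows[::-1]))
        pd.testing.assert_frame_equal(out1, out2)


class TestEffectiveTests:
    def test_identity_matrix(self):
        assert effective_tests(np.eye(100)) == 100

    def test_perfect_ld(self):
        assert effective_tests(np.ones((40, 40))) == 1

    def test_block_diagonal_matches_eigen_oracle(self):
        from scipy.linalg import eigh

        blocks = [np.full((10, 10), 0.9) + 0.1 * np.eye(10) for _ in range(10)]
        R = np.zeros((100, 100))
        for i, b in enumerate(blocks):
            R[i * 10:(i + 1) * 10, i * 10:(i + 1) * 10] = b
        # independent oracle: dense symmetric eigensolver + explicit scan
        # exact-arithmetic oracle: each block has one eigenvalue 9.1 and
        # nine eigenvalues 0.1, so 10*9.1 + k'*0.1 >= 99.5 first at k' = 85,
        # i.e. 95 components explain 99.5% of the trace
        w = sorted(eigh(R, eigvals_only=True), reverse=True)
        assert np.allclose(sorted(w, reverse=True)[:10], 9.1)
        assert effective_tests(R, var_explained=0.995) == 95

    def test_non_symmetric_rejected(self):
        R = np.eye(5)
        R[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            effective_tests(R)
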