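"""Score construction: threshold sums, allele alignment, PRS-PC, PCs, residualization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from trionurture import pgs, simtrio as st


def _sumstats(rows):
    return pd.DataFrame(rows, columns=["SNP", "A1", "A2", "BETA", "SE", "P", "FRQ"])


def _panel(vids, counted, matrix, other=None):
    vids = np.array(vids, dtype=object)
    matrix = np.asarray(matrix, dtype=np.int8)
    return pgs.DosagePanel(
        ids=np.array([f"i{k}" for k in range(matrix.shape[0])], dtype=object),
        variant_id=vids,
        counted_allele=np.array(counted, dtype=object),
        other_allele=np.array(other if other else [""] * len(vids), dtype=object),
        matrix=np.asarray(matrix, dtype=np.int8),
    )


class TestReadSumstats:
    def test_well_formed_roundtrip(self, tmp_path):
        df = _sumstats(
            [
                ["rs1", "A", "G", 0.5, 0.1, 1e-9, 0.3],
                ["rs2", "C", "T", -0.2, 0.1, 0.01, 0.4],
                ["rs3", "G", "A", 0.1, 0.1, 0.5, 0.2],
            ]
        )
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        out = pgs.read_sumstats(p)
        assert list(out["SNP"]) == ["rs1", "rs2", "rs3"]
        assert not out["ambiguous"].any()

    def test_rejects_pvalue_above_one(self, tmp_path):
        df = _sumstats([["rs1", "A", "G", 0.5, 0.1, 1.2, 0.3]])
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="rs1"):
            pgs.read_sumstats(p)

    def test_rejects_duplicate_ids(self, tmp_path):
        df = _sumstats(
            [["rs1", "A", "G", 0.5, 0.1, 0.1, 0.3], ["rs1", "C", "T", 0.2, 0.1, 0.2, 0.4]]
        )
        p = tmp_path / "ss.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            pgs.read_sumstats(p)

    def test_column_map_and_ambiguous_flag(self, tmp_path):
        raw = pd.DataFrame(
            {
                "rsid": ["rs1", "rs2"],
                "ea": ["A", "C"],
                "oa": ["T", "T"],
                "effect": [0.5, 0.2],
                "pval": [0.01, 0.02],
            }
        )
        p = tmp_path / "ss.tsv"
        raw.to_csv(p, sep="\t", index=False)
        out = pgs.read_sumstats(
            p, column_map={"SNP": "rsid", "A1": "ea", "A2": "oa", "BETA": "effect", "P": "pval"}
        )
        assert list(out["ambiguous"]) == [True, False]


class TestThresholdScores:
    def test_single_variant_hand_sum(self):
        panel = _panel(["rs1"], ["A"], [[0], [1], [2]])
        ss = _sumstats([["rs1", "A", "G", 0.5, 0.1, 0.01, 0.3]])
        mat = pgs.compute_threshold_scores(panel, ss, thresholds=[1.0])
        np.testing.assert_allclose(mat.raw_scores[:, 0], [0.0, 0.5, 1.0])

    def test_threshold_excludes_weak_variants(self):
        # p = (1e-9, 0.01, 0.5): at threshold 0.05 only the first two count
        panel = _panel(["rs1", "rs2", "rs3"], ["A", "C", "G"], [[1, 2, 2], [2, 0, 1]])
        ss = _sumstats(
            [
                ["rs1", "A", "T", 0.5, 0.1, 1e-9, 0.3],
                ["rs2", "C", "T", -0.3, 0.1, 0.01, 0.3],
                ["rs3", "G", "A", 1.0, 0.1, 0.5, 0.3],
            ]
        )
        mat = pgs.compute_threshold_scores(panel, ss, thresholds=[0.05, 1.0])
        np.testing.assert_allclose(
            mat.raw_scores[:, 0], [0.5 * 1 - 0.3 * 2, 0.5 * 2 - 0.3 * 0]
        )
        np.testing.assert_allclose(
            mat.raw_scores[:, 1], [0.5 - 0.6 + 2.0, 1.0 + 0.0 + 1.0]
        )
        assert list(mat.n_variants_used) == [2, 3]

    def test_allele_alignment_flip(self):
        # genotype file counts A2: dosage becomes 2 - d before weighting
        aligned = _panel(["rs1", "rs2"], ["A", "C"], [[0, 2], [1, 1]])
        flipped = _panel(["rs1", "rs2"], ["G", "T"], [[2, 0], [1, 1]])
        ss = _sumstats(
            [["rs1", "A", "G", 0.5, 0.1, 0.01, 0.3], ["rs2", "C", "T", -0.3, 0.1, 0.01, 0.3]]
        )
        a = pgs.compute_threshold_scores(aligned, ss, thresholds=[1.0])
        b = pgs.compute_threshold_scores(flipped, ss, thresholds=[1.0])
        np.testing.assert_allclose(a.raw_scores, b.raw_scores)

    def test_unmatchable_variant_dropped(self):
        panel = _panel(["rs1", "rs2"], ["A", "C"], [[1, 2]])
        ss = _sumstats(
            [["rs1", "A", "G", 0.5, 0.1, 0.01, 0.3], ["rs2", "G", "T", 9.9, 0.1, 0.01, 0.3]]
        )
        mat = pgs.compute_threshold_scores(panel, ss, thresholds=[1.0])
        np.testing.assert_allclose(mat.raw_scores[:, 0], [0.5])

    def test_empty_intersection_is_error(self):
        panel = _panel(["rsX"], ["A"], [[1]])
        ss = _sumstats([["rs1", "A", "G", 0.5, 0.1, 0.01, 0.3]])
        with pytest.raises(ValueError, match="shared"):
            pgs.compute_threshold_scores(panel, ss, thresholds=[1.0])

    def test_scoring_linearity(self, rng):
        panel = _panel(
            ["rs1", "rs2", "rs3"],
            ["A", "C", "G"],
            rng.integers(0, 3, size=(6, 3)),
        )
        base = [["rs1", "A", "T", 0.5, 0.1, 0.01, 0.3],
                ["rs2", "C", "T", -0.3, 0.1, 0.01, 0.3],
                ["rs3", "G", "A", 0.2, 0.1, 0.01, 0.3]]
        ss1 = _sumstats(base)
        ss2 = _sumstats([[r[0], r[1], r[2], 2 * r[3], r[4], r[5], r[6]] for r in base])
        ss3 = _sumstats([[r[0], r[1], r[2], 3 * r[3], r[4], r[5], r[6]] for r in base])
        s1 = pgs.compute_threshold_scores(panel, ss1, [1.0]).raw_scores
        s2 = pgs.compute_threshold_scores(panel, ss2, [1.0]).raw_scores
        s3 = pgs.compute_threshold_scores(panel, ss3, [1.0]).raw_scores
        np.testing.assert_allclose(s1 + s2, s3, atol=1e-12)


class TestPrsPc:
    def test_identical_columns_rank_one(self, rng):
        x = rng.normal(size=200)
        comp, _ = pgs.prs_pc(np.column_stack([x, x, x]))
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(comp, z, atol=1e-10)

    def test_two_column_closed_form(self, rng):
        # analytic eigenvectors of a 2x2 correlation matrix: (1,1)/sqrt(2),
        # leading eigenvalue 1 + r
        x = rng.normal(size=3000)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.normal(size=3000)
        raw = np.column_stack([x, y])
        comp, load = pgs.prs_pc(raw)
        np.testing.assert_allclose(load, [1 / np.sqrt(2)] * 2, atol=1e-10)
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        r = float(np.mean(zx * zy))
        expected = (zx + zy) / np.sqrt(2)
        assert abs(np.var(expected) - (1 + r)) < 1e-10
        np.testing.assert_allclose(comp, expected / expected.std(), atol=1e-8)

    def test_beta_negation_equivariance(self, rng):
        raw = rng.normal(size=(100, 4)) + rng.normal(size=(100, 1))
        comp, _ = pgs.prs_pc(raw)
        comp_neg, _ = pgs.prs_pc(-raw)
        np.testing.assert_allclose(comp_neg, -comp, atol=1e-8)

    def test_affine_invariance_of_columns(self, rng):
        raw = rng.normal(size=(150, 3)) + rng.normal(size=(150, 1))
        comp, _ = pgs.prs_pc(raw)
        scaled = raw * np.array([2.0, 0.5, 10.0]) + np.array([1.0, -3.0, 7.0])
        comp2, _ = pgs.prs_pc(scaled)
        np.testing.assert_allclose(comp, comp2, atol=1e-8)

    def test_all_constant_columns_error(self):
        with pytest.raises(ValueError, match="constant"):
            pgs.prs_pc(np.ones((10, 3)))

    def test_sign_convention_nonnegative_with_mean(self, rng):
        raw = rng.normal(size=(300, 5)) + 2 * rng.normal(size=(300, 1))
        comp, _ = pgs.prs_pc(raw)
        z = (raw - raw.mean(0)) / raw.std(0)
        assert np.corrcoef(comp, z.mean(axis=1))[0, 1] >= 0


class TestAncestryPcs:
    def test_matches_dense_svd_oracle(self, rng):
        x = rng.integers(0, 3, size=(5, 10)).astype(float)
        pcs = pgs.compute_ancestry_pcs(x, k=2)
        sds = x.std(0)
        z = (x[:, sds > 0] - x[:, sds > 0].mean(0)) / sds[sds > 0]
        u, s, _ = np.linalg.svd(z)
        for j in range(2):
            assert min(
                np.abs(pcs[:, j] - u[:, j]).max(), np.abs(pcs[:, j] + u[:, j]).max()
            ) < 1e-10

    def test_orthonormal(self, rng):
        x = rng.integers(0, 3, size=(50, 30)).astype(float)
        pcs = pgs.compute_ancestry_pcs(x, k=5)
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(5), atol=1e-10)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            pgs.compute_ancestry_pcs(rng.integers(0, 3, size=(5, 10)), k=5)

    def test_pc1_separates_strongly_diverged_demes(self):
        cfg = st.SimConfig(
            n_trios=1500, n_snps=400, n_demes=2, deme_fst_like=0.2, seed=71
        )
        co = st.simulate_cohort(cfg)
        pcs = pgs.compute_ancestry_pcs(co.mother, k=2)
        r = np.corrcoef(pcs[:, 0], co.deme)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_population_no_separation(self):
        cfg = st.SimConfig(n_trios=1500, n_snps=400, seed=72)
        co = st.simulate_cohort(cfg)
        pcs = pgs.compute_ancestry_pcs(co.mother, k=1)
        # no structure: PC1 correlates with any random split only at noise level
        rng = np.random.default_rng(72)
        fake = rng.integers(0, 2, size=co.n_trios)
        assert abs(np.corrcoef(pcs[:, 0], fake)[0, 1]) < 0.1


class TestResidualize:
    def test_orthogonal_covariate_is_zscore(self, rng):
        score = rng.normal(size=4000)
        cov = pd.DataFrame({"x": rng.normal(size=4000)})
        out = pgs.residualize_standardize(score, cov)
        z = (score - score.mean()) / score.std()
        # orthogonal projection removes almost nothing
        assert np.corrcoef(out, z)[0, 1] > 0.999

    def test_output_uncorrelated_with_covariates(self, rng):
        score = rng.normal(size=500)
        cov = pd.DataFrame(
            {
                "pc1": 0.5 * score + rng.normal(size=500),
                "batch": rng.choice(["a", "b", "c"], size=500),
            }
        )
        out = pgs.residualize_standardize(score, cov)
        assert abs(np.corrcoef(out, cov["pc1"])[0, 1]) < 1e-10
        for level in ("a", "b", "c"):
            ind = (cov["batch"] == level).astype(float)
            assert abs(np.corrcoef(out, ind)[0, 1]) < 1e-10
        assert abs(out.mean()) < 1e-12 and abs(out.std() - 1) < 1e-12

    def test_idempotent(self, rng):
        score = rng.normal(size=300)
        cov = pd.DataFrame({"x": 0.7 * score + rng.normal(size=300)})
        once = pgs.residualize_standardize(score, cov)
        twice = pgs.residualize_standardize(once, cov)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_fully_explained_score_degenerate(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="degenerate"):
            pgs.residualize_standardize(2 * x + 1, pd.DataFrame({"x": x}))

    def test_singleton_batch_level_merged(self, rng):
        score = rng.normal(size=50)
        batch = np.array(["a"] * 25 + ["b"] * 24 + ["z"])
        out = pgs.residualize_standardize(score, pd.DataFrame({"batch": batch}))
        assert np.isfinite(out).all()

    def test_incomplete_covariates_rejected(self, rng):
        score = rng.normal(size=10)
        cov = pd.DataFrame({"x": [np.nan] + [1.0] * 9})
        with pytest.raises(ValueError, match="complete"):
            pgs.residualize_standardize(score, cov)


@settings(max_examples=20, deadline=None)
@given(seed=hst.integers(0, 10_000))
def test_allele_flip_involution_property(seed):
    """Recoding every variant to count the other allele leaves scores unchanged."""
    rng = np.random.default_rng(seed)
    n, m = 8, 5
    mat = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    a1 = np.array(["A", "C", "G", "T", "A"], dtype=object)
    a2 = np.array(["G", "T", "A", "C", "C"], dtype=object)
    vids = [f"rs{i}" for i in range(m)]
    ss = pd.DataFrame(
        {"SNP": vids, "A1": a1, "A2": a2, "BETA": rng.normal(size=m), "P": rng.uniform(0.001, 1, size=m)}
    )
    p1 = pgs.DosagePanel(
        ids=np.arange(n), variant_id=np.array(vids, dtype=object),
        counted_allele=a1.copy(), other_allele=a2.copy(), matrix=mat,
    )
    p2 = pgs.DosagePanel(
        ids=np.arange(n), variant_id=np.array(vids, dtype=object),
        counted_allele=a2.copy(), other_allele=a1.copy(), matrix=(2 - mat).astype(np.int8),
    )
    s1 = pgs.compute_threshold_scores(p1, ss, [0.5, 1.0]).raw_scores
    s2 = pgs.compute_threshold_scores(p2, ss, [0.5, 1.0]).raw_scores
    np.testing.assert_allclose(s1, s2, atol=1e-12)
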