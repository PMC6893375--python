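"""Genotype I/O, distance/LD primitives, map interpolation and GRMs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wildintro as wi
from wildintro.ld import _corr_columns

from conftest import tiny_geno


class TestHamming:
    def test_forced_by_definition(self):
        assert wi.hamming_distance((0, 2, 1), (2, 2, 0)) == 3

    def test_identity(self):
        v = np.array([0, 1, 2, 1, 0])
        assert wi.hamming_distance(v, v) == 0

    def test_matches_loop_oracle(self, rng):
        a = rng.integers(0, 3, size=50).astype(float)
        b = rng.integers(0, 3, size=50).astype(float)
        expected = sum(abs(x - y) for x, y in zip(a, b))
        assert wi.hamming_distance(a, b) == expected

    def test_missing_skipped_and_rounding(self):
        a = np.array([0.4, np.nan, 1.6])
        b = np.array([1.0, 2.0, 2.0])
        # round(0.4)=0 vs 1 -> 1; nan skipped; round(1.6)=2 vs 2 -> 0
        assert wi.hamming_distance(a, b) == 1

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            wi.hamming_distance([0, 1], [0, 1, 2])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_metric_properties(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = (r.integers(0, 3, size=20).astype(float) for _ in range(3))
        dab = wi.hamming_distance(a, b)
        assert dab == wi.hamming_distance(b, a)
        assert dab <= wi.hamming_distance(a, c) + wi.hamming_distance(c, b)

    def test_matrix_agrees_with_scalar(self, rng):
        A = rng.integers(0, 3, size=(4, 30)).astype(float)
        B = rng.integers(0, 3, size=(3, 30)).astype(float)
        D = wi.hamming_distance_matrix(A, B)
        for i in range(4):
            for j in range(3):
                assert D[i, j] == wi.hamming_distance(A[i], B[j])


class TestPairwiseR2:
    def test_self_and_complement(self, rng):
        x = rng.integers(0, 3, size=(30, 1)).astype(float)
        g = tiny_geno(np.hstack([x, 2 - x]))
        r2 = wi.pairwise_r2(g, [0], [0, 1])
        assert r2[0, 0] == pytest.approx(1.0)
        assert r2[0, 1] == pytest.approx(1.0)  # perfect negative correlation squared

    def test_matches_formula_oracle(self, rng):
        X = rng.uniform(0, 2, size=(25, 10))
        g = tiny_geno(X)
        r2 = wi.pairwise_r2(g, list(range(10)), list(range(10)))
        for i in range(10):
            for j in range(10):
                assert r2[i, j] == pytest.approx(np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2)

    def test_monomorphic_yields_missing(self, rng):
        X = np.column_stack([np.full(20, 1.0), rng.uniform(0, 2, 20)])
        r2 = wi.pairwise_r2(tiny_geno(X), [0], [1])
        assert np.isnan(r2[0, 0])


class TestLdPrune:
    def test_duplicates_collapse(self, rng):
        x = rng.integers(0, 3, size=(40, 1)).astype(float)
        y = rng.integers(0, 3, size=(40, 1)).astype(float)
        g = tiny_geno(np.hstack([x, x, y]))
        kept = wi.ld_prune(g, window=3, step=1, r2_max=0.3)
        assert 0 in kept and 1 not in kept

    def test_uncorrelated_all_kept(self):
        X = np.kron(np.eye(4), np.ones((5, 1))) * 2  # orthogonal indicator columns
        g = tiny_geno(X)
        kept = wi.ld_prune(g, window=4, step=2, r2_max=0.99)
        assert len(kept) == 4

    def test_matches_exhaustive_scan_oracle(self, rng):
        # correlated block: haplotype-structured sites
        base = rng.integers(0, 3, size=(60, 1)).astype(float)
        X = np.clip(base + rng.normal(0, 0.7, size=(60, 200)), 0, 2)
        g = tiny_geno(X)
        kept = wi.ld_prune(g, window=50, step=10, r2_max=0.3)

        # independent oracle: same greedy rule, plain loops
        keep = np.ones(200, bool)
        starts = list(range(0, 151, 10))
        for s in starts:
            win = [i for i in range(s, min(s + 50, 200)) if keep[i]]
            for ii, i in enumerate(win):
                if not keep[i]:
                    continue
                for j in win[ii + 1:]:
                    if not keep[j]:
                        continue
                    r = np.corrcoef(X[:, i], X[:, j])[0, 1]
                    if np.isfinite(r) and r**2 > 0.3:
                        keep[j] = False
        assert list(kept) == list(np.flatnonzero(keep))

    def test_no_retained_pair_above_threshold(self, rng):
        base = rng.integers(0, 3, size=(50, 1)).astype(float)
        X = np.clip(base + rng.normal(0, 0.5, size=(50, 80)), 0, 2)
        g = tiny_geno(X)
        kept = wi.ld_prune(g, window=30, step=5, r2_max=0.4)
        r2 = _corr_columns(X[:, kept], X[:, kept]) ** 2
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if kept[b] - kept[a] < 30:  # within any possible shared window
                    assert not (np.isfinite(r2[a, b]) and r2[a, b] > 0.4 + 1e-12)


class TestInterpolate:
    def _map(self):
        return wi.GeneticMap(
            anchors=pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "pos": [1_000_000, 3_000_000], "cM": [0.0, 10.0]}
            )
        )

    def test_midpoint_anchor_and_clamp(self):
        sites = pd.DataFrame({"chrom": "chr1", "pos": [2_000_000, 1_000_000, 500_000, 9_999_999]})
        cm = wi.interpolate_cM(self._map(), sites)
        assert cm[0] == pytest.approx(5.0)
        assert cm[1] == pytest.approx(0.0)
        assert cm[2] == pytest.approx(0.0)  # clamped before first anchor
        assert cm[3] == pytest.approx(10.0)  # clamped after last anchor

    def test_missing_chromosome_raises(self):
        with pytest.raises(ValueError, match="chr9"):
            wi.interpolate_cM(self._map(), pd.DataFrame({"chrom": ["chr9"], "pos": [1]}))

    def test_monotone_in_position(self, rng):
        pos = np.sort(rng.integers(1, 4_000_000, size=50))
        cm = wi.interpolate_cM(self._map(), pd.DataFrame({"chrom": "chr1", "pos": pos}))
        assert (np.diff(cm) >= -1e-12).all()


class TestGrm:
    def test_duplicated_sample_offdiag_equals_diag(self, rng):
        X = rng.integers(0, 3, size=(5, 40)).astype(float)
        X[1] = X[0]
        K = wi.make_grm(tiny_geno(X)).K
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_hand_computed_small_matrix(self):
        X = np.array(
            [[0, 1, 2, 1, 0], [2, 1, 0, 1, 2], [1, 1, 1, 0, 2]], dtype=float
        )
        X = X[:, X.var(axis=0) > 0]  # monomorphic columns are dropped
        p = X.mean(axis=0) / 2
        W = X - 2 * p
        expected = W @ W.T / (2 * np.sum(p * (1 - p)))
        K = wi.make_grm(tiny_geno(X)).K
        assert np.allclose(K, expected)

    def test_weight_scale_invariance(self, rng):
        X = rng.integers(0, 3, size=(8, 30)).astype(float)
        g = tiny_geno(X)
        w = rng.uniform(0.1, 2.0, size=30)
        assert np.allclose(wi.make_grm(g, weights=w).K, wi.make_grm(g, weights=7.3 * w).K)

    def test_all_monomorphic_raises(self):
        with pytest.raises(ValueError):
            wi.make_grm(tiny_geno(np.ones((4, 5))))

    def test_diag_mean_near_one_outbred(self, rng):
        p = rng.uniform(0.05, 0.95, size=5000)
        X = rng.binomial(2, p, size=(200, 5000)).astype(float)
        K = wi.make_grm(tiny_geno(X)).K
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.05)


class TestOffdiagCorrelation:
    def test_self_and_negation(self, rng):
        A = rng.normal(size=(10, 10))
        K = wi.KinshipMatrix(samples=[f"s{i}" for i in range(10)], K=A @ A.T)
        Kneg = wi.KinshipMatrix(samples=K.samples, K=-K.K)
        assert wi.offdiag_correlation(K, K) == pytest.approx(1.0)
        assert wi.offdiag_correlation(K, Kneg) == pytest.approx(-1.0)

    def test_matches_flatten_oracle(self, rng):
        A = rng.normal(size=(20, 25))
        B = rng.normal(size=(20, 25))
        ids = [f"s{i}" for i in range(20)]
        K1 = wi.KinshipMatrix(samples=ids, K=A @ A.T)
        K2 = wi.KinshipMatrix(samples=ids, K=B @ B.T)
        iu = np.triu_indices(20, 1)
        assert wi.offdiag_correlation(K1, K2) == pytest.approx(
            np.corrcoef(K1.K[iu], K2.K[iu])[0, 1]
        )

    def test_sample_mismatch_raises(self, rng):
        K1 = wi.KinshipMatrix(samples=["a", "b"], K=np.eye(2))
        K2 = wi.KinshipMatrix(samples=["b", "a"], K=np.eye(2))
        with pytest.raises(ValueError):
            wi.offdiag_correlation(K1, K2)


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


class TestIO:
    def test_vcf_gt_and_ds(self, tmp_path):
        body = (
            "chr1\t100\tv1\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\n"
            "chr1\t200\tv2\tA\tG\t.\t.\t.\tGT:DS\t0/1:1.37\t0/0:0.02\n"
            "chr1\t300\tv3\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\n"
            "chr1\t400\tv4\tA\tG\t.\t.\t.\tGT\t./.\t1/1\n"
        )
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_HEADER + body)
        g = wi.read_genotypes(str(path))
        assert g.samples == ["S1", "S2"]
        assert list(g.sites["id"]) == ["v1", "v2", "v4"]  # triallelic skipped
        assert g.dosage[0, 0] == 1.0 and g.dosage[1, 0] == 2.0  # from GT
        assert g.dosage[0, 1] == pytest.approx(1.37)  # DS passthrough
        assert np.isnan(g.dosage[0, 2]) and g.dosage[1, 2] == 2.0

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            wi.read_genotypes("/nonexistent.vcf")

    def test_dosage_tsv_roundtrip(self, tmp_path, rng):
        g = tiny_geno(rng.uniform(0, 2, size=(4, 6)))
        path = tmp_path / "dose.tsv"
        wi.write_dosage_tsv(g, str(path))
        g2 = wi.read_genotypes(str(path), format="tsv")
        assert g2.samples == g.samples
        assert np.allclose(g2.dosage, g.dosage)
        assert list(g2.sites["pos"]) == list(g.sites["pos"])

    def test_grm_roundtrip(self, tmp_path, rng):
        X = rng.integers(0, 3, size=(6, 25)).astype(float)
        k = wi.make_grm(tiny_geno(X))
        wi.write_grm(k, str(tmp_path / "grm.tsv"))
        k2 = wi.read_grm(str(tmp_path / "grm.tsv"))
        assert k2.samples == k.samples
        assert np.allclose(k2.K, k.K)

    def test_doseglaz_writers(self, tmp_path):
        g = tiny_geno(np.array([[2.0, 0.0], [1.0, 1.0]]), spacing=300_000)
        dose = wi.window_dosage(g, width=250_000)
        wi.write_doseglaz_tsv(dose, str(tmp_path / "dose.tsv"))
        back = pd.read_csv(tmp_path / "dose.tsv", sep="\t", index_col=0)
        assert list(back.index) == dose.samples
        wi.write_doseglaz_bedgraph(dose, dose.samples[0], str(tmp_path / "d.bg"))
        lines = (tmp_path / "d.bg").read_text().strip().split("\n")
        assert len(lines) == np.isfinite(dose.values[0]).sum()
        first_finite = int(np.flatnonzero(np.isfinite(dose.values[0]))[0])
        chrom, start, end, val = lines[0].split("\t")
        assert int(start) == int(dose.windows["start"].iloc[first_finite]) - 1

    def test_genetic_map_reader(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("chrom\tpos\tcM\nchr1\t100\t0.0\nchr1\t2000\t1.5\n")
        gmap = wi.read_genetic_map(str(path))
        assert gmap.chroms() == ["chr1"]
        assert gmap.anchors["cM"].iloc[-1] == 1.5
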