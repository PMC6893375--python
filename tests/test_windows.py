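"""Windowed dosage maps, introgression summaries, PCA, load, recombination."""

import numpy as np
import pandas as pd
import pytest

import wildintro as wi

from conftest import tiny_geno


def _recoded_idm_geno(sim):
    idm = sim["idm_table"]
    return sim["recoded"].take_sites(idm["site_index"].to_numpy())


class TestWindowDosage:
    def test_simple_means(self):
        g = tiny_geno(np.array([[2, 2, 2, 2], [0, 1, 0, 1]]), spacing=10)
        dose = wi.window_dosage(g, width=250_000)
        assert dose.values[0, 0] == pytest.approx(2.0)
        assert dose.values[1, 0] == pytest.approx(0.5)
        assert dose.windows["n_idm"].iloc[0] == 4

    def test_no_sites_raises(self):
        g = tiny_geno(np.zeros((1, 1))).take_sites([])
        with pytest.raises(ValueError):
            wi.window_dosage(g)

    def test_bounds_and_proportion_identity(self, sim_small):
        geno = _recoded_idm_geno(sim_small)
        dose = wi.window_dosage(geno)
        vals = dose.values[np.isfinite(dose.values)]
        assert vals.min() >= 0 and vals.max() <= 2
        # weighted window mean recovers the individual proportion exactly
        n = dose.windows["n_idm"].to_numpy(dtype=float)
        prop = wi.individual_proportion(geno)
        with np.errstate(invalid="ignore"):
            recon = np.nansum(dose.values * n[None, :], axis=1) / (2 * n.sum())
        assert np.allclose(recon, prop.to_numpy(), atol=1e-12)

    def test_windows_match_ancestry_truth(self, sim_small):
        """Noiseless DoseGlaz tracks the true local wild-haplotype count."""
        geno = _recoded_idm_geno(sim_small)
        dose = wi.window_dosage(geno)
        idm_idx = sim_small["idm_table"]["site_index"].to_numpy()
        anc = sim_small["truth"].ancestry[:, idm_idx].astype(float)
        truth_dose = wi.window_dosage(
            wi.GenotypeMatrix(samples=geno.samples, sites=geno.sites.copy(), dosage=anc)
        )
        ok = np.isfinite(dose.values) & np.isfinite(truth_dose.values)
        # strict sites equal ancestry exactly; wild-private sites only carry
        # the diagnostic allele on a subset of wild haplotypes
        mae = np.abs(dose.values[ok] - truth_dose.values[ok]).mean()
        assert mae < 0.35
        strict_idx = np.flatnonzero(
            (sim_small["idm_table"]["idm_class"] == "strict").to_numpy()
        )
        g_strict = geno.take_sites(strict_idx)
        assert np.array_equal(g_strict.dosage, anc[:, strict_idx])


class TestProportions:
    def test_individual_proportion_cases(self):
        g = tiny_geno(np.array([[2, 2, 2, 2], [1, 1, 2, 0], [0, 0, 0, 0]]))
        prop = wi.individual_proportion(g)
        assert list(prop) == [1.0, 0.5, 0.0]

    def test_homozygosity_cases(self):
        g = tiny_geno(np.array([[2, 2, 0, 0], [1, 1, 1, 1], [1.96, 0, 0, 0]]))
        rate = wi.homozygosity_rate(g)
        assert rate.iloc[0] == 0.5
        assert rate.iloc[1] == 0.0
        assert rate.iloc[2] == 0.25  # 1.96 rounds to 2

    def test_empty_region_warns_missing(self):
        g = tiny_geno(np.array([[1, 1]]), spacing=100)
        region = wi.RegionSpec("chr9", 1, 10, "nowhere")
        assert wi.individual_proportion(g, region).isna().all()


class TestPopulationCompare:
    def test_identical_clones_group_mean(self):
        g = tiny_geno(np.array([[1, 1], [1, 1]]))
        pops = pd.Series("P1", index=g.samples)
        out = wi.population_compare(g, pops, {"genome": None})
        assert out["mean_proportion"].iloc[0] == pytest.approx(0.5)

    def test_doubled_frequency_between_generations(self, rng):
        base = rng.binomial(2, 0.1, size=(60, 200)).astype(float)
        doubled = rng.binomial(2, 0.2, size=(60, 200)).astype(float)
        g = tiny_geno(np.vstack([base, doubled]))
        pops = pd.Series(["G1"] * 60 + ["G2"] * 60, index=g.samples)
        out = wi.population_compare(g, pops, {"genome": None}).set_index("population")
        ratio = out.loc["G2", "mean_proportion"] / out.loc["G1", "mean_proportion"]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_exclusion_removes_outlier(self):
        g = tiny_geno(np.array([[0, 0], [0, 0], [2, 2]]))
        pops = pd.Series("P", index=g.samples)
        out = wi.population_compare(g, pops, {"genome": None}, exclude=[g.samples[2]])
        assert out["mean_proportion"].iloc[0] == 0.0
        assert out["n"].iloc[0] == 2

    def test_unknown_sample_raises(self):
        g = tiny_geno(np.zeros((2, 2)))
        pops = pd.Series("P", index=["nope"])
        with pytest.raises(ValueError):
            wi.population_compare(g, pops, {"genome": None})


class TestPca:
    def test_duplicated_samples_identical_scores(self, rng):
        X = rng.integers(0, 3, size=(10, 40)).astype(float)
        X[3] = X[0]
        scores, *_ = wi.pca(tiny_geno(X))
        assert np.allclose(scores[0], scores[3])

    def test_variance_explained_spectral_identity(self, rng):
        X = rng.integers(0, 3, size=(12, 30)).astype(float)
        _, _, ve, _ = wi.pca(tiny_geno(X), n_components=30)
        assert ve.sum() <= 1 + 1e-9

    def test_matches_svd_oracle_up_to_sign(self, rng):
        X = rng.uniform(0, 2, size=(20, 50))
        scores, loadings, _, kept = wi.pca(tiny_geno(X), maf_min=0.0)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        U, S, Vt = np.linalg.svd(Z[:, kept] if kept.size < 50 else Z, full_matrices=False)
        ref = U * S
        for k in range(3):
            assert np.allclose(np.abs(scores[:, k]), np.abs(ref[:, k]), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = rng.uniform(0, 2, size=(15, 25))
        _, loadings, _, _ = wi.pca(tiny_geno(X))
        for k in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, k])), k] > 0

    def test_region_loadings_dominate_pc1(self, sim_small):
        """With one cohort segregating for introgressions, the diagnostic-set
        PC1 loads most heavily on markers inside the introgressed regions."""
        geno = _recoded_idm_geno(sim_small)
        scores, loadings, ve, kept = wi.pca(geno)
        inside = wi.region_mask(geno.sites.iloc[kept], sim_small["cfg"].regions)
        assert inside.any() and (~inside).any()
        assert np.abs(loadings[inside, 0]).mean() > np.abs(loadings[~inside, 0]).mean()


class TestLoad:
    def test_simple_counts(self):
        g = tiny_geno(np.array([[1, 2, 0]]))
        out = wi.genetic_load(g, {"genome": None})
        assert out["total_load"].iloc[0] == 3
        assert out["hom_load"].iloc[0] == 1

    def test_all_zero(self):
        g = tiny_geno(np.zeros((2, 3)))
        out = wi.genetic_load(g, {"genome": None})
        assert (out["total_load"] == 0).all() and (out["hom_load"] == 0).all()

    def test_region_excess_under_enrichment(self, sim_small):
        """Load seeded preferentially on introgressed haplotypes shows up as
        a higher per-site load rate inside the regions than genome-wide."""
        cfg, truth, geno = sim_small["cfg"], sim_small["truth"], sim_small["geno"]
        dele = wi.simulate_deleterious(cfg, truth, geno, n_del=500,
                                       base_rate=0.05, enrichment=4.0)
        regions = {"genome": None}
        for r in cfg.regions:
            regions[r.label] = r
        out = wi.genetic_load(dele, regions, populations=truth.generation)
        region_rate = out.groupby("region")["total_load"].mean()
        n_per_region = {
            "genome": dele.n_sites,
            **{r.label: int(r.contains(dele.sites["chrom"].to_numpy(),
                                       dele.sites["pos"].to_numpy()).sum())
               for r in cfg.regions},
        }
        rates = {k: region_rate[k] / max(n_per_region[k], 1) for k in n_per_region}
        assert max(rates["chr1_distal"], rates["chr4_core"]) > rates["genome"]
        assert "group_change" in out.attrs


class TestRecombinationDensity:
    def _uniform_map(self, rate=1.0, length=10_000_000):
        pos = np.arange(1, length + 2, 500_000)
        return wi.GeneticMap(
            anchors=pd.DataFrame({"chrom": "chr1", "pos": pos, "cM": (pos - 1) / 1e6 * rate})
        )

    def test_uniform_map_zero_reduction(self):
        gmap = self._uniform_map()
        _, out = wi.recombination_density(gmap, [wi.RegionSpec("chr1", 1, 3_000_001, "r")])
        assert out["pct_reduction"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_flat_region_full_reduction(self):
        pos = np.array([1, 2_000_000, 4_000_000, 6_000_000, 8_000_000, 10_000_000])
        cm = np.array([0.0, 2.0, 2.0, 2.0, 4.0, 6.0])  # flat between 2 and 6 Mb
        gmap = wi.GeneticMap(anchors=pd.DataFrame({"chrom": "chr1", "pos": pos, "cM": cm}))
        _, out = wi.recombination_density(
            gmap, [wi.RegionSpec("chr1", 2_000_001, 6_000_001, "flat")]
        )
        assert out["pct_reduction"].iloc[0] == pytest.approx(100.0, abs=0.01)

    def test_suppressed_region_reduction(self):
        """Region with 0.29x the background rate shows ~71% reduction."""
        pos = np.arange(1, 20_000_002, 1_000_000)
        rate = np.where((pos >= 5_000_001) & (pos < 15_000_001), 0.29, 1.0)
        cm = np.concatenate([[0.0], np.cumsum(np.diff(pos) / 1e6 * rate[:-1])])
        gmap = wi.GeneticMap(anchors=pd.DataFrame({"chrom": "chr1", "pos": pos, "cM": cm}))
        _, out = wi.recombination_density(
            gmap, [wi.RegionSpec("chr1", 5_000_001, 15_000_001, "sup")]
        )
        assert out["pct_reduction"].iloc[0] == pytest.approx(71.0, abs=1.5)


class TestAdvancement:
    def test_flagging_and_join(self):
        hom = pd.Series({"a": 0.8, "b": 0.0, "c": 0.1})
        prop = pd.Series({"a": 0.5, "b": 0.1, "c": 0.2})
        plots = pd.Series({"a": 60, "b": 10, "x": 99})
        out = wi.advancement_summary(hom, prop, plots, threshold=50)
        assert list(out["clone"]) == ["a", "b"]
        assert out.set_index("clone")["advanced"].to_dict() == {"a": True, "b": False}
        assert "c" in out.attrs["unmatched"] and "x" in out.attrs["unmatched"]

    def test_empty_join(self):
        out = wi.advancement_summary(
            pd.Series(dtype=float), pd.Series(dtype=float), pd.Series(dtype=float)
        )
        assert out.empty

    def test_constructed_cohort_exclusion(self, rng):
        """If homozygotes were excluded above threshold, no advanced clone
        is highly homozygous."""
        hom = pd.Series(rng.uniform(0, 1, 100), index=[f"c{i}" for i in range(100)])
        plots = pd.Series(
            np.where(hom > 0.5, rng.integers(1, 40, 100), rng.integers(10, 200, 100)),
            index=hom.index,
        )
        out = wi.advancement_summary(hom, hom / 2, plots, threshold=50)
        assert not (out.loc[out["advanced"], "homozygosity"] > 0.5).any()
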