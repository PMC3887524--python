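"""Generator: catalog composition, planted truth, hybridization structure."""

import numpy as np
import pandas as pd
import pytest

import poiarray as pa
from poiarray.synthetic_data import (
    DEFAULT_ARM_PROPORTIONS, generate_gene_catalog, generate_hybridizations,
    generate_planted_truth, generate_tissue_atlas, _largest_remainder,
)
from poiarray.types import ARMS


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        props = dict(DEFAULT_ARM_PROPORTIONS)
        props["X"] += 0.01
        with pytest.raises(ValueError, match="sum"):
            pa.SimulationConfig(chromosome_proportions=props)

    def test_grid_capacity(self):
        with pytest.raises(ValueError, match="grid capacity"):
            pa.SimulationConfig(n_genes=100, grid_shape=(5, 5))

    @pytest.mark.parametrize("field,value", [
        ("prop_testis_specific", -0.1),
        ("qc_fail_fraction", 1.5),
        ("n_genes", 0),
        ("technical_sd", -1.0),
    ])
    def test_out_of_range_fields(self, field, value):
        with pytest.raises(ValueError):
            pa.SimulationConfig(**{field: value})

    def test_dye_swap_pattern_length(self):
        with pytest.raises(ValueError, match="dye_swap_pattern"):
            pa.SimulationConfig(n_arrays=4, dye_swap_pattern=(1, -1))


class TestGeneCatalog:
    def test_largest_remainder_counts_at_1000(self):
        # frozen from the arm spot counts (2719/2992/3225/3235/3915/98/514
        # of 16,698) under largest-remainder rounding
        cfg = pa.SimulationConfig(n_genes=1000, grid_shape=(32, 32), seed=0)
        cat = generate_gene_catalog(cfg)
        counts = cat["arm"].value_counts()
        expected = {"X": 163, "2L": 179, "2R": 193, "3L": 194,
                    "3R": 234, "4": 6, "Other": 31}
        assert {a: int(counts[a]) for a in ARMS} == expected
        # mapped-only X share reproduces the printed 16.8%
        mapped = sum(v for k, v in expected.items() if k != "Other")
        assert 100.0 * expected["X"] / mapped == pytest.approx(16.8, abs=0.05)

    def test_seed_determinism(self):
        cfg = pa.SimulationConfig(n_genes=500, grid_shape=(23, 23), seed=42)
        a = generate_gene_catalog(cfg)
        b = generate_gene_catalog(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_no_testis_class_when_proportion_zero(self):
        cfg = pa.SimulationConfig(n_genes=500, grid_shape=(23, 23),
                                  prop_testis_specific=0.0)
        cat = generate_gene_catalog(cfg)
        assert (cat["tissue_class"] == "testis").sum() == 0

    def test_every_gene_has_one_arm_and_class(self):
        cfg = pa.SimulationConfig(n_genes=777, grid_shape=(28, 28), seed=3)
        cat = generate_gene_catalog(cfg)
        assert cat["arm"].isin(ARMS).all()
        assert cat["tissue_class"].isin(["testis", "midgut", "none"]).all()
        assert cat["gene_id"].is_unique

    def test_largest_remainder_exact_total(self):
        for n in (7, 100, 999):
            counts = _largest_remainder(n, DEFAULT_ARM_PROPORTIONS, ARMS)
            assert sum(counts.values()) == n


class TestPlantedTruth:
    def test_class_medians_enforced_exactly(self, small_sim):
        truth = small_sim["truth"]
        cfg = small_sim["config"]
        cls = truth.tissue_class
        eff = truth.effects
        assert eff[cls == "testis"].median() == pytest.approx(
            cfg.testis_median_shift, abs=1e-6)
        assert eff[cls == "midgut"].median() == pytest.approx(
            cfg.midgut_median_shift, abs=1e-6)
        assert eff[cls == "none"].median() == pytest.approx(
            cfg.background_shift, abs=1e-6)

    def test_null_effects_zero_median_without_background_shift(self):
        cfg = pa.SimulationConfig(n_genes=900, grid_shape=(30, 30),
                                  background_shift=0.0, seed=9)
        cat = generate_gene_catalog(cfg)
        truth = generate_planted_truth(cat, cfg)
        nulls = truth.effects[truth.tissue_class == "none"]
        assert nulls.median() == pytest.approx(0.0, abs=1e-9)


class TestHybridizations:
    def test_zero_everything_gives_exact_zero_m(self):
        cfg = pa.SimulationConfig(
            n_genes=400, grid_shape=(20, 20), seed=5,
            testis_median_shift=0.0, midgut_median_shift=0.0,
            background_shift=0.0, biological_sd=0.0, technical_sd=0.0,
            dye_bias_amplitude=0.0, spatial_amplitude=0.0,
            qc_fail_fraction=0.0)
        cat = generate_gene_catalog(cfg)
        truth = generate_planted_truth(cat, cfg)
        hybs = generate_hybridizations(cat, truth, cfg)
        for h in hybs:
            m = np.log2(h.spots["fg_median_ch1"] / h.spots["fg_median_ch2"])
            assert np.all(m == 0.0)

    def test_seed_determinism(self, small_sim):
        cfg = small_sim["config"]
        cat2, truth2, _, hybs2 = pa.simulate_experiment(cfg)
        pd.testing.assert_frame_equal(small_sim["catalog"], cat2)
        pd.testing.assert_series_equal(small_sim["truth"].effects,
                                       truth2.effects)
        for a, b in zip(small_sim["hybs"], hybs2):
            pd.testing.assert_frame_equal(a.spots, b.spots)

    def test_dye_swap_pattern_and_batches(self, small_sim):
        hybs = small_sim["hybs"]
        assert [h.orientation for h in hybs] == [1, -1, 1, -1, 1, -1, 1, -1]
        assert len({h.batch for h in hybs}) == 2

    def test_null_genes_dye_swap_mean_near_zero(self):
        # orientation-corrected mean of unaffected genes: |mean| < 3 SE
        cfg = pa.SimulationConfig(n_genes=2000, grid_shape=(45, 45), seed=13,
                                  background_shift=0.0)
        cat = generate_gene_catalog(cfg)
        truth = generate_planted_truth(cat, cfg)
        hybs = generate_hybridizations(cat, truth, cfg)
        null = (truth.tissue_class == "none").to_numpy()
        ms = []
        for h in hybs:
            m = np.log2(h.spots["fg_median_ch1"] / h.spots["fg_median_ch2"])
            ms.append(h.orientation * m.to_numpy())
        corrected = np.mean(ms, axis=0)[null]
        # planted effects still spread per gene; the *mean across genes*
        # should center at zero (dye bias cancels across swapped pairs)
        se = corrected.std(ddof=1) / np.sqrt(null.sum())
        assert abs(corrected.mean()) < 3 * se

    def test_qc_fail_spots_fail_qc(self, small_sim):
        from poiarray.spot_qc import evaluate_spots
        truth, hybs = small_sim["truth"], small_sim["hybs"]
        for j, h in enumerate(hybs):
            decisions = evaluate_spots(h.spots)
            planted_fail = truth.qc_fail.iloc[:, j].to_numpy()
            assert np.array_equal(decisions["passed"].to_numpy(),
                                  ~planted_fail)


class TestTissueAtlas:
    def test_designated_specific_exceed_tau_cutoff(self, small_sim):
        atlas = pa.preprocess_atlas(small_sim["atlas"])
        calls = pa.classify_specific(atlas).set_index("gene_id")
        cat = small_sim["catalog"]
        for cls_name, tissue in (("testis", "testes"),
                                 ("midgut", "adult midgut")):
            genes = cat.loc[cat["tissue_class"] == cls_name, "gene_id"]
            sub = calls.loc[genes]
            recovered = (sub["specific"] & (sub["argmax_tissue"] == tissue))
            assert recovered.mean() >= 0.99

    def test_atlas_seed_determinism(self, small_sim):
        atlas2 = generate_tissue_atlas(small_sim["catalog"],
                                       small_sim["config"])
        pd.testing.assert_frame_equal(small_sim["atlas"].values,
                                      atlas2.values)

    def test_atlas_has_the_twenty_tissues_and_multiprobe_genes(self, small_sim):
        atlas = small_sim["atlas"]
        assert atlas.tissues == list(pa.TISSUES)
        assert len(pa.TISSUES) == 20
        assert atlas.genes.duplicated().any()  # some genes have 2 probe sets
        assert (~atlas.present.to_numpy()).any()  # some absent calls

    def test_empty_catalog_rejected(self, small_sim):
        with pytest.raises(ValueError, match="empty"):
            generate_tissue_atlas(small_sim["catalog"].iloc[:0],
                                  small_sim["config"])
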