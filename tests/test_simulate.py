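import numpy as np
import pandas as pd
import pytest

import plastiqtl as pq
from plastiqtl import simulate
from plastiqtl.simulate import ArchitectureConfig, PlantedArchitecture, PlantedEffect


class TestMakeMap:
    def test_three_markers_on_10cM(self):
        gmap = pq.make_map([10.0], 5.0)
        assert list(gmap.table["position_cM"]) == [0.0, 5.0, 10.0]

    def test_study_layout_marker_counts(self):
        gmap = pq.make_map([100, 70, 80, 80, 100], 1.0)
        counts = gmap.table.groupby("chromosome", sort=False).size()
        assert list(counts) == [101, 71, 81, 81, 101]

    def test_dense_spacing_count_and_monotonicity(self):
        gmap = pq.make_map([100.0], 0.17)
        pos = gmap.positions("1")
        # floor(100/0.17) interior steps + origin + terminal marker
        assert len(pos) == int(np.floor(100 / 0.17)) + 2
        assert (np.diff(pos) > 0).all()
        assert pos[-1] == 100.0

    def test_spacing_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            pq.make_map([10.0], 20.0)


class TestRILGenotypes:
    def test_zero_distance_markers_always_identical(self):
        gmap = pq.make_map([10.0], 5.0)
        # duplicate position: insert marker at same cM via 0-length interval
        table = gmap.table.copy()
        table.loc[len(table)] = {"marker": "dup", "chromosome": "1",
                                 "position_cM": 10.0}
        gmap2 = pq.GeneticMap(table, {"1": 10.0})
        geno = pq.simulate_ril_genotypes(gmap2, 500, seed=0)
        calls = geno.calls.to_numpy()
        assert (calls[:, 2] == calls[:, 3]).all()

    def test_unlinked_chromosomes_co_inherit_at_half(self):
        gmap = pq.make_map([10.0, 10.0], 10.0)
        geno = pq.simulate_ril_genotypes(gmap, 2000, seed=1)
        d = geno.dosage_observed()
        same = float(np.mean(d[:, 0] == d[:, 2]))
        se = np.sqrt(0.25 / 2000)
        assert abs(same - 0.5) < 3 * se

    def test_adjacent_recombination_matches_haldane_waddington(self):
        gmap = pq.make_map([10.0], 10.0)
        geno = pq.simulate_ril_genotypes(gmap, 2000, seed=2)
        d = geno.dosage_observed()
        observed = float(np.mean(d[:, 0] != d[:, 1]))
        R = simulate.ril_R(10.0)
        assert abs(R - 0.15345) < 1e-4  # closed form sanity
        se = np.sqrt(R * (1 - R) / 2000)
        assert abs(observed - R) < 3 * se

    def test_allele_frequency_near_half_everywhere(self, small_map):
        geno = pq.simulate_ril_genotypes(small_map, 1000, seed=3)
        freq = geno.dosage_observed().mean(axis=0)
        se = np.sqrt(0.25 / 1000)
        assert (np.abs(freq - 0.5) < 4 * se).all()

    def test_map_expansion_toward_independence(self):
        gmap = pq.make_map([100.0], 50.0)
        geno = pq.simulate_ril_genotypes(gmap, 4000, seed=4)
        d = geno.dosage_observed()
        recomb = float(np.mean(d[:, 0] != d[:, 2]))  # markers 100 cM apart
        # exact two-step composition of the per-interval transition
        R50 = simulate.ril_R(50.0)
        expected = 2 * R50 * (1 - R50)
        se = np.sqrt(expected * (1 - expected) / 4000)
        assert abs(recomb - expected) < 3 * se
        assert 0.45 < recomb <= 0.5 + 3 * se  # effectively unlinked

    def test_seed_determinism(self, small_map):
        a = pq.simulate_ril_genotypes(small_map, 50, seed=9)
        b = pq.simulate_ril_genotypes(small_map, 50, seed=9)
        pd.testing.assert_frame_equal(a.calls, b.calls)


class TestPlantArchitecture:
    def test_zero_effects(self, small_map):
        cfg = ArchitectureConfig(n_cis=0, n_trans=0, hotspots=[],
                                 opposing_fraction=0.0)
        arch = pq.plant_architecture(small_map, 10, cfg, seed=0)
        assert arch.effects == []

    def test_hotspot_targets_share_one_locus(self, study_map):
        cfg = ArchitectureConfig(n_cis=0, n_trans=0,
                                 hotspots=[("2", 48.0, 200)],
                                 opposing_fraction=0.0)
        arch = pq.plant_architecture(study_map, 300, cfg, seed=1)
        at_locus = [e for e in arch.effects
                    if e.chromosome == "2" and e.position_cM == 48.0]
        assert len(at_locus) == 200
        assert len({e.transcript for e in at_locus}) == 200

    def test_full_opposing_fraction_cancels_per_transcript(self, study_map):
        cfg = ArchitectureConfig(n_cis=0, n_trans=10, hotspots=[],
                                 opposing_fraction=1.0)
        arch = pq.plant_architecture(study_map, 10, cfg, seed=2)
        frame = arch.to_frame()
        sums = frame.groupby("transcript")[
            ["baseline_effect", "interaction_effect"]].sum()
        assert np.allclose(sums.to_numpy(), 0.0)
        assert (frame.groupby("transcript").size() == 2).all()

    def test_deterministic_given_seed(self, study_map):
        cfg = ArchitectureConfig()
        a = pq.plant_architecture(study_map, 50, cfg, seed=3).to_frame()
        b = pq.plant_architecture(study_map, 50, cfg, seed=3).to_frame()
        pd.testing.assert_frame_equal(a, b)


class TestSimulateExpression:
    def _noiseless_arch(self, effects, positions):
        tx = pd.DataFrame(positions)
        return PlantedArchitecture(effects, [], tx, baseline_mean=8.0,
                                   noise_sd=0.0, replicate_sd=0.0)

    def test_no_effects_no_noise_gives_baseline(self, small_map,
                                                small_genotypes):
        arch = self._noiseless_arch(
            [], [{"transcript": "T1", "chromosome": "1", "position_cM": 5.0}])
        ds = pq.simulate_expression(small_genotypes, arch, 2, seed=0)
        assert np.allclose(ds.values.to_numpy(), 8.0)

    def test_single_effect_gives_exact_parental_difference(self, small_map,
                                                           small_genotypes):
        eff = PlantedEffect("T1", "1", 10.0, "trans", 2.0, 0.0)
        arch = self._noiseless_arch(
            [eff],
            [{"transcript": "T1", "chromosome": "2", "position_cM": 5.0}])
        ds = pq.simulate_expression(small_genotypes, arch, 1, seed=0)
        from plastiqtl.phenotypes import build_phenotypes
        phen = build_phenotypes(ds)
        for table in (phen.control, phen.SA):
            diff = table.loc["Sha", "T1"] - table.loc["Bay", "T1"]
            assert diff == pytest.approx(2.0)
        assert phen.delta.loc["Sha", "T1"] == pytest.approx(
            phen.delta.loc["Bay", "T1"])

    def test_opposing_pair_reproduces_transgression(self, small_genotypes):
        # interaction +1 at locus1, -1 at locus2: parents cancel, a RIL with
        # A at locus1 and B at locus2 has its SA response shifted by -1
        effects = [PlantedEffect("T1", "1", 0.0, "trans", 0.0, 1.0),
                   PlantedEffect("T1", "2", 0.0, "trans", 0.0, -1.0)]
        arch = self._noiseless_arch(
            [effects[0], effects[1]],
            [{"transcript": "T1", "chromosome": "2", "position_cM": 25.0}])
        ds = pq.simulate_expression(small_genotypes, arch, 1, seed=0)
        meta = ds.metadata
        vals = ds.values["T1"]

        def response(genotype):
            sa = vals[(meta["genotype"] == genotype)
                      & (meta["treatment"] == "SA")].iloc[0]
            ctl = vals[(meta["genotype"] == genotype)
                       & (meta["treatment"] == "control")].iloc[0]
            return sa - ctl

        assert response("Bay") == pytest.approx(response("Sha"))
        m1, m2 = small_genotypes.map.markers[0], None
        for m in small_genotypes.map.markers:
            if small_genotypes.map.table.set_index("marker").loc[m, "chromosome"] == "2":
                m2 = m
                break
        recombinant = small_genotypes.calls[
            (small_genotypes.calls[m1] == "A")
            & (small_genotypes.calls[m2] == "B")].index
        assert len(recombinant) > 0
        assert response(recombinant[0]) == pytest.approx(response("Bay") - 1.0)

    def test_generative_variance_matches_planted(self):
        gmap = pq.make_map([50.0], 10.0)
        geno = pq.simulate_ril_genotypes(gmap, 2000, seed=5)
        eff = PlantedEffect("T1", "1", 20.0, "trans", 1.0, 0.0)
        tx = pd.DataFrame([{"transcript": "T1", "chromosome": "1",
                            "position_cM": 45.0}])
        arch = PlantedArchitecture([eff], [], tx, noise_sd=0.5,
                                   replicate_sd=0.0)
        ds = pq.simulate_expression(geno, arch, 1, seed=6,
                                    include_parents=False)
        ctl = ds.values.loc[ds.metadata["treatment"] == "control", "T1"]
        expected = 0.25 * 1.0 + 0.25  # allele variance * b^2 + noise
        assert np.var(ctl) == pytest.approx(expected, rel=0.10)

    def test_seed_determinism(self, small_genotypes):
        arch = self._noiseless_arch(
            [], [{"transcript": "T1", "chromosome": "1", "position_cM": 5.0}])
        arch.noise_sd = 0.3
        a = pq.simulate_expression(small_genotypes, arch, 2, seed=8)
        b = pq.simulate_expression(small_genotypes, arch, 2, seed=8)
        pd.testing.assert_frame_equal(a.values, b.values)
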