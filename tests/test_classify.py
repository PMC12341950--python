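import itertools

import numpy as np
import pandas as pd
import pytest

from plastiqtl import classify, scan
from plastiqtl.phenotypes import PhenotypeSet, compute_delta


def records_frame(rows):
    defaults = {"transcript": "T1", "phenotype": "control", "chromosome": "1",
                "lod": 5.0, "slope_sign": 1, "r2": np.nan}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestGenePositionInterpolation:
    @pytest.fixture()
    def anchors(self):
        return pd.DataFrame({
            "marker": ["a1", "a2", "a3"],
            "chromosome": ["1", "1", "1"],
            "bp": [1_000_000, 2_000_000, 4_000_000],
            "cM": [10.0, 20.0, 50.0],
        })

    def test_gene_at_anchor_gets_anchor_cM(self, anchors):
        genes = pd.DataFrame([{"transcript": "g", "chromosome": "1",
                               "bp": 2_000_000}])
        out = classify.interpolate_gene_positions(genes, anchors)
        assert out["cM"].iloc[0] == 20.0

    def test_midpoint_linearity(self, anchors):
        genes = pd.DataFrame([{"transcript": "g", "chromosome": "1",
                               "bp": 1_500_000}])
        out = classify.interpolate_gene_positions(genes, anchors)
        assert out["cM"].iloc[0] == pytest.approx(15.0)

    def test_beyond_span_clamped(self, anchors):
        genes = pd.DataFrame([{"transcript": "g", "chromosome": "1",
                               "bp": 5_000_000}])
        out = classify.interpolate_gene_positions(genes, anchors)
        assert out["cM"].iloc[0] == 50.0

    def test_unanchored_chromosome_rejected(self, anchors):
        genes = pd.DataFrame([{"transcript": "gX", "chromosome": "9",
                               "bp": 100}])
        with pytest.raises(ValueError, match="gX"):
            classify.interpolate_gene_positions(genes, anchors)

    def test_monotone_between_anchors(self, anchors):
        bps = np.linspace(1_000_000, 4_000_000, 25)
        genes = pd.DataFrame({"transcript": [f"g{i}" for i in range(25)],
                              "chromosome": "1", "bp": bps})
        out = classify.interpolate_gene_positions(genes, anchors)
        assert (np.diff(out["cM"]) >= 0).all()


class TestCisTransLabel:
    @pytest.mark.parametrize("chrom,pos,expected", [
        ("1", 39.9, "cis"),
        ("2", 30.0, "trans"),
        ("1", 40.0, "cis"),    # boundary inclusive
        ("1", 40.01, "trans"),
    ])
    def test_window_convention(self, chrom, pos, expected):
        label = classify.classify_cis_trans(chrom, pos, "1", 30.0, window=10.0)
        assert label == expected

    def test_unknown_gene_position_unplaced(self):
        assert classify.classify_cis_trans("1", 5.0, "1", None) == "unplaced"


class TestMerging:
    def test_sa_delta_pair_merges_at_mean_position(self):
        rec = records_frame([
            {"phenotype": "SA", "chromosome": "3", "position_cM": 40.0},
            {"phenotype": "delta", "chromosome": "3", "position_cM": 45.0},
        ])
        merged = classify.merge_across_phenotypes(rec, window=5.5)
        assert len(merged) == 1
        assert merged[0].consensus_cM == pytest.approx(42.5)
        assert merged[0].membership == frozenset({"SA", "delta"})

    def test_records_beyond_window_stay_separate(self):
        rec = records_frame([
            {"phenotype": "SA", "position_cM": 40.0},
            {"phenotype": "delta", "position_cM": 46.0},
        ])
        merged = classify.merge_across_phenotypes(rec, window=5.5)
        assert len(merged) == 2

    def test_chained_records_form_one_cluster(self):
        rec = records_frame([
            {"phenotype": "control", "position_cM": 0.0},
            {"phenotype": "SA", "position_cM": 5.0},
            {"phenotype": "delta", "position_cM": 10.0},
        ])
        merged = classify.merge_across_phenotypes(rec, window=5.5)
        assert len(merged) == 1
        assert merged[0].consensus_cM == pytest.approx(5.0)
        assert merged[0].membership == frozenset({"control", "SA", "delta"})

    def test_brute_force_single_linkage_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = np.round(rng.uniform(0, 60, size=6), 2)
            phen = rng.choice(["control", "SA", "delta"], size=6)
            rec = records_frame([
                {"phenotype": p, "position_cM": x, "lod": 3.0}
                for p, x in zip(phen, pos)])
            merged = classify.merge_across_phenotypes(rec, window=5.5)
            # oracle: connected components of the <=5.5 cM adjacency graph
            adj = {i: {j for j in range(6)
                       if abs(pos[i] - pos[j]) <= 5.5} for i in range(6)}
            seen, components = set(), []
            for i in range(6):
                if i in seen:
                    continue
                stack, comp = [i], set()
                while stack:
                    k = stack.pop()
                    if k in comp:
                        continue
                    comp.add(k)
                    stack.extend(adj[k] - comp)
                seen |= comp
                components.append(comp)
            # every merged cluster must sit inside one oracle component
            for m in merged:
                member_pos = {r["position_cM"] for r in m.members}
                holding = [c for c in components
                           if member_pos <= {pos[i] for i in c}]
                assert holding, (pos, phen, member_pos)

    def test_duplicate_phenotype_keeps_higher_lod(self):
        rec = records_frame([
            {"phenotype": "SA", "position_cM": 40.0, "lod": 3.0},
            {"phenotype": "SA", "position_cM": 43.0, "lod": 8.0},
            {"phenotype": "control", "position_cM": 41.0, "lod": 4.0},
        ])
        merged = classify.merge_across_phenotypes(rec, window=5.5)
        primary = max(merged, key=lambda m: len(m.members))
        assert {r["position_cM"] for r in primary.members} == {43.0, 41.0}
        # the displaced lower-LOD SA record survives as its own locus
        all_positions = {r["position_cM"] for m in merged for r in m.members}
        assert 40.0 in all_positions

    def test_partition_and_order_invariance(self):
        rec = records_frame([
            {"phenotype": p, "position_cM": x, "lod": l}
            for p, x, l in [("control", 2.0, 3.0), ("SA", 6.0, 4.0),
                            ("delta", 30.0, 5.0), ("control", 33.0, 6.0)]])
        base = classify.merge_across_phenotypes(rec, window=5.5)
        n_members = sum(len(m.members) for m in base)
        assert n_members == len(rec)  # every record in exactly one cluster
        for perm in itertools.permutations(range(len(rec))):
            shuffled = rec.iloc[list(perm)].reset_index(drop=True)
            merged = classify.merge_across_phenotypes(shuffled, window=5.5)
            key = sorted((m.consensus_cM, tuple(sorted(m.membership)))
                         for m in merged)
            base_key = sorted((m.consensus_cM, tuple(sorted(m.membership)))
                              for m in base)
            assert key == base_key


class TestEffectSize:
    def test_perfect_predictor_gives_unity(self):
        x = pd.Series([0.0, 1.0, 0.0, 1.0, 1.0])
        assert classify.effect_size(x, x * 2.5 + 1) == pytest.approx(1.0)

    def test_zero_variance_gives_zero(self):
        x = pd.Series([0.0, 1.0, 0.0])
        assert classify.effect_size(x, pd.Series([2.0, 2.0, 2.0])) == 0.0

    def test_permutation_mean_matches_one_over_n_minus_1(self):
        rng = np.random.default_rng(8)
        n = 210
        x = pd.Series(rng.integers(0, 2, size=n).astype(float))
        y = rng.normal(size=n)
        r2s = [classify.effect_size(x, pd.Series(rng.permutation(y)))
               for _ in range(3000)]
        expected = 1 / (n - 1)
        assert np.mean(r2s) == pytest.approx(expected, rel=0.15)

    def test_r2_lod_consistency_identity(self, small_genotypes):
        probs = scan.genotype_probabilities(small_genotypes)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=len(probs)), index=probs.index)
        curve = scan.scan1_hk(probs, y, lod_cap=np.inf)
        n = len(y)
        for j in [0, 3, 7]:
            r2 = classify.effect_size(probs.iloc[:, j], y)
            assert r2 == pytest.approx(1 - 10 ** (-2 * curve.lod[j] / n),
                                       abs=1e-9)


class TestAnnotation:
    def _merged(self, chrom="2", pos=50.0, label="trans"):
        m = classify.MergedEQTL("T1", chrom, pos, frozenset({"SA"}),
                                [], cis_trans=label)
        return m

    def test_paralog_within_window_flags(self):
        paralogs = pd.DataFrame([{"transcript": "T1", "accession": "Bay-0",
                                  "paralog_chromosome": "2",
                                  "paralog_cM": 58.0}])
        out = classify.annotate_paralogs([self._merged()], paralogs)
        assert out[0].paralog_flag
        assert out[0].paralog_counts == {"Bay-0": 1}

    def test_no_paralogs_no_flag(self):
        out = classify.annotate_paralogs([self._merged()], pd.DataFrame(
            columns=["transcript", "accession", "paralog_chromosome",
                     "paralog_cM"]))
        assert not out[0].paralog_flag

    def test_cis_eqtl_never_paralog_flagged(self):
        paralogs = pd.DataFrame([{"transcript": "T1", "accession": "Sha",
                                  "paralog_chromosome": "2",
                                  "paralog_cM": 50.0}])
        out = classify.annotate_paralogs([self._merged(label="cis")], paralogs)
        assert not out[0].paralog_flag

    def test_hotspot_membership_by_region_distance(self):
        m = self._merged(chrom="5", pos=30.0)
        out = classify.annotate_paralogs(
            [m], None, hotspot_regions=[("5", 33.0, 40.0)],
            membership_window=5.0)
        assert out[0].hotspot_flag
        m2 = self._merged(chrom="5", pos=27.0)
        out2 = classify.annotate_paralogs(
            [m2], None, hotspot_regions=[("5", 33.0, 40.0)],
            membership_window=5.0)
        assert not out2[0].hotspot_flag


class TestSummaries:
    def _merged_set(self):
        mk = classify.MergedEQTL
        return [
            mk("T1", "1", 10.0, frozenset({"SA"}), [], cis_trans="trans"),
            mk("T2", "1", 20.0, frozenset({"SA"}), [], cis_trans="trans"),
            mk("T3", "2", 30.0, frozenset({"SA"}), [], cis_trans="trans"),
            mk("T4", "2", 40.0, frozenset({"SA"}), [], cis_trans="cis"),
        ]

    def test_trans_proportion(self):
        summary = classify.summarize_cis_trans(self._merged_set())
        assert summary["per_phenotype"]["SA"]["trans_proportion"] == 0.75
        assert summary["overall"]["n_cis"] == 1

    def test_absent_membership_subsets_missing(self):
        summary = classify.summarize_cis_trans(self._merged_set())
        assert set(summary["per_membership"]) == {"SA"}

    def test_planted_trans_proportion_recovered(self):
        from plastiqtl.validation import recovery_experiment
        result = recovery_experiment(seed=2, n_transcripts=200, n_cis=8,
                                     n_trans=32)
        planted = result["planted_trans_proportion"]
        assert abs(result["recovered_trans_proportion"] - planted) <= 0.05
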