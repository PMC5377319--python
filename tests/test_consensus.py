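import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import _oracles as oracle
from refgenestab import consensus
from refgenestab.errors import ParameterError, ValidationError
from refgenestab.synthetic_data import generate_study


class TestZScore:
    def test_unit_spaced_scores(self):
        z, degenerate = consensus.zscore_column({"a": 1.0, "b": 2.0, "c": 3.0})
        assert not degenerate
        assert z == pytest.approx({"a": -1.0, "b": 0.0, "c": 1.0})

    def test_constant_scores_flagged_degenerate(self):
        z, degenerate = consensus.zscore_column({"a": 2.0, "b": 2.0, "c": 2.0})
        assert degenerate and all(v == 0.0 for v in z.values())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=12, unique=True))
    def test_mean_zero_sd_one(self, scores):
        assume(max(scores) - min(scores) > 1e-6)
        z, degenerate = consensus.zscore_column(
            {f"g{i}": s for i, s in enumerate(scores)})
        assert not degenerate
        arr = np.array(list(z.values()))
        assert arr.mean() == pytest.approx(0.0, abs=1e-9)
        assert arr.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_non_finite_score_names_gene(self):
        with pytest.raises(ValidationError, match="g2"):
            consensus.zscore_column({"g1": 1.0, "g2": float("nan"), "g3": 2.0})


class TestConsensusRank:
    def test_dominant_gene_ranks_first(self):
        key = consensus.consensus_rank(
            {"a": 0.1, "b": 0.5, "c": 0.9},
            {"a": 0.05, "b": 0.4, "c": 0.8},
            {"a": 0.2, "b": 0.6, "c": 1.1})
        assert key.per_gene.loc["a", "final_rank"] == 1
        assert key.top_k[0] == "a"

    def test_excel_rank_tie_semantics(self):
        # two genes tied at the best mean z -> both rank 1, next rank 3
        scores = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 4.0}
        key = consensus.consensus_rank(scores, dict(scores), dict(scores))
        ranks = key.per_gene["final_rank"]
        assert list(ranks[["b", "c"]]) == [1, 1]
        assert ranks["a"] == 3 and ranks["d"] == 4

    def test_boundary_ties_spill_into_top_k(self):
        key = consensus.consensus_rank(
            {"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 5.0},
            {"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 5.0},
            {"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 5.0}, k=3)
        assert key.top_k == ["a", "b", "c", "d"]

    def test_end_to_end_recomputation_oracle(self, rng):
        genes = [f"g{i}" for i in range(7)]
        maps = [dict(zip(genes, rng.uniform(0, 2, 7))) for _ in range(3)]
        key = consensus.consensus_rank(*maps)

        def z(col):
            vals = np.array([col[g] for g in genes])
            return (vals - vals.mean()) / vals.std(ddof=1)

        mean_z = np.mean([z(m) for m in maps], axis=0)
        expected_order = [genes[i] for i in np.argsort(mean_z)]
        assert key.ranking == expected_order

    def test_gene_set_mismatch_lists_difference(self):
        with pytest.raises(ValidationError, match="g3"):
            consensus.consensus_rank(
                {"g1": 1.0, "g2": 2.0}, {"g1": 1.0, "g2": 2.0},
                {"g1": 1.0, "g3": 2.0})

    def test_invariant_under_affine_transform_of_one_method(self, rng):
        genes = [f"g{i}" for i in range(6)]
        maps = [dict(zip(genes, rng.uniform(0, 2, 6))) for _ in range(3)]
        base = consensus.consensus_rank(*maps)
        transformed = consensus.consensus_rank(
            {g: 7.0 * v + 3.0 for g, v in maps[0].items()}, maps[1], maps[2])
        assert base.ranking == transformed.ranking
        np.testing.assert_allclose(base.per_gene["mean_z"],
                                   transformed.per_gene["mean_z"], atol=1e-9)

    def test_unanimous_rankings_are_preserved(self, rng):
        genes = [f"g{i}" for i in range(6)]
        base = np.sort(rng.uniform(0, 1, 6))
        # three distinct monotone score sets agreeing on the order
        maps = [dict(zip(genes, base)),
                dict(zip(genes, base * 3 + 0.1)),
                dict(zip(genes, np.exp(base)))]
        key = consensus.consensus_rank(*maps)
        assert key.ranking == genes


class TestOverlapProbabilities:
    def test_single_gene_of_nine_in_top_three(self):
        assert consensus.top_k_overlap_probability(9, 3, 1) == pytest.approx(1 / 3)

    def test_empty_requirement_is_certain(self):
        assert consensus.top_k_overlap_probability(9, 3, 0) == 1.0

    @pytest.mark.parametrize("k_spec, expected", [(2, 1 / 12), (3, 1 / 84)])
    def test_published_family(self, k_spec, expected):
        assert consensus.top_k_overlap_probability(9, 3, k_spec) == pytest.approx(
            expected)

    @pytest.mark.parametrize("n", range(3, 13))
    @pytest.mark.parametrize("k_top", range(1, 6))
    def test_matches_exhaustive_enumeration(self, n, k_top):
        if k_top > n:
            pytest.skip("k_top > n")
        for k_spec in range(k_top + 1):
            closed = consensus.top_k_overlap_probability(n, k_top, k_spec)
            brute = oracle.enumerate_overlap_probability(n, k_top, k_spec)
            assert closed == pytest.approx(brute, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            consensus.top_k_overlap_probability(9, 3, 4)

    def test_cross_experiment_squares_single(self):
        a2 = consensus.cross_experiment_overlap(9, 3, {"x", "y"})
        a3 = consensus.cross_experiment_overlap(9, 3, {"x", "y", "z"})
        assert a2.p_cross_experiment == pytest.approx((1 / 12) ** 2)
        assert a3.p_cross_experiment == pytest.approx((1 / 84) ** 2)
        empty = consensus.cross_experiment_overlap(9, 3, set())
        assert empty.p_cross_experiment == 1.0


class TestConsensusTable:
    def _key(self, species, tissue, order):
        import pandas as pd
        genes = list(order)
        frame = pd.DataFrame({
            "z_genorm": range(len(genes)), "z_normfinder": range(len(genes)),
            "z_bestkeeper": range(len(genes))}, index=pd.Index(genes, name="gene"),
            dtype=float)
        frame["mean_z"] = frame.mean(axis=1)
        frame["final_rank"] = range(1, len(genes) + 1)
        frame["_input_order"] = range(len(genes))
        return consensus.ConsensusKey(species, tissue, frame, genes[:3], 3)

    def test_identical_top3_all_marked_shared(self):
        keys = [self._key("sp1", "egg", ["a", "b", "c", "d"]),
                self._key("sp2", "egg", ["a", "b", "c", "d"])]
        table = consensus.build_consensus_table(keys)
        assert table.shared["egg"] == {"a", "b", "c"}

    def test_frequency_counting_across_tissues(self):
        keys = [self._key("sp1", t, ["a", "b", "c", "d"]) for t in
                ["t1", "t2", "t3", "t4", "t5", "t6", "t7"]]
        keys += [self._key("sp1", t, ["d", "e", "f", "a"]) for t in
                 ["t8", "t9", "t10", "t11", "t12", "t13"]]
        table = consensus.build_consensus_table(keys)
        assert table.frequency.loc["a", "sp1"] == 7
        assert table.frequency.loc["d", "sp1"] == 6

    def test_planted_shared_stable_genes_marked(self):
        collection, truths = generate_study(
            species=("sA", "sB"), tissues=["egg", "larva", "head"],
            shared_stable_genes={"RPL19", "tbp"}, stable_sd=0.05,
            noise_sd_range=(0.5, 0.8), seed=4)
        from refgenestab.cli_reporting import RunConfig, analyze_panel
        cfg = RunConfig(input_path=".", outdir=".")
        keys = [analyze_panel(p, cfg, None).consensus for p in collection]
        table = consensus.build_consensus_table(keys)
        shared_hits = sum(
            {"RPL19", "tbp"} <= table.shared[t] for t in ["egg", "larva", "head"])
        assert shared_hits >= 2  # planted genes dominate most tissues

    def test_rendered_table_stars_shared_genes(self):
        keys = [self._key("sp1", "egg", ["a", "b", "c", "d"]),
                self._key("sp2", "egg", ["a", "x", "y", "z"])]
        table = consensus.build_consensus_table(keys)
        text = consensus.render_consensus_table(table)
        assert "a*" in text and "b*" not in text
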