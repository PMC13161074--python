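import numpy as np
import pytest

from dtakit.errors import ConfigError, DomainError
from dtakit.interaction_model import CrossAttentionRegressor, ModelConfig
from dtakit.interpretability import (
    OcclusionConfig,
    attention_column_profile,
    extract_cross_attention,
    map_hotspots,
    occlude_scan,
    shap_segments,
    top_windows,
)


@pytest.fixture(scope="module")
def constant_model():
    model = CrossAttentionRegressor(
        ModelConfig(d_model=8, n_heads=2, head_widths=(8,), dropout=0.0, seed=2)
    )
    model.head.out.W.data[:] = 0.0
    model.head.out.b.data[:] = 3.0
    model.eval()
    return model


@pytest.fixture(scope="module")
def random_model():
    model = CrossAttentionRegressor(
        ModelConfig(d_model=8, n_heads=2, head_widths=(8,), dropout=0.0, seed=11)
    )
    model.eval()
    return model


SMILES = "CC(=O)Nc1ccc(cc1)C=CC(=O)NCCO"
SEQUENCE = "MKLVHGWYDEACDEFGHIKLMNPQRSTVWYAAKKLLMMNN"


class TestOcclusion:
    def test_constant_model_gives_all_zero_deltas(self, constant_model):
        profile = occlude_scan(constant_model, SMILES, SEQUENCE, "protein")
        assert all(d == 0.0 for _, _, d in profile.window_scores)
        assert np.all(profile.position_scores == 0.0)

    def test_window_count_formula_protein(self, random_model):
        profile = occlude_scan(random_model, SMILES, "A" * 100, "protein")
        assert len(profile.window_scores) == 100 - 21 + 1

    def test_window_count_formula_drug(self, random_model):
        profile = occlude_scan(random_model, "C" * 60, SEQUENCE, "drug")
        assert len(profile.window_scores) == 60 - 15 + 1

    def test_window_longer_than_content_rejected(self, random_model):
        with pytest.raises(DomainError):
            occlude_scan(random_model, "CCO", SEQUENCE, "drug")

    def test_deltas_are_signed_and_baseline_recorded(self, random_model):
        profile = occlude_scan(random_model, SMILES, SEQUENCE, "protein")
        assert profile.baseline_prediction == pytest.approx(
            random_model.predict_pair(SMILES, SEQUENCE)
        )

    def test_position_scores_cover_content(self, random_model):
        profile = occlude_scan(random_model, SMILES, SEQUENCE, "protein")
        assert len(profile.position_scores) == len(SEQUENCE)


class TestShap:
    def test_single_segment_is_full_minus_baseline(self, random_model):
        res = shap_segments(random_model, SMILES, "MKLVHGWYDE", "protein",
                            segment_size=50)
        assert len(res.segments) == 1
        assert res.phi[0] == pytest.approx(res.full_prediction - res.phi0)

    def test_efficiency_axiom_exact(self, random_model):
        res = shap_segments(random_model, SMILES, SEQUENCE, "protein")
        assert res.estimator["kind"] == "exact"
        assert res.phi0 + res.phi.sum() == pytest.approx(
            res.full_prediction, abs=1e-6
        )

    def test_efficiency_axiom_drug_axis(self, random_model):
        res = shap_segments(random_model, SMILES, SEQUENCE, "drug")
        assert res.phi0 + res.phi.sum() == pytest.approx(
            res.full_prediction, abs=1e-6
        )

    def test_symmetry_for_interchangeable_segments(self, constant_model):
        # under a constant model every segment has identical (zero) effect on
        # every coalition; exact Shapley must give them equal values
        res = shap_segments(constant_model, SMILES, SEQUENCE, "protein")
        assert np.allclose(res.phi, res.phi[0], atol=1e-9)
        assert np.allclose(res.phi, 0.0, atol=1e-9)

    def test_additive_game_recovers_standalone_contributions(self):
        """For a value function that is additive over segments, exact Shapley
        equals each segment's standalone contribution."""
        import itertools
        from dtakit.interpretability import _shapley_exact

        M = 5
        rng = np.random.default_rng(0)
        standalone = rng.normal(size=M)
        values = {
            frozenset(c): 1.0 + sum(standalone[m] for m in c)
            for size in range(M + 1)
            for c in itertools.combinations(range(M), size)
        }
        phi = _shapley_exact(values, M)
        assert np.allclose(phi, standalone, atol=1e-12)

    def test_sampled_estimator_variance_shrinks_with_permutations(self, random_model):
        # force sampling by tiny segments -> M > 12
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        results = {}
        for n_perm in (20, 200):
            phis = [
                shap_segments(random_model, "CCO", seq, "protein",
                              segment_size=2, n_perm=n_perm, seed=s).phi
                for s in range(4)
            ]
            results[n_perm] = np.mean(np.var(np.stack(phis), axis=0))
        assert results[200] < results[20]

    def test_sampled_estimator_records_provenance(self, random_model):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        res = shap_segments(random_model, "CCO", seq, "protein",
                            segment_size=2, n_perm=10, seed=3)
        assert res.estimator == {"kind": "sampled", "n_perm": 10, "seed": 3}


class TestAttentionExtraction:
    def test_rows_of_head_average_sum_to_one(self, random_model):
        att = extract_cross_attention(random_model, SMILES, SEQUENCE)
        assert np.allclose(att.head_average.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_head_average_equals_the_head(self):
        model = CrossAttentionRegressor(
            ModelConfig(d_model=8, n_heads=1, head_widths=(8,), dropout=0.0,
                        seed=4)
        )
        model.eval()
        att = extract_cross_attention(model, SMILES, SEQUENCE)
        assert np.allclose(att.head_average, att.per_head[0])

    def test_capture_does_not_change_prediction(self, random_model):
        before = random_model.predict_pair(SMILES, SEQUENCE)
        extract_cross_attention(random_model, SMILES, SEQUENCE)
        after = random_model.predict_pair(SMILES, SEQUENCE)
        assert before == after

    def test_mode_none_raises(self):
        model = CrossAttentionRegressor(
            ModelConfig(d_model=8, n_heads=2, head_widths=(8,), dropout=0.0,
                        interaction_mode="none", seed=4)
        )
        with pytest.raises(ConfigError):
            extract_cross_attention(model, SMILES, SEQUENCE)

    def test_two_equal_logit_protein_tokens_attend_half_each(self):
        model = CrossAttentionRegressor(
            ModelConfig(d_model=8, n_heads=1, head_widths=(8,), dropout=0.0,
                        seed=4)
        )
        model.eval()
        # two identical residues -> identical keys -> softmax of equal logits
        att = extract_cross_attention(model, "CC", "AA")
        assert np.allclose(att.head_average, 0.5)


class TestHotspots:
    def test_single_spike_ranks_first(self):
        scores = np.zeros(100)
        scores[60] = 5.0
        hot = map_hotspots(scores, top_k=1)[0]
        assert hot.start <= 61 <= hot.end  # 1-based

    def test_uniform_scores_tie_break_leftmost(self):
        hot = map_hotspots(np.ones(30), top_k=1)[0]
        assert hot.start == 1

    def test_returns_at_most_top_k_non_overlapping(self):
        scores = np.zeros(60)
        scores[[5, 25, 45]] = 1.0
        hotspots = map_hotspots(scores, top_k=3)
        assert len(hotspots) == 3
        intervals = [(h.start, h.end) for h in hotspots]
        for a, b in zip(sorted(intervals), sorted(intervals)[1:]):
            assert a[1] < b[0]

    def test_empty_scores_rejected(self):
        with pytest.raises(DomainError):
            map_hotspots(np.array([]))


class TestPlantedMotifRecovery:
    """On the trained synthetic-benchmark model, every interpretability view
    must localise the planted protein motif."""

    @pytest.fixture(scope="class")
    @staticmethod
    def case(trained_benchmark_model):
        tb = trained_benchmark_model
        truth, dicts = tb["truth"], tb["dicts"]
        did = next(d for d, f in truth.drug_has_warhead.items() if f)
        pid = next(p for p, f in truth.protein_has_motif.items() if f)
        pos = truth.motif_position[pid]
        motif_interval = (pos + 1, pos + len(truth.spec["motif"]))  # 1-based
        return tb["model"], dicts.drugs[did], dicts.proteins[pid], motif_interval

    @staticmethod
    def _overlaps(a, b):
        return a[0] <= b[1] and b[0] <= a[1]

    def test_occlusion_top_hotspot_overlaps_motif(self, case):
        model, smiles, seq, motif = case
        profile = occlude_scan(model, smiles, seq, "protein")
        hot = top_windows(profile, top_k=1)[0]
        assert self._overlaps((hot.start, hot.end), motif)

    def test_shap_top_segment_overlaps_motif(self, case):
        model, smiles, seq, motif = case
        res = shap_segments(model, smiles, seq, "protein")
        top = res.segments[int(np.argmax(np.abs(res.phi)))]
        assert self._overlaps((top[0] + 1, top[1]), motif)

    def test_attention_top_hotspot_overlaps_motif(self, case):
        model, smiles, seq, motif = case
        att = extract_cross_attention(model, smiles, seq)
        hot = map_hotspots(attention_column_profile(att), top_k=1,
                           positions=att.protein_positions)[0]
        assert self._overlaps((hot.start, hot.end), motif)
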