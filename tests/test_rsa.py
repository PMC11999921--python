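"""RDM constructions, comparisons, decoding and similarity summaries."""

import numpy as np
import pytest
from scipy import stats

from realign.datasets import NeuralDataset
from realign.rsa import (RDM, SimilarityReport, compare_rdms, improvement_ratio,
                         layerwise_similarity, rdm_from_decoding, rdm_from_patterns,
                         rdm_from_weights, timecourse_similarity)
from realign.synth import average_repeats, simulate_eeg, _pooled_stage_features


class TestPatternRDM:
    def test_duplicated_rows_zero_distance(self):
        p = np.array([[1.0, 2, 3], [1, 2, 3], [3, 1, 2]])
        rdm = rdm_from_patterns(p)
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_centered_row_distance_two(self):
        row = np.array([1.0, -2, 3, -2])       # zero mean
        rdm = rdm_from_patterns(np.stack([row, -row, row * 2]))
        assert rdm.matrix[0, 1] == pytest.approx(2.0)
        assert rdm.matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_hand_matrix_matches_pairwise_oracle(self):
        p = np.array([[0.2, 1.4, -0.3, 2.2],
                      [1.1, 0.5, 0.9, -0.4],
                      [-0.7, 0.8, 1.5, 0.1]])
        rdm = rdm_from_patterns(p)
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else 1 - stats.pearsonr(p[i], p[j]).statistic
                assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_convention(self):
        with pytest.warns(UserWarning):
            rdm = rdm_from_patterns(np.array([[1.0, 1, 1], [0, 1, 2]]))
        assert rdm.matrix[0, 1] == 1.0

    def test_invariants_asserted_on_construction(self):
        with pytest.raises(ValueError):
            RDM(np.array([[0.0, 1], [0.5, 0]]), ["a", "b"], "one_minus_pearson")
        with pytest.raises(ValueError):
            RDM(np.array([[0.5, 1], [1, 0.5]]), ["a", "b"], "one_minus_pearson")
        with pytest.raises(ValueError):
            RDM(np.array([[0.0, 3], [3, 0]]), ["a", "b"], "one_minus_pearson")


class TestWeightRDM:
    def test_arithmetic(self):
        rdm = rdm_from_weights(np.array([[0.0], [1.0], [3.0]]), 0)
        assert rdm.matrix[0, 1] == 1 and rdm.matrix[1, 2] == 2 and rdm.matrix[0, 2] == 3

    def test_constant_column_all_zero(self):
        rdm = rdm_from_weights(np.full((4, 2), 7.0), 1)
        assert (rdm.matrix == 0).all()

    def test_one_rdm_per_dimension(self):
        w = np.random.default_rng(0).random((10, 49))
        rdms = [rdm_from_weights(w, d) for d in range(49)]
        assert len(rdms) == 49


class TestCompareRDMs:
    def test_self_similarity_one(self):
        rdm = rdm_from_patterns(np.random.default_rng(1).normal(size=(6, 5)))
        assert compare_rdms(rdm, rdm) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        a = rdm_from_patterns(np.random.default_rng(2).normal(size=(7, 5)))
        m = np.tanh(a.matrix)                  # strictly monotone, keeps zeros
        b = RDM(m, a.stimulus_ids, "one_minus_pearson")
        assert compare_rdms(a, b) == pytest.approx(1.0)

    def test_hand_rdms_match_rank_correlation(self):
        rng = np.random.default_rng(3)
        a = rdm_from_patterns(rng.normal(size=(4, 6)))
        b = rdm_from_patterns(rng.normal(size=(4, 6)))
        iu = np.triu_indices(4, 1)
        expected = stats.spearmanr(a.matrix[iu], b.matrix[iu]).statistic
        assert compare_rdms(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_in_arguments_and_reorder_invariant(self):
        rng = np.random.default_rng(4)
        pa, pb = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        a, b = rdm_from_patterns(pa), rdm_from_patterns(pb)
        assert compare_rdms(a, b) == pytest.approx(compare_rdms(b, a))
        perm = rng.permutation(6)
        ids = [a.stimulus_ids[i] for i in perm]
        a2 = RDM(a.matrix[np.ix_(perm, perm)], ids, "one_minus_pearson")
        b2 = RDM(b.matrix[np.ix_(perm, perm)], ids, "one_minus_pearson")
        assert compare_rdms(a2, b2) == pytest.approx(compare_rdms(a, b))

    def test_id_mismatch_is_an_error(self):
        a = rdm_from_patterns(np.random.default_rng(5).normal(size=(4, 4)),
                              ["a", "b", "c", "d"])
        b = rdm_from_patterns(np.random.default_rng(5).normal(size=(4, 4)),
                              ["b", "a", "c", "d"])
        with pytest.raises(ValueError):
            compare_rdms(a, b)


def _synthetic_epochs(n_cond, n_rep, n_ch, n_t, seed, separation=0.0):
    """Gaussian epochs; optional per-condition mean separation."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, separation, size=(n_cond, n_ch * n_t))
    data = means[:, None, :] + rng.normal(size=(n_cond, n_rep, n_ch * n_t))
    return NeuralDataset([f"c{i}" for i in range(n_cond)], data, {},
                         modality="channel_time", sfreq_hz=100.0,
                         n_channels=n_ch, n_timepoints=n_t)


class TestDecodingRDM:
    def test_separable_noiseless_conditions_decode_perfectly(self):
        eeg = _synthetic_epochs(3, 8, 4, 2, seed=0, separation=50.0)
        rdm = rdm_from_decoding(eeg, 0, cv_folds=4, seed=1, pseudo_size=2)
        iu = np.triu_indices(3, 1)
        assert (rdm.matrix[iu] == 1.0).all()

    def test_identical_distributions_stay_in_chance_band(self):
        """Null decoding over many pairs averages to chance."""
        eeg = _synthetic_epochs(25, 16, 5, 1, seed=2, separation=0.0)
        rdm = rdm_from_decoding(eeg, 0, cv_folds=4, seed=3, pseudo_size=4)
        mean_acc = rdm.upper().mean()          # 300 null pairs
        assert 0.35 < mean_acc < 0.65

    def test_entries_bounded_and_diagonal_zero(self):
        eeg = _synthetic_epochs(6, 8, 3, 2, seed=4, separation=1.0)
        rdm = rdm_from_decoding(eeg, 1, cv_folds=4, seed=5, pseudo_size=2)
        assert rdm.matrix.min() >= 0 and rdm.matrix.max() <= 1
        assert (np.diag(rdm.matrix) == 0).all()

    def test_fold_count_reduced_with_warning(self):
        eeg = _synthetic_epochs(4, 3, 3, 1, seed=6, separation=2.0)
        with pytest.warns(UserWarning, match="reducing folds"):
            rdm_from_decoding(eeg, 0, cv_folds=8, seed=7, pseudo_size=1)

    def test_requires_channel_time_modality(self):
        data = NeuralDataset(["a", "b"], np.zeros((2, 3, 4)), {}, modality="voxel")
        with pytest.raises(ValueError):
            rdm_from_decoding(data, 0)


class TestLayerwiseSimilarity:
    def test_single_layer_summary_equals_its_rho(self):
        rng = np.random.default_rng(8)
        patterns = rng.normal(size=(8, 10))
        brain = {"V1": rdm_from_patterns(patterns)}
        rep = layerwise_similarity({"only": patterns + rng.normal(size=(8, 10)) * 0.1},
                                   brain, brain["V1"].stimulus_ids)
        assert rep.max_rho("V1") == pytest.approx(
            float(rep.table["spearman_rho"].iloc[0]))
        assert rep.argmax_layer("V1") == "only"

    def test_identical_model_and_brain_rdms_give_one(self):
        rng = np.random.default_rng(9)
        patterns = {f"L{i}": rng.normal(size=(7, 6)) for i in range(3)}
        brain = {roi: rdm_from_patterns(patterns["L1"]) for roi in ("A", "B")}
        rep = layerwise_similarity(patterns, brain, brain["A"].stimulus_ids)
        for roi in ("A", "B"):
            assert rep.max_rho(roi) == pytest.approx(1.0)
            assert rep.argmax_layer(roi) == "L1"

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            layerwise_similarity({"V1": np.zeros((4, 4))}, {})

    def test_report_roundtrip(self, tmp_path):
        rng = np.random.default_rng(10)
        patterns = {f"L{i}": rng.normal(size=(6, 5)) for i in range(2)}
        brain = {"A": rdm_from_patterns(rng.normal(size=(6, 5)))}
        rep = layerwise_similarity(patterns, brain, brain["A"].stimulus_ids)
        rep.save(tmp_path / "rep.json")
        back = SimilarityReport.load(tmp_path / "rep.json")
        assert back.region_summary == rep.region_summary


class TestImprovementRatio:
    def _report(self, rhos):
        import pandas as pd
        rows = [{"model_layer": "L0", "brain_context": k, "spearman_rho": v}
                for k, v in rhos.items()]
        return SimilarityReport.from_table(pd.DataFrame(rows))

    def test_arithmetic(self):
        out = improvement_ratio(self._report({"V1": 0.22}), self._report({"V1": 0.20}))
        assert out["V1"]["ratio"] == pytest.approx(0.10)
        out = improvement_ratio(self._report({"V1": 0.143}), self._report({"V1": 0.10}))
        assert out["V1"]["ratio"] == pytest.approx(0.43)

    def test_equal_reports_zero_and_self_ratio(self):
        rep = self._report({"V1": 0.4, "LOC": 0.2})
        out = improvement_ratio(rep, rep)
        assert all(v["ratio"] == 0.0 for v in out.values())

    def test_nonpositive_baseline_flagged_undefined(self):
        out = improvement_ratio(self._report({"V1": 0.3}), self._report({"V1": -0.1}))
        assert out["V1"]["ratio"] is None and not out["V1"]["defined"]


class TestTimecourse:
    def test_layer_by_timepoint_shape(self, teacher_spec6, images60):
        sub = images60.subset(np.arange(12))
        eeg = simulate_eeg(sub, teacher_spec6, n_channels=6, n_timepoints=5,
                           n_repeats=8, seed=11)
        z = _pooled_stage_features(teacher_spec6.teacher, sub.pixels, 2)
        frame = timecourse_similarity(z, eeg, cv_folds=4, seed=12, pseudo_size=2)
        assert frame.shape == (4, 5)

    def test_pure_noise_epochs_give_near_zero_rho(self, teacher_spec6, images60):
        sub = images60.subset(np.arange(15))
        rng = np.random.default_rng(13)
        noise = NeuralDataset(list(sub.ids), rng.normal(size=(15, 12, 4 * 3)), {},
                              modality="channel_time", sfreq_hz=100.0,
                              n_channels=4, n_timepoints=3)
        z = _pooled_stage_features(teacher_spec6.teacher, sub.pixels, 2)
        frame = timecourse_similarity(z, noise, cv_folds=4, seed=14, pseudo_size=3)
        assert frame.abs().to_numpy().mean() < 0.1

    def test_late_layer_peaks_later_than_early_layer(self, teacher_spec6, images60):
        """The latency ramp shows up in the decoding timecourse."""
        sub = images60.subset(np.arange(40))
        eeg = simulate_eeg(sub, teacher_spec6, n_channels=17, n_timepoints=10,
                           n_repeats=48, seed=15)
        z = _pooled_stage_features(teacher_spec6.teacher, sub.pixels,
                                   teacher_spec6.pool_grid)
        frame = timecourse_similarity({"V1": z["V1"], "IT": z["IT"]}, eeg,
                                      cv_folds=4, seed=16, pseudo_size=12)
        assert int(frame.loc["IT"].idxmax()) > int(frame.loc["V1"].idxmax())
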