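"""HRM normalization, clustering, confidence and unknown assignment."""

import numpy as np
import pytest

from meltmark.hrm import (HRMConfig, UNASSIGNED, assign_unknown, cluster_curves,
                          difference_curves, normalize_curve)
from meltmark.pcr import amplify
from meltmark.thermo import MeltCurve, melt_grid, simulate_melt_curve


def sigmoid_curve(sample_id, tm, width=1.0, grid=(65.0, 95.0, 0.2),
                  noise_sd=0.0, rng=None, slope=0.0, offset=10.0, group=None):
    """Raw melt curve with a logistic transition at ``tm`` plus baseline."""
    temps = melt_grid(grid)
    theta = 1.0 / (1.0 + np.exp((temps - tm) / width))
    raw = 90.0 * theta + offset + slope * (temps - temps[0])
    if noise_sd:
        raw = raw + (rng or np.random.default_rng(0)).normal(0, noise_sd, len(temps))
    return MeltCurve(sample_id=sample_id, temperatures=temps,
                     fluorescence=np.clip(raw, 0, None), group_label=group)


class TestNormalize:
    def test_two_state_curve_normalizes_to_plateaus(self, hrm_config):
        curve = sigmoid_curve("s", tm=80.0)
        nc = normalize_curve(curve, hrm_config)
        pre = nc.values[nc.temperatures <= 67.0]
        post = nc.values[nc.temperatures >= 93.0]
        assert np.allclose(pre, 100.0, atol=0.5)
        assert np.allclose(post, 0.0, atol=0.5)
        assert nc.tm_est == pytest.approx(80.0, abs=hrm_config.grid[2] / 2)

    def test_baseline_window_means_pinned(self, hrm_config):
        rng = np.random.default_rng(1)
        curve = sigmoid_curve("s", tm=80.0, noise_sd=0.3, rng=rng, slope=-0.05)
        nc = normalize_curve(curve, hrm_config)
        pre_mask = (nc.temperatures >= 65.0) & (nc.temperatures <= 67.0)
        post_mask = (nc.temperatures >= 93.0) & (nc.temperatures <= 95.0)
        # least-squares baselines leave zero mean residual in each window
        assert nc.values[pre_mask].mean() == pytest.approx(100.0, abs=1e-6)
        assert nc.values[post_mask].mean() == pytest.approx(0.0, abs=1e-6)

    def test_idempotent_on_normalized_output(self, hrm_config):
        # re-normalizing an already-normalized curve (offset to stay
        # non-negative) reproduces it: the baselines are flat at 100/0
        nc = normalize_curve(sigmoid_curve("s", tm=80.0), hrm_config)
        again = normalize_curve(
            MeltCurve("s", nc.temperatures, nc.values + 5.0),
            HRMConfig(pre_melt_window=hrm_config.pre_melt_window,
                      post_melt_window=hrm_config.post_melt_window))
        assert np.allclose(again.values, nc.values, atol=1e-6)

    def test_hand_computed_five_point_curve(self):
        # grid 0..8 step 2; baselines fit on the two end windows have slope
        # -1: upper(T) = 100 - T, lower(T) = 20 - T.  At T = 4, F = 58:
        # v = 100*(58 - 16)/(96 - 16) = 52.5
        config = HRMConfig(pre_melt_window=(0, 2), post_melt_window=(6, 8),
                           grid=(0, 8, 2))
        curve = MeltCurve("h", [0, 2, 4, 6, 8], [100, 98, 58, 14, 12])
        nc = normalize_curve(curve, config)
        assert nc.values[2] == pytest.approx(52.5)
        assert nc.values[0] == pytest.approx(100.0)
        assert nc.values[4] == pytest.approx(0.0)

    def test_degenerate_baselines_rejected(self, hrm_config):
        flat = MeltCurve("f", melt_grid(hrm_config.grid),
                         np.full(151, 10.0))
        with pytest.raises(ValueError, match="degenerate"):
            normalize_curve(flat, hrm_config)

    def test_no_crossing_curves_clustered_by_shape_only(self, hrm_config):
        from meltmark.hrm import NormalizedCurve

        good = [normalize_curve(sigmoid_curve(f"s{i}", 80.0), hrm_config)
                for i in range(2)]
        flat = NormalizedCurve(sample_id="flat", temperatures=good[0].temperatures,
                               values=np.full_like(good[0].values, 80.0),
                               tm_est=None, no_crossing=True)
        result = cluster_curves([*good, flat], hrm_config)
        assert result.shape_only_samples == ("flat",)
        assert result.labels["flat"] != result.labels["s0"]


class TestDifferenceCurves:
    def test_reference_difference_is_zero(self, hrm_config):
        curves = [normalize_curve(sigmoid_curve(f"s{i}", 80.0), hrm_config)
                  for i in range(3)]
        diffs = difference_curves(curves, "s0")
        assert np.allclose(diffs["s0"], 0.0)
        assert np.allclose(diffs["s1"], diffs["s2"])

    def test_tm_shift_creates_larger_lobe(self, hrm_config):
        ref = normalize_curve(sigmoid_curve("ref", 80.0), hrm_config)
        same = normalize_curve(sigmoid_curve("same", 80.0), hrm_config)
        shifted = normalize_curve(sigmoid_curve("shift", 80.5), hrm_config)
        diffs = difference_curves([ref, same, shifted], "ref")
        assert np.abs(diffs["shift"]).max() > np.abs(diffs["same"]).max()

    def test_missing_reference(self, hrm_config):
        curves = [normalize_curve(sigmoid_curve("a", 80.0), hrm_config)]
        with pytest.raises(KeyError):
            difference_curves(curves, "nope")


class TestClustering:
    def test_identical_curves_one_cluster_full_confidence(self, hrm_config):
        curves = [normalize_curve(sigmoid_curve(f"s{i}", 80.0), hrm_config)
                  for i in range(6)]
        result = cluster_curves(curves, hrm_config)
        assert result.n_clusters == 1
        assert all(c == pytest.approx(100.0) for c in result.confidence.values())

    def test_two_tm_groups_recovered(self):
        # melt region set around the transition, as in practice: baselines
        # fitted close to the curve keep replicate Tm estimates tight
        config = HRMConfig(pre_melt_window=(75.0, 77.0),
                           post_melt_window=(84.0, 86.0))
        rng = np.random.default_rng(42)
        curves = []
        for i in range(3):
            curves.append(sigmoid_curve(f"a{i}", 80.0, noise_sd=0.3, rng=rng))
        for i in range(3):
            curves.append(sigmoid_curve(f"b{i}", 80.5, noise_sd=0.3, rng=rng))
        normalized = [normalize_curve(c, config) for c in curves]
        result = cluster_curves(normalized, config)
        assert result.n_clusters == 2
        a = {result.labels[f"a{i}"] for i in range(3)}
        b = {result.labels[f"b{i}"] for i in range(3)}
        assert len(a) == 1 and len(b) == 1 and a != b
        # every cross-group Tm gap respects the threshold (brute check)
        tms = {nc.sample_id: nc.tm_est for nc in normalized}
        for i in range(3):
            for j in range(3):
                assert abs(tms[f"a{i}"] - tms[f"b{j}"]) >= config.tm_diff_threshold

    def test_confidences_sum_to_100_per_sample(self, hrm_config):
        rng = np.random.default_rng(9)
        curves = [sigmoid_curve(f"s{i}", 79.0 + 0.6 * (i % 3), noise_sd=0.3, rng=rng)
                  for i in range(9)]
        result = cluster_curves([normalize_curve(c, hrm_config) for c in curves],
                                hrm_config)
        for vec in result.confidence_matrix.values():
            assert vec.sum() == pytest.approx(100.0, abs=1e-6)

    def test_permutation_invariance(self, hrm_config):
        rng = np.random.default_rng(10)
        curves = [sigmoid_curve(f"s{i}", 79.0 + 0.5 * (i % 4), noise_sd=0.2, rng=rng)
                  for i in range(8)]
        normalized = [normalize_curve(c, hrm_config) for c in curves]
        fwd = cluster_curves(normalized, hrm_config)
        rev = cluster_curves(list(reversed(normalized)), hrm_config)
        assert fwd.labels == rev.labels

    def test_knob_monotonicity(self, hrm_config):
        rng = np.random.default_rng(12)
        curves = [sigmoid_curve(f"s{i}", 79.0 + 0.3 * i, noise_sd=0.2, rng=rng)
                  for i in range(8)]
        normalized = [normalize_curve(c, hrm_config) for c in curves]

        def n_clusters(sens):
            cfg = HRMConfig(shape_sensitivity=sens)
            return cluster_curves(normalized, cfg).n_clusters

        assert n_clusters(90) >= n_clusters(75) >= n_clusters(40)

        def n_stage1(threshold):
            cfg = HRMConfig(tm_diff_threshold=threshold, shape_sensitivity=0)
            return cluster_curves(normalized, cfg).n_clusters

        assert n_stage1(0.1) >= n_stage1(0.4) >= n_stage1(1.0)

    def test_single_curve_rejected(self, hrm_config):
        nc = normalize_curve(sigmoid_curve("only", 80.0), hrm_config)
        with pytest.raises(ValueError):
            cluster_curves([nc], hrm_config)

    def test_reference_labels_inherited_by_majority(self, hrm_config):
        rng = np.random.default_rng(14)
        curves = ([sigmoid_curve(f"a{i}", 79.0, noise_sd=0.2, rng=rng) for i in range(3)]
                  + [sigmoid_curve(f"b{i}", 81.0, noise_sd=0.2, rng=rng) for i in range(3)])
        normalized = [normalize_curve(c, hrm_config) for c in curves]
        labels = {f"a{i}": "alpha" for i in range(3)} | {f"b{i}": "beta" for i in range(3)}
        result = cluster_curves(normalized, hrm_config, reference_labels=labels,
                                reference_group="alpha")
        assert set(result.cluster_labels.values()) == {"alpha", "beta"}
        assert result.cluster_labels[result.reference_cluster] == "alpha"


class TestAssignUnknown:
    def _reference(self, config, rng):
        curves = []
        labels = {}
        for g, tm in (("A", 79.0), ("B", 80.0), ("C", 81.0)):
            for i in range(3):
                sid = f"{g}{i}"
                curves.append(normalize_curve(
                    sigmoid_curve(sid, tm, noise_sd=0.2, rng=rng), config))
                labels[sid] = g
        return curves, cluster_curves(curves, config, reference_labels=labels)

    def test_known_curve_recovers_its_label(self, hrm_config):
        rng = np.random.default_rng(20)
        curves, result = self._reference(hrm_config, rng)
        unknown = normalize_curve(sigmoid_curve("unk", 80.0, noise_sd=0.2, rng=rng),
                                  hrm_config)
        call = assign_unknown(unknown, curves, result, hrm_config)
        assert call.call == "B"
        assert call.confidence >= 95.0

    def test_new_variant_unassigned(self, hrm_config):
        rng = np.random.default_rng(22)
        curves, result = self._reference(hrm_config, rng)
        unknown = normalize_curve(sigmoid_curve("unk", 81.6, noise_sd=0.2, rng=rng),
                                  hrm_config)
        call = assign_unknown(unknown, curves, result, hrm_config)
        assert call.call == UNASSIGNED
        assert call.evidence["nearest_label"] == "C"

    def test_midpoint_curve_low_confidence_deterministic(self):
        config = HRMConfig(tm_diff_threshold=5.0)  # force shape-only split
        a = normalize_curve(sigmoid_curve("a0", 79.0), config)
        a2 = normalize_curve(sigmoid_curve("a1", 79.0), config)
        b = normalize_curve(sigmoid_curve("b0", 81.0), config)
        b2 = normalize_curve(sigmoid_curve("b1", 81.0), config)
        curves = [a, a2, b, b2]
        labels = {"a0": "A", "a1": "A", "b0": "B", "b1": "B"}
        result = cluster_curves(curves, config, reference_labels=labels)
        mid_values = (a.values + b.values) / 2
        unknown = type(a)(sample_id="mid", temperatures=a.temperatures,
                          values=mid_values,
                          tm_est=float(np.interp(50.0, mid_values[::-1],
                                                 a.temperatures[::-1])))
        call = assign_unknown(unknown, curves, result, config)
        assert call.call == UNASSIGNED
        again = assign_unknown(unknown, curves, result, config)
        assert call.evidence["nearest_cluster"] == again.evidence["nearest_cluster"]

    def test_grid_mismatch_rejected(self, hrm_config):
        rng = np.random.default_rng(24)
        curves, result = self._reference(hrm_config, rng)
        other = normalize_curve(
            sigmoid_curve("unk", 80.0, grid=(65.0, 95.0, 0.4)),
            HRMConfig(grid=(65.0, 95.0, 0.4)))
        with pytest.raises(ValueError):
            assign_unknown(other, curves, result, hrm_config)


class TestReferencePanelFixture:
    def test_six_groups_separate_with_high_confidence(self, genomes, primers,
                                                      hrm_config):
        """Triplicate curves of the 113 bp cytb fragment cluster by group."""
        rng = np.random.default_rng(33)
        curves = []
        labels = {}
        for code in ("PpG", "PpI", "Pm", "Pc", "Pe", "Dg"):
            amp = amplify(genomes[code], primers["HRMcytbF2"], primers["HRMcytbR1"])[0]
            base = simulate_melt_curve(amp.sequence, sample_id=code)
            temps = base.temperatures
            for rep in range(3):
                raw = 0.9 * base.fluorescence + 10 + rng.normal(0, 0.3, len(temps))
                sid = f"{code}_r{rep}"
                curves.append(normalize_curve(
                    MeltCurve(sid, temps, np.clip(raw, 0, None)), hrm_config))
                labels[sid] = code
        result = cluster_curves(curves, hrm_config, reference_labels=labels)
        assert result.n_clusters == 6
        assert set(result.cluster_labels.values()) == {"PpG", "PpI", "Pm",
                                                       "Pc", "Pe", "Dg"}
        assert min(result.confidence.values()) >= 95.0
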