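"""Connectivity measures, class-conditioned adjacency, and normalization."""

import numpy as np
import pytest

from tsann import (
    ConnectivityConfig,
    build_task_adjacency,
    coherence_matrix,
    connectivity_matrix,
    normalize_adjacency,
    pearson_matrix,
    pli_matrix,
    plv_matrix,
    select_by_label,
)
from tsann.connectivity import (
    pli_from_phase_difference,
    plv_from_phase_difference,
)

from conftest import make_trial, sine_trial

CFG = ConnectivityConfig()


class TestPearson:
    def test_scaled_and_negated_copies(self, rng):
        x = rng.standard_normal(500)
        trial = make_trial([x, 2 * x, -x])
        r = pearson_matrix(trial)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_four_point_hand_oracle(self):
        # r computed directly from the covariance definition on these points
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 8.0])
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = cov / (x.std() * y.std())
        trial = make_trial([x, y], fs=4.0)
        assert pearson_matrix(trial)[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_channel_warns_not_raises(self, rng):
        trial = make_trial([rng.standard_normal(100), np.zeros(100)])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = pearson_matrix(trial)
        assert r[0, 1] == 0.0 and r[1, 1] == 1.0


class TestCoherence:
    def test_identical_channels_give_one(self, rng):
        x = rng.standard_normal(1280)
        c = coherence_matrix(make_trial([x, x.copy()]), CFG)
        assert c[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_single_welch_segment_degenerates_to_one(self, rng):
        # with one segment |S_ab|^2 = S_aa S_bb identically
        trial = make_trial(rng.standard_normal((2, 1280)))
        cfg = ConnectivityConfig(method="coh", welch_seg_s=10.0)
        assert coherence_matrix(trial, cfg)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_against_independent_periodogram_oracle(self, rng):
        """Band-averaged coherence of coupled sinusoids + noise matches a
        from-scratch periodogram-averaging implementation."""
        fs, n = 128.0, 1280
        t = np.arange(n) / fs
        s = np.sin(2 * np.pi * 10 * t)
        x = s + rng.standard_normal(n) * np.sqrt(0.1)
        y = s + rng.standard_normal(n) * np.sqrt(0.1)
        got = coherence_matrix(make_trial([x, y]), CFG)[0, 1]

        # oracle: Hann-windowed 50%-overlap segment averaging, written plainly
        nseg, step = 128, 64
        win = np.hanning(nseg)
        sxx = syy = sxy = 0.0
        starts = range(0, n - nseg + 1, step)
        for s0 in starts:
            fx = np.fft.rfft((x[s0 : s0 + nseg] - x[s0 : s0 + nseg].mean()) * win)
            fy = np.fft.rfft((y[s0 : s0 + nseg] - y[s0 : s0 + nseg].mean()) * win)
            sxx = sxx + np.abs(fx) ** 2
            syy = syy + np.abs(fy) ** 2
            sxy = sxy + fx * np.conj(fy)
        freqs = np.fft.rfftfreq(nseg, 1 / fs)
        coh = np.abs(sxy) ** 2 / (sxx * syy)
        keep = (freqs >= 4.0) & (freqs <= 45.0)
        assert got == pytest.approx(coh[keep].mean(), abs=0.05)

    def test_empty_band_errors(self, rng):
        trial = make_trial(rng.standard_normal((2, 1280)))
        with pytest.raises(ValueError, match="no frequency bins"):
            coherence_matrix(trial, ConnectivityConfig(method="coh", band=(30.2, 30.3)))


class TestPhaseIndices:
    def test_plv_constant_offset_is_one(self):
        trial = sine_trial([(10, 0.0), (10, 0.5)])
        assert plv_matrix(trial, CFG)[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_pli_zero_lag_is_zero(self):
        trial = sine_trial([(10, 0.0), (10, 0.0)])
        assert pli_matrix(trial, CFG)[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_pli_quarter_cycle_lag_is_one(self):
        trial = sine_trial([(10, 0.0), (10, np.pi / 2)])
        assert pli_matrix(trial, CFG)[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_alternating_phase_difference_cancels(self):
        # dphi alternating 0 / pi: phasors cancel pairwise
        dphi = np.tile([0.0, np.pi], 500)
        assert plv_from_phase_difference(dphi) == pytest.approx(0.0, abs=1e-12)
        # dphi alternating +pi/2 / -pi/2: signs cancel by symmetry
        dphi = np.tile([np.pi / 2, -np.pi / 2], 500)
        assert pli_from_phase_difference(dphi) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_phases_give_small_plv(self, rng):
        n = 10**5
        dphi = rng.uniform(-np.pi, np.pi, size=n)
        # E|mean phasor| ~ sqrt(pi/(4n)); 0.02 is many sigma above
        assert plv_from_phase_difference(dphi) <= 0.02

    def test_matrix_path_agrees_with_scalar_helpers(self, rng):
        from tsann.connectivity import _analytic_phase, phase_difference

        trial = make_trial(rng.standard_normal((3, 1280)))
        phi = _analytic_phase(trial, CFG)
        plv = plv_matrix(trial, CFG)
        pli = pli_matrix(trial, CFG)
        for a in range(3):
            for b in range(a + 1, 3):
                d = phase_difference(phi[a], phi[b])
                assert plv[a, b] == pytest.approx(plv_from_phase_difference(d), abs=1e-9)
                assert pli[a, b] == pytest.approx(pli_from_phase_difference(d), abs=1e-9)

    def test_too_short_for_phase_analysis(self, rng):
        trial = make_trial(rng.standard_normal((2, 256)))  # 2 s at 128 Hz
        with pytest.raises(ValueError, match="too short"):
            plv_matrix(trial, CFG)

    def test_independent_signals_both_indices_small(self, rng):
        """For independent noise both indices are near 0; in ensemble mean the
        phasor average (PLV) exceeds the sign average (PLI)."""
        plvs, plis = [], []
        for _ in range(40):
            trial = make_trial(rng.standard_normal((2, 1280)))
            plvs.append(plv_matrix(trial, CFG)[0, 1])
            plis.append(pli_matrix(trial, CFG)[0, 1])
        assert max(plvs) < 0.25 and max(plis) < 0.25
        assert np.mean(plvs) < 0.15 and np.mean(plis) < 0.15


@pytest.mark.parametrize("method", ["cor", "coh", "plv", "pli"])
class TestMatrixInvariants:
    def _matrix(self, trial, method):
        return connectivity_matrix(trial, ConnectivityConfig(method=method))

    def test_symmetry_and_range(self, rng, method):
        trial = make_trial(rng.standard_normal((4, 1280)))
        m = self._matrix(trial, method)
        np.testing.assert_allclose(m, m.T, atol=1e-10)
        if method == "cor":
            assert (m >= -1 - 1e-12).all() and (m <= 1 + 1e-12).all()
        else:
            assert (m >= 0).all() and (m <= 1 + 1e-12).all()

    def test_channel_permutation_equivariance(self, rng, method):
        trial = make_trial(rng.standard_normal((5, 1280)))
        m = self._matrix(trial, method)
        perm = rng.permutation(5)
        permuted = make_trial(trial.data[perm])
        mp = self._matrix(permuted, method)
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-9)


class TestSelectByLabel:
    def test_order_preserved(self, rng):
        trials = [make_trial(rng.standard_normal((2, 16)), label=l, trial_id=f"t{i}")
                  for i, l in enumerate(["l1", "l2", "l1", "l2", "l1"])]
        sel = select_by_label(trials, "l1")
        assert [t.trial_id for t in sel] == ["t0", "t2", "t4"]

    def test_unknown_label_errors(self, rng):
        trials = [make_trial(rng.standard_normal((2, 16)), label="l1")]
        with pytest.raises(ValueError, match="no data"):
            select_by_label(trials, "l9")

    def test_counts(self, rng):
        trials = [make_trial(rng.standard_normal((2, 16)), label="l2" if i < 7 else "l1",
                             trial_id=f"s{i}") for i in range(12)]
        assert len(select_by_label(trials, "l2")) == 7


class TestTaskAdjacency:
    def test_single_segment_mean_is_identity_of_mean(self, rng):
        segs = [make_trial(rng.standard_normal((3, 1280)), label=l, trial_id=l)
                for l in ("l1", "l2")]
        cfg = ConnectivityConfig(method="cor")
        ta = build_task_adjacency(segs, cfg)
        for lab, seg in zip(("l1", "l2"), segs):
            expected = np.abs(pearson_matrix(seg))
            np.fill_diagonal(expected, 1.0)
            np.testing.assert_allclose(ta.adj[lab], expected, atol=1e-12)

    def test_duplicated_segment_idempotent(self, rng):
        base = make_trial(rng.standard_normal((3, 1280)), label="l1", trial_id="a")
        twin = make_trial(base.data.copy(), label="l1", trial_id="b")
        other = make_trial(rng.standard_normal((3, 1280)), label="l2", trial_id="c")
        cfg = ConnectivityConfig(method="plv")
        one = build_task_adjacency([base, other], cfg)
        two = build_task_adjacency([base, twin, other], cfg)
        np.testing.assert_allclose(one.adj["l1"], two.adj["l1"], atol=1e-12)

    def test_two_known_matrices_average_entrywise(self, rng):
        m1 = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        m2 = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.2], [0.0, 0.2, 1.0]])
        segs = [make_trial(rng.standard_normal((3, 1280)), label=l, trial_id=f"x{i}")
                for i, l in enumerate(["l1", "l1", "l2"])]
        mats = np.stack([m1, m2, m1])
        ta = build_task_adjacency(segs, ConnectivityConfig(method="plv"), matrices=mats)
        np.testing.assert_allclose(ta.adj["l1"], (m1 + m2) / 2, atol=1e-12)

    def test_absent_class_errors(self, rng):
        segs = [make_trial(rng.standard_normal((3, 1280)), label="l1", trial_id="a")]
        with pytest.raises(ValueError):
            build_task_adjacency(segs, ConnectivityConfig(method="cor"), labels=("l1", "l2"))


class TestNormalizeAdjacency:
    def test_identity_fixed_point(self):
        np.testing.assert_allclose(normalize_adjacency(np.eye(4)), np.eye(4))

    def test_all_ones_two_by_two(self):
        np.testing.assert_allclose(normalize_adjacency(np.ones((2, 2))), np.full((2, 2), 0.5))

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(100):
            c = int(rng.integers(2, 8))
            a = np.abs(rng.standard_normal((c, c)))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            deg = a.sum(axis=1)
            expected = np.empty_like(a)
            for i in range(c):
                for j in range(c):
                    expected[i, j] = a[i, j] / np.sqrt(deg[i] * deg[j])
            np.testing.assert_allclose(normalize_adjacency(a), expected, atol=1e-12)

    def test_zero_row_sum_names_channel(self):
        a = np.eye(3)
        a[1, 1] = 0.0
        with pytest.raises(ValueError, match="1"):
            normalize_adjacency(a)

    def test_rejects_asymmetric_and_negative(self, rng):
        bad = np.abs(rng.standard_normal((3, 3)))
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(bad)
        a = np.eye(3)
        a[0, 1] = a[1, 0] = -0.5
        with pytest.raises(ValueError, match="nonnegative"):
            normalize_adjacency(a)
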