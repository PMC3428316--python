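"""Penalized segmentation: closed forms, DP optimality against exhaustive
enumeration, joint-objective behavior."""

import numpy as np
import pytest

from bruteforce import brute_joint, brute_single, coupled_block_cost
from conftest import make_noiseless_config
from rulerarray.config import PreprocessParams, SegmentationParams
from rulerarray.preprocess import build_track
from rulerarray.segmentation import (
    fit_genome,
    segment_channel,
    segment_joint,
    wls_line_fit,
)
from rulerarray.synthetic_data import simulate_experiment


class TestWlsLineFit:
    def test_two_points_interpolate(self):
        slope, intercept, wrss = wls_line_fit([0.0, 2.0], [1.0, 5.0], [1.0, 1.0])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert wrss == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_any_weights(self, rng):
        x = np.sort(rng.uniform(0, 100, size=20))
        y = -0.3 * x + 7.0
        w = rng.uniform(0.1, 5.0, size=20)
        slope, intercept, wrss = wls_line_fit(x, y, w)
        assert slope == pytest.approx(-0.3, abs=1e-10)
        assert intercept == pytest.approx(-0.3 * x[0] + 7.0, abs=1e-9)
        assert wrss == pytest.approx(0.0, abs=1e-9)

    def test_hand_solved_example(self):
        # x=[0,1,2], y=[0,1,0], equal weights: slope 0, mean 1/3, wrss 2/3
        slope, intercept, wrss = wls_line_fit([0.0, 1.0, 2.0], [0.0, 1.0, 0.0],
                                              [1.0, 1.0, 1.0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(1.0 / 3.0)
        assert wrss == pytest.approx(2.0 / 3.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wls_line_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [1.0, 1.0, 1.0])


def _random_instance(rng, n, with_step=True):
    x = np.cumsum(rng.uniform(0.5, 2.0, size=n))
    y = 0.4 * x + rng.normal(scale=0.5, size=n)
    if with_step and n >= 6:
        k = int(rng.integers(2, n - 2))
        y[k:] += rng.normal() * 2.0
    w = rng.uniform(0.3, 3.0, size=n)
    return x, y, w


class TestSegmentChannel:
    def test_linear_noiseless_one_segment(self):
        x = np.arange(20.0)
        y = 1.0 - 0.1 * x
        fit = segment_channel(x, y, np.ones(20), lam=0.5, min_probes=2)
        assert len(fit.segments["A"]) == 1
        assert fit.boundaries["A"] == []

    def test_step_found_at_known_boundary(self, rng):
        x = np.arange(20.0)
        y = np.where(x < 11, 0.0, 2.0) + rng.normal(scale=0.05, size=20)
        fit = segment_channel(x, y, np.full(20, 1 / 0.1 ** 2), lam=3.0, min_probes=2)
        assert len(fit.segments["A"]) == 2
        assert fit.boundaries["A"] == [11]

    def test_huge_penalty_one_segment(self, rng):
        x, y, w = _random_instance(rng, 14)
        fit = segment_channel(x, y, w, lam=1e9, min_probes=2)
        assert len(fit.segments["A"]) == 1

    def test_tiny_instance_degenerate_flag(self):
        fit = segment_channel(np.array([0.0]), np.array([1.0]), np.array([1.0]),
                              lam=1.0, min_probes=2)
        assert fit.segments["A"][0].degenerate

    def test_dp_equals_brute_force(self, rng):
        """DP cost equals the exhaustive minimum on 200 random instances
        with up to 14 probes."""
        for i in range(200):
            n = int(rng.integers(4, 15))
            lam = float(rng.uniform(0.3, 5.0))
            mp = int(rng.integers(2, 4))
            x, y, w = _random_instance(rng, n)
            fit = segment_channel(x, y, w, lam=lam, min_probes=mp)
            brute = brute_single(x, y, w, lam, mp)
            assert fit.cost == pytest.approx(brute, rel=1e-9, abs=1e-9)

    def test_monotone_in_lambda(self, rng):
        x, y, w = _random_instance(rng, 30)
        counts = [len(segment_channel(x, y, w, lam=lam, min_probes=2).segments["A"])
                  for lam in (0.1, 0.5, 1.0, 3.0, 10.0, 100.0)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, rng):
        x, y, w = _random_instance(rng, 25)
        f1 = segment_channel(x, y, w, lam=2.0, min_probes=2)
        f2 = segment_channel(x, y, w, lam=2.0, min_probes=2)
        assert f1.cost == f2.cost
        assert f1.boundaries == f2.boundaries
        assert all(s1.slope == s2.slope for s1, s2 in
                   zip(f1.segments["A"], f2.segments["A"]))


class TestSegmentJoint:
    def test_identical_channels_identical_fit(self, rng):
        x, y, w = _random_instance(rng, 16)
        fit = segment_joint(x, y, y, w, w, lam=2.0, delta=1.0, kappa=10.0,
                            min_probes=2)
        assert fit.boundaries["A"] == fit.boundaries["B"]
        assert fit.shared == fit.boundaries["A"]

    def test_step_in_one_channel_only(self, rng):
        """Channel B carries a step in its right half; A stays linear: the
        joint fit gives one segment in A, two in B (verified by brute
        force below on the same kind of instance)."""
        x = np.arange(16.0)
        ya = 0.1 * x
        yb = 0.1 * x + np.where(x < 8, 0.0, 3.0)
        w = np.full(16, 1 / 0.1 ** 2)
        fit = segment_joint(x, ya, yb, w, w, lam=3.0, delta=1.0, kappa=1.0,
                            min_probes=2)
        assert len(fit.segments["A"]) == 1
        assert len(fit.segments["B"]) == 2
        assert fit.boundaries["B"] == [8]
        brute = brute_joint(x, ya, yb, w, w, 3.0, 1.0, 1.0, 2)
        assert fit.cost == pytest.approx(brute, rel=1e-9)

    def test_strong_coupling_precision_weighted_slope(self):
        """kappa -> infinity forces both slopes to the precision-weighted
        mean slope."""
        x = np.arange(10.0)
        ya = 0.2 * x
        yb = 0.6 * x
        wa = np.full(10, 4.0)
        wb = np.full(10, 1.0)
        # a large per-segment penalty pins both channels to one segment,
        # so the aligned coupled fit is exercised
        fit = segment_joint(x, ya, yb, wa, wb, lam=1e6, delta=0.0, kappa=1e12,
                            min_probes=2)
        sa = fit.segments["A"][0].slope
        sb = fit.segments["B"][0].slope
        vxx_a = (wa * (x - x.mean()) ** 2).sum()
        vxx_b = (wb * (x - x.mean()) ** 2).sum()
        expected = (0.2 * vxx_a + 0.6 * vxx_b) / (vxx_a + vxx_b)
        assert sa == pytest.approx(sb, abs=1e-6)
        assert sa == pytest.approx(expected, abs=1e-6)

    def test_dp_equals_brute_force_joint(self, rng):
        """Joint DP cost equals the exhaustive minimum over both channels'
        boundary placements and sharing structures, 50 instances, n<=10."""
        for i in range(50):
            n = int(rng.integers(4, 11))
            lam = float(rng.uniform(0.5, 4.0))
            delta = float(rng.uniform(0.0, lam))
            kappa = float(rng.choice([0.0, 0.5, 5.0]))
            x, ya, wa = _random_instance(rng, n)
            _, yb, wb = _random_instance(rng, n)
            yb = yb + 0.3 * ya  # correlate the channels a little
            fit = segment_joint(x, ya, yb, wa, wb, lam=lam, delta=delta,
                                kappa=kappa, min_probes=2)
            brute = brute_joint(x, ya, yb, wa, wb, lam, delta, kappa, 2)
            assert fit.cost == pytest.approx(brute, rel=1e-9, abs=1e-9)

    def test_intercept_shift_changes_nothing_but_intercepts(self, rng):
        """Adding a constant to one channel moves intercepts only: the
        boundaries and slopes are unchanged for any coupling strength
        (intercepts are deliberately uncoupled)."""
        x, ya, wa = _random_instance(rng, 20)
        _, yb, wb = _random_instance(rng, 20)
        for kappa in (0.0, 50.0):
            f1 = segment_joint(x, ya, yb, wa, wb, lam=2.0, delta=1.0,
                               kappa=kappa, min_probes=2)
            f2 = segment_joint(x, ya, yb + 5.0, wa, wb, lam=2.0, delta=1.0,
                               kappa=kappa, min_probes=2)
            assert f1.boundaries == f2.boundaries
            for s1, s2 in zip(f1.segments["B"], f2.segments["B"]):
                assert s1.slope == pytest.approx(s2.slope, abs=1e-9)
                assert s2.intercept - s1.intercept == pytest.approx(5.0, abs=1e-9)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="probe grid"):
            segment_joint(np.arange(5.0), np.zeros(5), np.zeros(4),
                          np.ones(5), np.ones(4), lam=1.0, delta=0.5, kappa=0.0)

    def test_coupled_block_oracle_agreement(self, rng):
        """The closed-form 2x2 coupled fit agrees with the assembled
        4-parameter normal equations."""
        x, ya, wa = _random_instance(rng, 8, with_step=False)
        _, yb, wb = _random_instance(rng, 8, with_step=False)
        fit = segment_joint(x, ya, yb, wa, wb, lam=100.0, delta=0.0, kappa=3.0,
                            min_probes=2)
        assert len(fit.segments["A"]) == 1 == len(fit.segments["B"])
        oracle = coupled_block_cost(x, ya, yb, wa, wb, 3.0)
        assert fit.cost == pytest.approx(oracle + 200.0, rel=1e-9)


class TestFitGenome:
    def _track(self, cfg, variants=()):
        sim = simulate_experiment(cfg, list(variants))
        return sim, build_track(sim.probes, sim.intensities, sim.sites_ref,
                                PreprocessParams())

    def test_intervals_counted_and_short_ones_skipped(self):
        cfg = make_noiseless_config()
        sim, track = self._track(cfg)
        fits = fit_genome(track, SegmentationParams())
        n_iv = len(np.unique(track.interval_id))
        short = sum(1 for iv in np.unique(track.interval_id)
                    if (track.interval_id == iv).sum() < 2)
        assert len(fits) == n_iv - short
        # fitted ranges tile the track without overlap
        for f in fits:
            assert f.probe_end - f.probe_start >= 2

    def test_noiseless_one_sided_interval_single_shared_segment(self):
        """A noiseless, linear (one-side-dominated) interval is fitted by
        one segment per channel with no private boundaries."""
        import numpy as np
        from rulerarray.ruler_model import ExtensionModel, expected_log_profile
        x = np.arange(250.0, 3000.0, 250.0)
        m = ExtensionModel(0.001, "include_runoff", 0.0)
        y = expected_log_profile(x, [0], m)
        w = np.full(x.size, 1e4)
        fit = segment_joint(x, y, y, w, w, lam=3.0, delta=1.5, kappa=1e6,
                            min_probes=2)
        assert len(fit.segments["A"]) == 1 == len(fit.segments["B"])
        assert fit.segments["A"][0].slope == pytest.approx(np.log2(0.999), rel=1e-6)
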