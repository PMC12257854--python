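"""Boundary detection: sub-pixel accuracy, DP optimality, determinism."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sclsettle.errors import SegmentationError
from sclsettle.geometry import CorneaModel
from sclsettle.render import ScanProtocol, render_bscan
from sclsettle.segmentation import (
    DEFAULT_PARAMS,
    detect_boundaries,
    min_cost_path,
    resize_for_segmentation,
    segment_frame,
)


def dp_reference(cost, lam, max_step):
    """Plain-loop dynamic program over the same path model (test oracle)."""
    rows, cols = cost.shape
    D = [cost[r, 0] for r in range(rows)]
    back = [[0] * cols for _ in range(rows)]
    for c in range(1, cols):
        newD = [None] * rows
        for r in range(rows):
            best, bstep = None, None
            for d in range(max_step, -max_step - 1, -1):
                p = r - d
                if 0 <= p < rows:
                    val = D[p] + lam * d * d
                    if best is None or val < best:
                        best, bstep = val, d
            newD[r] = best + cost[r, c]
            back[r][c] = bstep
        D = newD
    end = int(np.argmin(D))
    path = [0] * cols
    path[-1] = end
    for c in range(cols - 1, 0, -1):
        path[c - 1] = path[c] - back[path[c]][c]
    return np.array(path)


def brute_force_enumeration(cost, lam, max_step):
    """Exhaustive enumeration over all feasible paths (tiny images only)."""
    rows, cols = cost.shape
    best_cost, best_path = None, None
    for path in itertools.product(range(rows), repeat=cols):
        if any(abs(path[c] - path[c - 1]) > max_step for c in range(1, cols)):
            continue
        total = sum(cost[path[c], c] for c in range(cols)) + sum(
            lam * (path[c] - path[c - 1]) ** 2 for c in range(1, cols)
        )
        if best_cost is None or total < best_cost - 1e-12:
            best_cost, best_path = total, path
    return np.array(best_path), best_cost


@pytest.fixture
def frame_pair():
    cornea = CorneaModel(apical_radius=7.8, asphericity=-0.25)
    field = lambda x, y: 350.0 + 15.0 * np.asarray(y)  # noqa: E731

    def make(noise, seed=5, meridian=90.0):
        protocol = ScanProtocol(noise_level=noise)
        return render_bscan(cornea, field, meridian, protocol, seed=seed)

    return make


class TestMinCostPath:
    @given(st.integers(0, 10_000))
    def test_vectorized_dp_matches_reference_dp(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.normal(size=(14, 9))
        path = min_cost_path(cost, 0.05, 3)
        ref = dp_reference(cost, 0.05, 3)
        assert np.array_equal(path, ref)

    @given(st.integers(0, 2_000))
    def test_dp_equals_exhaustive_enumeration_on_tiny_images(self, seed):
        rng = np.random.default_rng(seed)
        cost = rng.normal(size=(6, 5))
        lam, step = 0.1, 2
        path = min_cost_path(cost, lam, step)
        bf_path, bf_cost = brute_force_enumeration(cost, lam, step)
        got = sum(cost[path[c], c] for c in range(cost.shape[1])) + sum(
            lam * (path[c] - path[c - 1]) ** 2 for c in range(1, cost.shape[1])
        )
        assert got == pytest.approx(bf_cost, abs=1e-9)

    def test_tie_break_prefers_smaller_row(self):
        cost = np.zeros((5, 4))  # all paths cost 0 with zero penalty
        path = min_cost_path(cost, 0.0, 2)
        assert np.array_equal(path, np.zeros(4, dtype=int))


class TestResize:
    def test_identity_for_square_input(self):
        img = np.zeros((512, 512))
        work, tr = resize_for_segmentation(img)
        assert tr.identity and work is img

    def test_anisotropic_roundtrip_is_exact(self, rng):
        img = rng.random((1024, 2048))
        work, tr = resize_for_segmentation(img)
        assert work.shape == (512, 512)
        assert tr.row_scale == 2.0 and tr.col_scale == 4.0
        r, c = rng.random(50) * 511, rng.random(50) * 511
        ro, co = tr.to_original(r, c)
        rb, cb = tr.to_working(ro, co)
        assert np.max(np.abs(rb - r)) < 1e-9
        assert np.max(np.abs(cb - c)) < 1e-9


class TestDetectBoundaries:
    def test_noise_free_error_below_half_pixel(self, frame_pair):
        frame, truth = frame_pair(0.0)
        pair = segment_frame(frame)
        ok = pair.valid & np.isfinite(truth.lens_back_rows)
        assert ok.sum() > 300
        for det, gt in (
            (pair.lens_back_rows, truth.lens_back_rows),
            (pair.cornea_front_rows, truth.cornea_front_rows),
        ):
            assert np.mean(np.abs(det[ok] - gt[ok])) < 0.5

    def test_default_noise_error_and_validity(self, frame_pair):
        errs, valid_fracs = [], []
        for seed in range(5):
            frame, truth = frame_pair(0.3, seed=seed)
            pair = segment_frame(frame)
            support = np.isfinite(truth.lens_back_rows)
            ok = pair.valid & support
            for det, gt in (
                (pair.lens_back_rows, truth.lens_back_rows),
                (pair.cornea_front_rows, truth.cornea_front_rows),
            ):
                errs.append(np.mean(np.abs(det[ok] - gt[ok])))
            valid_fracs.append(ok.sum() / support.sum())
        assert np.mean(errs) < 1.5
        assert np.mean(valid_fracs) > 0.90

    def test_blank_image_rejected_not_hallucinated(self):
        with pytest.raises(SegmentationError):
            detect_boundaries(np.full((512, 512), 0.2))

    def test_ordering_invariant_on_valid_columns(self, frame_pair):
        frame, _ = frame_pair(0.3, seed=11)
        pair = segment_frame(frame)
        assert np.all(
            pair.lens_back_rows[pair.valid] < pair.cornea_front_rows[pair.valid]
        )

    def test_segmentation_is_deterministic(self, frame_pair):
        frame, _ = frame_pair(0.3, seed=12)
        a = segment_frame(frame)
        b = segment_frame(frame)
        assert np.array_equal(a.lens_back_rows, b.lens_back_rows, equal_nan=True)
        assert np.array_equal(a.cornea_front_rows, b.cornea_front_rows, equal_nan=True)
        assert np.array_equal(a.valid, b.valid)

    def test_anisotropic_frame_recovers_same_thickness(self):
        from sclsettle.reconstruction import boundaries_to_profile

        cornea = CorneaModel(apical_radius=7.8, asphericity=-0.25)
        field = lambda x, y: np.full(np.shape(x), 320.0)  # noqa: E731
        results = {}
        for name, size in (("iso", (512, 512)), ("aniso", (640, 800))):
            protocol = ScanProtocol(noise_level=0.0, image_size=size)
            frame, _ = render_bscan(cornea, field, 0.0, protocol)
            pair = segment_frame(frame)
            prof = boundaries_to_profile(
                pair, frame.axial_pitch_um, frame.lateral_pitch_um,
                frame.frame_width_mm,
            )
            sel = prof.valid & (np.abs(prof.lateral_position_mm) < 5.5)
            results[name] = float(np.mean(prof.thickness_um[sel]))
        assert results["iso"] == pytest.approx(320.0, abs=2.0)
        assert results["aniso"] == pytest.approx(results["iso"], abs=2.0)
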