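"""Video profiling: segmentation, frame metrics, profiles, split endpoint."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odfkit import (
    DisintegrationProfile,
    SegmentationConfig,
    detect_endpoint,
    extract_profile,
    measure_frame,
    render_video,
    segment_frame,
)
from odfkit.scenarios import build_scenario

from conftest import flat_frame, frame_with_rect, jaccard


# ---------------------------------------------------------------------------
# segmentation


def test_background_only_frame_gives_empty_mask(seg_config):
    rng = np.random.default_rng(0)
    frame = flat_frame(120, 160).astype(np.int16)
    frame = np.clip(frame + rng.normal(0, 3, frame.shape), 0, 255).astype(np.uint8)
    assert segment_frame(frame, seg_config).sum() == 0


def test_film_rectangle_area_exact(seg_config):
    frame = frame_with_rect(200, 300, top=40, left=60, rh=50, rw=100)
    mask = segment_frame(frame, seg_config)
    assert mask.sum() == 5000
    assert mask[40:90, 60:160].all()


def test_edge_mode_recovers_rectangle():
    frame = frame_with_rect(120, 160, top=30, left=40, rh=40, rw=60)
    mask = segment_frame(frame, SegmentationConfig(mode="edge"))
    # gradient-based mode is approximate near the boundary
    assert abs(mask.sum() - 2400) < 0.1 * 2400


def test_rejects_empty_or_non_rgb_frames(seg_config):
    with pytest.raises(ValueError):
        segment_frame(np.zeros((0, 0, 3), dtype=np.uint8), seg_config)
    with pytest.raises(ValueError):
        segment_frame(np.zeros((10, 10), dtype=np.uint8), seg_config)


def test_segmentation_matches_ground_truth_masks(small_render, seg_config):
    """Pipeline masks agree with the generator's rasters (Jaccard >= 0.95)
    and areas agree within 5% — including compression-artifact frames."""
    scn = build_scenario("P1", "ocm", {"duration_s": 30.0})
    seq = render_video(scn, seed=1, config=small_render)
    for i in range(0, len(seq), 23):  # stride co-prime with the 2 s artifact period
        gt = seq.mask(i)
        est = segment_frame(seq.frame(i), seg_config)
        assert jaccard(est, gt) >= 0.95
        assert abs(int(est.sum()) - int(gt.sum())) < 0.05 * max(gt.sum(), 1)


# ---------------------------------------------------------------------------
# frame metrics


def test_empty_mask_measures_zero():
    m = measure_frame(np.zeros((20, 20), dtype=bool))
    assert (m.area_px, m.perimeter_px, m.n_fragments, m.largest_fragment_area_px) == (0, 0.0, 0, 0)


@pytest.mark.parametrize(("h", "w"), [(10, 10), (5, 20), (30, 7)])
def test_rectangle_perimeter_contour_walk_oracle(h, w):
    """Outer contour through boundary-pixel centres: a filled h x w rectangle
    measures 2(h-1) + 2(w-1)."""
    mask = np.pad(np.ones((h, w), dtype=bool), 3)
    m = measure_frame(mask)
    assert m.perimeter_px == pytest.approx(2 * (h - 1) + 2 * (w - 1))
    assert m.area_px == h * w
    assert m.n_fragments == 1


def test_two_fragments_counted_and_summed():
    mask = np.zeros((60, 60), dtype=bool)
    mask[5:25, 5:25] = True
    mask[35:55, 35:55] = True
    m = measure_frame(mask, min_fragment_px=10)
    assert m.n_fragments == 2
    assert m.area_px == 800
    assert m.largest_fragment_area_px == 400


def test_min_fragment_filters_specks():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5:25, 5:25] = True  # 400 px film
    mask[35, 35] = True  # 1 px speck
    m = measure_frame(mask, min_fragment_px=10)
    assert m.n_fragments == 1
    assert m.area_px == 400


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    h=st.integers(3, 20),
    w=st.integers(3, 20),
    min_px=st.integers(1, 30),
)
def test_metrics_invariants_hold_for_random_rectangles(h, w, min_px):
    mask = np.pad(np.ones((h, w), dtype=bool), 2)
    m = measure_frame(mask, min_fragment_px=min_px)
    assert m.largest_fragment_area_px <= m.area_px
    assert (m.n_fragments == 0) == (m.area_px == 0)
    if m.n_fragments:
        assert m.area_px == h * w


# ---------------------------------------------------------------------------
# profiles


def test_profile_normalised_to_first_frame(small_render, seg_config):
    scn = build_scenario("C1", "ocm", {"duration_s": 10.0})
    seq = render_video(scn, seed=0, config=small_render)
    prof = extract_profile(seq, seg_config)
    assert prof.area_fraction[0] == 1.0
    assert np.all(np.diff(prof.t_s) > 0)


def test_shrink_scenario_profile_non_increasing(small_render, seg_config):
    scn = build_scenario(
        "P1",
        "ocm",
        {
            "duration_s": 20.0,
            "events": [{"kind": "shrink", "onset_s": 0.0, "params": {"rate_frac_per_s": 0.02}}],
            "censored": True,
            "true_endpoint_s": None,
        },
    )
    seq = render_video(scn, seed=2, config=small_render)
    prof = extract_profile(seq, seg_config)
    # median filtering leaves at most segmentation-noise sized increases
    assert np.all(np.diff(prof.area_fraction) <= 0.005)
    assert prof.area_fraction[-1] < 0.75


def test_event_free_scenario_stays_at_unit_area(small_render, seg_config):
    scn = build_scenario(
        "C1", "ocm", {"duration_s": 10.0, "events": [], "censored": True, "true_endpoint_s": None}
    )
    seq = render_video(scn, seed=3, config=small_render)
    prof = extract_profile(seq, seg_config)
    assert np.allclose(prof.area_fraction, 1.0, atol=0.02)
    assert (prof.n_fragments == 1).all()


def test_p2_transient_tear_area_returns(small_render, seg_config):
    scn = build_scenario("P2", "ocm", {"duration_s": 78.0})
    seq = render_video(scn, seed=1, config=small_render)
    prof = extract_profile(seq, seg_config)
    torn = (prof.t_s > 70.5) & (prof.t_s < 74.5)
    assert prof.area_fraction[torn].min() < 0.995  # area dips while torn
    assert prof.area_fraction[-1] == pytest.approx(1.0, abs=0.02)  # and returns
    ep = detect_endpoint(prof)
    assert ep.censored  # transient tears never count as disintegration


def test_no_film_at_t0_rejected(seg_config):
    frames = [flat_frame(60, 80) for _ in range(4)]
    with pytest.raises(ValueError, match="no film detected"):
        extract_profile(frames, seg_config, fps=10.0)


def test_plain_sequences_need_fps(seg_config):
    frames = [frame_with_rect(60, 80, 10, 10, 20, 30)] * 3
    with pytest.raises(ValueError, match="fps"):
        extract_profile(frames, seg_config)
    prof = extract_profile(frames, seg_config, fps=5.0)
    assert len(prof) == 3


def test_ocm_phase_sampling_reduces_frames(small_render):
    cfg = SegmentationConfig(ocm_phase_sampling=True)
    scn = build_scenario("C2", "ocm", {"duration_s": 20.0})
    seq = render_video(scn, seed=0, config=small_render)
    prof = extract_profile(seq, cfg)
    assert len(prof) == 11  # frame 0 plus one per 2 s compression period
    assert detect_endpoint(prof).censored


# ---------------------------------------------------------------------------
# endpoint detection


def _profile_with_counts(counts, fps=30.0):
    n = len(counts)
    t = np.arange(n) / fps
    area = np.full(n, 1000.0)
    return DisintegrationProfile(
        t_s=t,
        area_px=area,
        perimeter_px=np.full(n, 120.0),
        n_fragments=np.asarray(counts, dtype=int),
        largest_fragment_area_px=area,
        area_fraction=area / area[0] if n else area,
    )


def test_transient_split_shorter_than_persistence_is_ignored():
    counts = [1] * 40 + [2] * 3 + [1] * 40
    res = detect_endpoint(_profile_with_counts(counts), persistence_frames=5)
    assert res.censored


def test_persistent_split_detected_at_first_frame_of_run():
    counts = [1] * 40 + [2] * 30
    res = detect_endpoint(_profile_with_counts(counts), persistence_frames=5)
    assert not res.censored
    assert res.time_s == pytest.approx(40 / 30.0)


def test_p1_ocm_endpoint_recovered_within_two_frames(small_render, seg_config):
    scn = build_scenario("P1", "ocm", {"duration_s": 28.0})
    for seed in (0, 1, 2):
        seq = render_video(scn, seed=seed, config=small_render)
        prof = extract_profile(seq, seg_config)
        res = detect_endpoint(prof)
        assert not res.censored
        assert abs(res.time_s - 24.0) <= 2.0 / small_render.fps


def test_c2_ocm_swell_scenario_censored(small_render, seg_config):
    scn = build_scenario("C2", "ocm", {"duration_s": 24.0})
    seq = render_video(scn, seed=0, config=small_render)
    res = detect_endpoint(extract_profile(seq, seg_config))
    assert res.censored
    assert res.render() == ">180.0"


def test_empty_profile_rejected():
    prof = _profile_with_counts([])
    with pytest.raises(ValueError, match="empty"):
        detect_endpoint(prof)
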