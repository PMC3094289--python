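"""Rendering and image-tracing round trips."""

import numpy as np
import pytest

from pscarbor.morphometry import filter_and_normalize, summarize_arbor
from pscarbor.render import render_stack
from pscarbor.synthgen import sample_arbor
from pscarbor.trace import (
    NoAxonFoundError,
    detect_varicosities,
    extract_tree,
    project_and_segment,
    trace_stack,
)
from pscarbor.types import ArborTree, Branch, RenderParams, TraceParams, Varicosity


def _one_branch_arbor(length=100.0, varicosities=()):
    b = Branch(id="b1", parent_id=None,
               polyline=np.array([[10.0, 50.0], [10.0 + length, 50.0]]),
               varicosities=list(varicosities))
    return ArborTree(entry_point=np.array([10.0, 50.0]), ganglion_width=180.0,
                     branches=[b])


def test_noise_free_straight_branch_round_trips_within_two_microns():
    arbor = _one_branch_arbor(100.0)
    stack = render_stack(arbor, RenderParams(noise_sd=0.0), np.random.default_rng(0))
    mask, _ = project_and_segment(stack)
    from scipy import ndimage
    _, n = ndimage.label(mask)
    assert n == 1
    tree = trace_stack(stack)
    assert len(tree.branches) == 1
    assert tree.branches[0].length == pytest.approx(100.0, abs=2.0)


def test_pure_background_stack_raises_no_axon_found():
    empty = ArborTree(entry_point=np.zeros(2), ganglion_width=180.0, branches=[])
    stack = render_stack(empty, RenderParams(noise_sd=5.0), np.random.default_rng(1))
    with pytest.raises(NoAxonFoundError):
        project_and_segment(stack)


def test_varicosity_projects_brighter_than_the_axon_shaft():
    arbor = _one_branch_arbor(100.0, [Varicosity(50.0, 4.5, 3.0)])
    stack = render_stack(arbor, RenderParams(noise_sd=0.0), np.random.default_rng(2))
    proj = stack.max_projection()
    on_axon = proj[proj > np.median(proj) + 20]
    assert proj.max() > 1.5 * np.median(on_axon)


def test_y_shaped_arbor_traces_to_three_branches_within_5pct():
    trunk = Branch(id="t", parent_id=None,
                   polyline=np.array([[10.0, 50.0], [110.0, 50.0]]))
    d1 = Branch(id="d1", parent_id="t",
                polyline=np.array([[40.0, 50.0], [68.0, 90.0]]))
    d2 = Branch(id="d2", parent_id="t",
                polyline=np.array([[70.0, 50.0], [100.0, 15.0]]))
    arbor = ArborTree(entry_point=np.array([10.0, 50.0]), ganglion_width=180.0,
                      branches=[trunk, d1, d2])
    stack = render_stack(arbor, RenderParams(noise_sd=0.0), np.random.default_rng(3))
    tree = trace_stack(stack)
    got = sorted(b.length for b in tree.branches)
    want = sorted(b.length for b in arbor.branches)
    assert len(got) == 3
    for g, w in zip(got, want):
        assert g == pytest.approx(w, rel=0.05)
    roots = [b for b in tree.branches if b.parent_id is None]
    assert len(roots) == 1


def test_straight_unbranched_axon_has_no_children():
    arbor = _one_branch_arbor(80.0)
    tree = trace_stack(render_stack(arbor, RenderParams(noise_sd=2.0),
                                    np.random.default_rng(4)))
    assert len(tree.branches) == 1
    assert tree.branches[0].parent_id is None


def test_three_separated_blobs_detect_as_three_varicosities():
    arbor = _one_branch_arbor(
        100.0, [Varicosity(20, 3.0, 2.0), Varicosity(50, 3.0, 2.0),
                Varicosity(80, 3.0, 2.0)]
    )
    stack = render_stack(arbor, RenderParams(noise_sd=1.0), np.random.default_rng(5))
    tree = trace_stack(stack)
    arcs = sorted(v.arc_position for b in tree.branches for v in b.varicosities)
    assert len(arcs) == 3
    for got, want in zip(arcs, [20.0, 50.0, 80.0]):
        assert got == pytest.approx(want, abs=2.0)


def test_uniform_axon_has_zero_detections():
    arbor = _one_branch_arbor(100.0)
    stack = render_stack(arbor, RenderParams(noise_sd=0.0), np.random.default_rng(6))
    tree = trace_stack(stack)
    assert tree.varicosity_count == 0


def test_raising_the_intensity_factor_never_increases_detections():
    arbor = _one_branch_arbor(
        100.0, [Varicosity(25, 3.5, 2.0), Varicosity(55, 4.0, 2.5),
                Varicosity(85, 3.2, 2.2)]
    )
    stack = render_stack(arbor, RenderParams(noise_sd=4.0), np.random.default_rng(7))
    mask, proj = project_and_segment(stack)
    meta = stack.metadata
    tree = extract_tree(mask, proj, np.array(meta["entry_point_um"]),
                        stack.pixel_size, tuple(meta["origin_um"]), metadata=meta)
    counts = []
    for factor in (1.2, 1.5, 2.5, 4.0, 8.0):
        params = TraceParams(varicosity_intensity_factor=factor)
        det = detect_varicosities(proj, tree, params, stack.pixel_size,
                                  tuple(meta["origin_um"]))
        counts.append(det.varicosity_count)
    assert counts == sorted(counts, reverse=True)


def test_mask_area_is_noise_stable_within_15pct(template, calibrated):
    arbor = sample_arbor(calibrated("wildtype"), template, np.random.default_rng(42))
    clean = render_stack(arbor, RenderParams(noise_sd=0.0), np.random.default_rng(0))
    noisy = render_stack(arbor, RenderParams(noise_sd=8.0), np.random.default_rng(0))
    # compare at a fixed threshold (adaptive thresholds differ by design)
    thr = clean.metadata and (10.0 + 25.0)
    p = TraceParams(threshold_method="fixed", fixed_threshold=thr)
    m0, _ = project_and_segment(clean, p)
    m1, _ = project_and_segment(noisy, p)
    assert abs(int(m1.sum()) - int(m0.sum())) / int(m0.sum()) < 0.15


def test_round_trip_arbor_length_within_5pct_noise_free_10pct_noisy(
        template, calibrated):
    arbor = sample_arbor(calibrated("wildtype"), template, np.random.default_rng(21))
    truth = summarize_arbor(filter_and_normalize(arbor, reference_width=180.0))
    for noise, tol in [(0.0, 0.05), (8.0, 0.10)]:
        stack = render_stack(arbor, RenderParams(noise_sd=noise),
                             np.random.default_rng(9))
        tree = trace_stack(stack)
        got = summarize_arbor(filter_and_normalize(tree, reference_width=180.0))
        assert got.total_length == pytest.approx(truth.total_length, rel=tol)


def test_doubling_pixel_size_changes_lengths_by_less_than_5pct(
        template, calibrated):
    arbor = sample_arbor(calibrated("wildtype"), template, np.random.default_rng(33))
    lens = {}
    for px in (0.5, 1.0):
        stack = render_stack(arbor, RenderParams(pixel_size=px, noise_sd=8.0),
                             np.random.default_rng(1))
        lens[px] = trace_stack(stack).total_length
    assert abs(lens[1.0] - lens[0.5]) / lens[0.5] < 0.05


def test_degraded_flag_set_when_pixels_exceed_axon_width():
    arbor = _one_branch_arbor(60.0)
    stack = render_stack(arbor, RenderParams(pixel_size=2.0, axon_width=1.5),
                         np.random.default_rng(0))
    assert stack.metadata.get("degraded") is True


def test_field_of_view_expands_to_fit_large_arbors():
    big = Branch(id="b", parent_id=None,
                 polyline=np.array([[0.0, 0.0], [300.0, 0.0]]))
    arbor = ArborTree(entry_point=np.zeros(2), ganglion_width=180.0, branches=[big])
    stack = render_stack(arbor, RenderParams(noise_sd=0.0), np.random.default_rng(0))
    assert stack.metadata.get("fov_expanded") is True
    assert stack.voxels.shape[-1] * stack.pixel_size >= 300.0


def test_cohort_round_trip_recovers_counts_at_cohort_scale(template, calibrated):
    """Cohort-level fidelity: mean branch count within 10% and most arbors
    within +-1 of their ground-truth count after render -> trace -> filter."""
    cal = calibrated("wildtype")
    rng = np.random.default_rng(11)
    gt, tr, within1 = [], [], 0
    n = 12
    for _ in range(n):
        a = sample_arbor(cal, template, rng)
        stack = render_stack(a, RenderParams(), rng)
        t = trace_stack(stack)
        g = summarize_arbor(filter_and_normalize(a, reference_width=180.0))
        m = summarize_arbor(filter_and_normalize(t, reference_width=180.0))
        gt.append(g.branch_count)
        tr.append(m.branch_count)
        within1 += abs(m.branch_count - g.branch_count) <= 1
    assert abs(np.mean(tr) - np.mean(gt)) / np.mean(gt) < 0.10
    assert within1 / n >= 0.6
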