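"""Branch correspondence, consensus extraction, and error scoring."""

import itertools

import numpy as np
import pytest

from pscarbor.consensus import (
    _cost_matrices,
    build_consensus,
    branch_descriptors,
    classify_branches,
    classify_entry,
    match_to_template,
    template_descriptors,
)
from pscarbor.morphometry import cohort_reference_width, filter_and_normalize
from pscarbor.synthgen import sample_arbor, sample_cohort
from pscarbor.templates import instantiate_template, make_template
from pscarbor.types import ArborTree, Branch, ConsensusParams, ValidationError
from scipy.optimize import linear_sum_assignment

_BIG_CUTOFF = 1e8


def brute_force_assigner(cost: np.ndarray):
    """Exhaustive minimum-cost assignment (oracle for the Hungarian step)."""
    nt, no = cost.shape
    if nt <= no:
        best, best_cols = np.inf, None
        for cols in itertools.permutations(range(no), nt):
            c = cost[np.arange(nt), list(cols)].sum()
            if c < best:
                best, best_cols = c, cols
        return np.arange(nt), np.array(best_cols)
    rows, cols = brute_force_assigner(cost.T)
    return cols, rows


def _drop(tree: ArborTree, ids) -> ArborTree:
    out = tree.copy()
    out.branches = [b for b in out.branches if b.id not in ids]
    return out


def test_unperturbed_canonical_arbor_matches_all_sixteen(template):
    tree = instantiate_template(template)
    res = match_to_template(tree, template)
    assert all(v is not None for v in res.assignments.values())
    assert res.unmatched_observed == []
    assert res.cost == pytest.approx(0.0, abs=1e-6)


def test_deleting_three_branches_leaves_three_template_ids_unmatched(template):
    tree = _drop(instantiate_template(template), {"b08", "b09", "b15"})
    res = match_to_template(tree, template)
    unmatched = [k for k, v in res.assignments.items() if v is None]
    assert sorted(unmatched) == ["b08", "b09", "b15"]
    assert sum(v is not None for v in res.assignments.values()) == 13


def test_empty_tree_leaves_every_template_branch_unmatched(template):
    tree = ArborTree(entry_point=np.zeros(2), ganglion_width=180.0, branches=[])
    res = match_to_template(tree, template)
    assert all(v is None for v in res.assignments.values())
    assert res.cost == 0.0


def test_hungarian_assignment_equals_exhaustive_search_on_small_instances(template):
    """Oracle equivalence on <=6x6 instances built from real descriptors."""
    rng = np.random.default_rng(4)
    tdesc = list(template_descriptors(template).values())
    params = ConsensusParams()
    for _ in range(30):
        nt = rng.integers(2, 7)
        no = rng.integers(2, 7)
        a = [tdesc[i] for i in rng.choice(len(tdesc), nt, replace=False)]
        b = [tdesc[i] for i in rng.choice(len(tdesc), no, replace=False)]
        cost, _ = _cost_matrices(a, b, params)
        r1, c1 = linear_sum_assignment(cost)
        r2, c2 = brute_force_assigner(cost)
        assert cost[r1, c1].sum() == pytest.approx(cost[r2, c2].sum(), rel=1e-12)


def test_iterative_consensus_equals_brute_force_consensus_on_tiny_cohorts(rng):
    """On <=6-arbor cohorts with <=6 branches, the iterative consensus with
    the Hungarian matcher equals the one computed with exhaustive
    assignment at every step."""
    rows = [
        ("a", "-", 0.0, 0.55, 0.835, 80.0, 16.0, 1.0),
        ("b", "a", 0.3, 1.0, 0.0, 40.0, 8.0, 0.9),
        ("c", "a", 0.7, -0.5, 0.866, 30.0, 6.0, 0.9),
        ("d", "b", 0.5, 0.32, -0.947, 20.0, 4.0, 0.9),
    ]
    toy = make_template(rows)
    from pscarbor.synthgen import calibrate_config
    from pscarbor.types import GenotypeConfig

    cfg = GenotypeConfig(
        name="tiny", n_animals=6,
        target_branch_mean=3.8, target_branch_sem=0.2,
        target_total_len_mean=160.0, target_total_len_sem=8.0,
        target_varicosity_mean=4.0, target_varicosity_sem=1.0,
    )
    cal = calibrate_config(cfg, toy)
    cohort = sample_cohort(cal, toy, rng, n=6)
    cohort = [filter_and_normalize(x, reference_width=180.0) for x in cohort]
    c_fast = build_consensus(cohort)
    c_slow = build_consensus(cohort, assigner=brute_force_assigner)
    assert len(c_fast) == len(c_slow)
    d1 = list(template_descriptors(c_fast).values())
    d2 = list(template_descriptors(c_slow).values())
    cost, _ = _cost_matrices(d1, d2, ConsensusParams())
    r, c = linear_sum_assignment(cost)
    assert float(cost[r, c].max()) < 1e-9


def _jittered_canonical(template, seed, drop=()):
    rng = np.random.default_rng(seed)
    tree = instantiate_template(template)
    for b in tree.branches:
        b.polyline = b.polyline + rng.normal(0.0, 0.05, size=(1, 2))
    return _drop(tree, set(drop))


def test_strict_80pct_boundary_17_in_16_out(template):
    """A branch present in 17/21 arbors (81%) enters the consensus; in
    16/21 (76%) it does not — the threshold is strictly greater-than."""
    for n_drop, expect in [(4, 16), (5, 15)]:
        cohort = [
            _jittered_canonical(template, seed=i,
                                drop={"b15"} if i < n_drop else ())
            for i in range(21)
        ]
        cons = build_consensus(cohort)
        assert len(cons) == expect


def test_single_arbor_consensus_is_its_own_branch_set(template):
    tree = instantiate_template(template)
    cons = build_consensus([tree])
    assert len(cons) == len(tree.branches)
    assert all(b.presence_prob == 1.0 for b in cons.branches)


def test_consensus_is_invariant_to_cohort_ordering(template):
    """Same branch set and descriptor means (to 1e-6) for any cohort order.

    Uses presence frequencies away from the 80% boundary: a frequency at
    exactly the 16-vs-17-of-21 edge can legitimately flip with the
    iteration path, which is a threshold property, not an ordering one."""
    cohort = [
        _jittered_canonical(template, seed=i, drop={"b15"} if i < 2 else ())
        for i in range(21)
    ]
    reference = build_consensus(cohort)
    for reordered in (cohort[::-1], cohort[7:] + cohort[:7]):
        other = build_consensus(reordered)
        assert len(other) == len(reference) == 16
        d1 = list(template_descriptors(reference).values())
        d2 = list(template_descriptors(other).values())
        cost, _ = _cost_matrices(d1, d2, ConsensusParams())
        r, c = linear_sum_assignment(cost)
        assert float(cost[r, c].max()) < 1e-6


def test_raising_the_frequency_threshold_never_grows_the_consensus(
        template, calibrated, rng):
    cohort = sample_cohort(calibrated("wildtype"), template, rng)
    ref = cohort_reference_width(cohort)
    cohort = [filter_and_normalize(x, reference_width=ref) for x in cohort]
    sizes = [
        len(build_consensus(cohort, ConsensusParams(freq_threshold=f)))
        for f in (0.55, 0.8, 0.95)
    ]
    assert sizes[0] >= sizes[1] >= sizes[2]


def test_classification_recovers_generator_labels_on_clean_cohorts(
        template, calibrated):
    """Ground-truth recovery: >=95% of branches get their generator label
    back on unperturbed (no routing-error) wildtype arbors."""
    cal = calibrated("wildtype")
    rng = np.random.default_rng(99)
    correct = total = 0
    for _ in range(80):
        a = sample_arbor(cal, template, rng)
        a = filter_and_normalize(a, reference_width=180.0)
        truth = {b.id: b.label for b in a.branches}
        c = classify_branches(a, template)
        for b in c.branches:
            total += 1
            correct += b.label == truth[b.id]
    assert correct / total >= 0.95


def test_classification_counts_are_mutually_consistent(template, calibrated, rng):
    a = sample_arbor(calibrated("plexa_rnai"), template, rng)
    a = filter_and_normalize(a, reference_width=180.0)
    c = classify_branches(a, template)
    f = c.flags
    assert f["n_skeletal"] + f["n_variable"] == len(c.branches)
    assert f["n_missing_skeletal"] >= f["n_routing_errors"]
    assert f["n_missing_skeletal"] <= len(template)


def test_zero_branch_arbor_classifies_to_zero_counts(template):
    tree = ArborTree(entry_point=np.zeros(2), ganglion_width=180.0, branches=[])
    c = classify_branches(tree, template)
    assert c.flags["n_skeletal"] == 0
    assert c.flags["n_variable"] == 0
    assert c.flags["n_missing_skeletal"] == len(template)


def test_misrouted_branch_is_flagged_and_counted_variable(template):
    tree = instantiate_template(template)
    b = tree.branch_by_id("b09")  # childless: rotation cannot orphan anyone
    origin = b.polyline[0].copy()
    rel = b.polyline - origin
    ang = np.radians(90.0)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    b.polyline = origin + rel @ rot.T
    c = classify_branches(tree, template)
    routed = [x for x in c.branches if x.routing_error]
    assert [x.id for x in routed] == ["b09"]
    assert c.flags["n_routing_errors"] == 1
    assert c.flags["n_skeletal"] == 15
    assert c.flags["n_variable"] == 1
    assert c.flags["n_missing_skeletal"] == 1


def test_entry_classification_uses_the_segmental_bands():
    meso = ArborTree(entry_point=np.array([12.0, 60.0]), ganglion_width=180.0)
    meta = ArborTree(entry_point=np.array([12.0, 185.0]), ganglion_width=180.0)
    nowhere = ArborTree(entry_point=np.array([12.0, 135.0]), ganglion_width=180.0)
    assert classify_entry(meso) is False
    assert classify_entry(meta) is True
    with pytest.raises(ValidationError):
        classify_entry(nowhere)


def test_guidance_error_frequency_recovers_the_configured_rate(
        template, calibrated):
    cal = calibrated("plexa_rnai_lof")  # published 56% at n = 18
    rng = np.random.default_rng(17)
    freqs = []
    for _ in range(25):
        cohort = sample_cohort(cal, template, rng, n=18)
        freqs.append(np.mean([classify_entry(a) for a in cohort]))
    se = np.sqrt(0.56 * 0.44 / (18 * 25))
    assert abs(np.mean(freqs) - 0.56) < 3 * se
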