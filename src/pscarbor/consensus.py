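"""Branch correspondence, consensus-skeleton extraction, and error scoring.

A branch is described by four geometric features: where it attaches along
its parent, its topological depth, its initial heading, and its length.
Correspondence between a template and an observed arbor is a minimum-cost
one-to-one assignment (Hungarian algorithm) under a weighted descriptor
distance.  A pair is *assignable* when its non-direction cost is within
``gate_distance``; an assigned branch whose direction term alone exceeds
the gate follows an aberrant trajectory and is scored as a routing error
(excluded from the skeletal count, per the counting convention in which
misrouted skeletal branches are no longer identifiable).

The consensus skeleton of a cohort is built iteratively: starting from
one arbor's branch set, arbors are matched to the working template and
per-branch mean descriptors and presence frequencies re-estimated until
assignments stabilize; branches present at strictly more than the
frequency threshold (default 80%) form the consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .synthgen import MESOTHORACIC_BAND, METATHORACIC_BAND
from .types import (
    ArborTree,
    BranchDescriptor,
    ConsensusParams,
    MatchResult,
    SkeletonTemplate,
    TemplateBranch,
    ValidationError,
)

__all__ = [
    "branch_descriptors",
    "descriptor_cost",
    "match_to_template",
    "build_consensus",
    "classify_branches",
    "classify_entry",
    "DEFAULT_REGION_MAP",
]

_BIG = 1e9

DEFAULT_REGION_MAP = {
    "mesothoracic": MESOTHORACIC_BAND,
    "metathoracic": METATHORACIC_BAND,
}


def branch_descriptors(tree: ArborTree) -> dict[str, BranchDescriptor]:
    """Geometric descriptors of every branch of an arbor."""
    by_id = {b.id: b for b in tree.branches}
    depth_cache: dict[str, int] = {}

    def depth(bid: str) -> int:
        if bid in depth_cache:
            return depth_cache[bid]
        b = by_id[bid]
        d = 0 if b.parent_id is None or b.parent_id not in by_id else depth(b.parent_id) + 1
        depth_cache[bid] = d
        return d

    out = {}
    for b in tree.branches:
        if b.parent_id is not None and b.parent_id in by_id:
            parent = by_id[b.parent_id]
            af = _arc_position(parent, b.polyline[0]) / max(parent.length, 1e-9)
        else:
            af = 0.0
        out[b.id] = BranchDescriptor(
            attach_fraction=float(np.clip(af, 0.0, 1.0)),
            depth=depth(b.id),
            direction=tuple(_initial_heading(b.polyline)),
            length=max(b.length, 1e-9),
        )
    return out


def template_descriptors(template: SkeletonTemplate) -> dict[str, BranchDescriptor]:
    return {
        tb.id: BranchDescriptor(
            attach_fraction=tb.attach_fraction,
            depth=template.depth(tb.id),
            direction=tb.direction,
            length=max(tb.mean_length, 1e-9),
        )
        for tb in template.branches
    }


def descriptor_cost(
    a: BranchDescriptor, b: BranchDescriptor, params: ConsensusParams
) -> tuple[float, float, float]:
    """(total cost, non-direction cost, direction term) for one pair."""
    w1, w2, w3, w4 = params.descriptor_weights
    d_af = abs(a.attach_fraction - b.attach_fraction) / params.attach_scale
    d_depth = abs(a.depth - b.depth)
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    d_dir = math.degrees(math.acos(cosang)) / params.direction_scale_deg
    d_len = abs(math.log(a.length / b.length)) / params.length_scale
    non_dir = w1 * d_af + w2 * d_depth + w4 * d_len
    return non_dir + w3 * d_dir, non_dir, w3 * d_dir


Assigner = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


def _hungarian(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return linear_sum_assignment(cost)


def _cost_matrices(
    tmpl: Sequence[BranchDescriptor],
    obs: Sequence[BranchDescriptor],
    params: ConsensusParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (gated total cost, direction term) matrices."""
    w1, w2, w3, w4 = params.descriptor_weights
    t_af = np.array([d.attach_fraction for d in tmpl])[:, None]
    o_af = np.array([d.attach_fraction for d in obs])[None, :]
    t_dep = np.array([d.depth for d in tmpl])[:, None]
    o_dep = np.array([d.depth for d in obs])[None, :]
    t_dir = np.array([d.direction for d in tmpl])
    o_dir = np.array([d.direction for d in obs])
    t_len = np.array([d.length for d in tmpl])[:, None]
    o_len = np.array([d.length for d in obs])[None, :]
    d_af = np.abs(t_af - o_af) / params.attach_scale
    d_dep = np.abs(t_dep - o_dep)
    cosang = np.clip(t_dir @ o_dir.T, -1.0, 1.0)
    d_dir = np.degrees(np.arccos(cosang)) / params.direction_scale_deg
    d_len = np.abs(np.log(t_len / o_len)) / params.length_scale
    non_dir = w1 * d_af + w2 * d_dep + w4 * d_len
    dirterm = w3 * d_dir
    total = non_dir + dirterm
    total[non_dir > params.gate_distance] = _BIG
    return total, dirterm


def _match_descriptors(
    tmpl: dict[str, BranchDescriptor],
    obs: dict[str, BranchDescriptor],
    params: ConsensusParams,
    assigner: Assigner = _hungarian,
) -> MatchResult:
    t_ids = list(tmpl)
    o_ids = list(obs)
    if not t_ids or not o_ids:
        return MatchResult(
            assignments={t: None for t in t_ids}, unmatched_observed=list(o_ids), cost=0.0
        )
    cost, dirterm = _cost_matrices(
        [tmpl[t] for t in t_ids], [obs[o] for o in o_ids], params
    )
    rows, cols = assigner(cost)
    assignments: dict[str, Optional[str]] = {t: None for t in t_ids}
    routing: list[str] = []
    total_cost = 0.0
    matched_obs = set()
    for i, j in zip(rows, cols):
        if cost[i, j] >= _BIG:
            continue
        assignments[t_ids[i]] = o_ids[j]
        matched_obs.add(o_ids[j])
        total_cost += float(cost[i, j])
        if dirterm[i, j] > params.gate_distance:
            routing.append(o_ids[j])
    unmatched = [o for o in o_ids if o not in matched_obs]
    return MatchResult(
        assignments=assignments,
        unmatched_observed=unmatched,
        cost=total_cost,
        routing_errors=routing,
    )


def match_to_template(
    tree: ArborTree,
    template: SkeletonTemplate,
    params: Optional[ConsensusParams] = None,
    assigner: Assigner = _hungarian,
) -> MatchResult:
    """Optimal one-to-one correspondence between template and arbor branches."""
    params = params or ConsensusParams()
    return _match_descriptors(
        template_descriptors(template), branch_descriptors(tree), params, assigner
    )


def classify_branches(
    tree: ArborTree,
    template: SkeletonTemplate,
    params: Optional[ConsensusParams] = None,
) -> ArborTree:
    """Label branches skeletal/variable and score routing and skeletal loss.

    Returns a relabelled copy; counts live in ``flags``:
    ``n_skeletal`` (cleanly assigned), ``n_variable`` (everything else,
    including misrouted branches), ``n_missing_skeletal`` (template ids
    without a clean assignment) and ``n_routing_errors``.
    """
    params = params or ConsensusParams()
    out = tree.copy()
    match = match_to_template(out, template, params)
    routed = set(match.routing_errors)
    obs_to_tmpl = {o: t for t, o in match.assignments.items() if o is not None}
    n_skel = 0
    for b in out.branches:
        tid = obs_to_tmpl.get(b.id)
        if tid is not None and b.id not in routed:
            b.label = f"skeletal:{tid}"
            b.routing_error = False
            n_skel += 1
        else:
            b.label = "variable"
            b.routing_error = b.id in routed
    n_missing = sum(
        1 for t, o in match.assignments.items() if o is None or o in routed
    )
    out.flags.update(
        n_skeletal=n_skel,
        n_variable=len(out.branches) - n_skel,
        n_missing_skeletal=n_missing,
        n_routing_errors=len(routed),
        match_cost=match.cost,
    )
    return out


def classify_entry(
    tree: ArborTree, region_map: Optional[dict[str, tuple[float, float]]] = None
) -> bool:
    """True iff the entry point lies outside the mesothoracic band."""
    region_map = region_map or DEFAULT_REGION_MAP
    y = float(tree.entry_point[1])
    hit = None
    for label, (lo, hi) in region_map.items():
        if lo <= y <= hi:
            hit = label
            break
    if hit is None:
        raise ValidationError(f"entry point y={y:.1f} μm falls outside all mapped bands")
    return hit != "mesothoracic"


# --------------------------------------------------------------------------
# consensus construction
# --------------------------------------------------------------------------

@dataclass
class _Entry:
    descriptor: BranchDescriptor
    parent_key: Optional[int]
    matches: list[tuple[BranchDescriptor, Optional[int]]] = field(default_factory=list)
    freq_count: int = 0


def build_consensus(
    cohort: Sequence[ArborTree],
    params: Optional[ConsensusParams] = None,
    assigner: Assigner = _hungarian,
) -> SkeletonTemplate:
    """Extract the cohort consensus skeleton (> freq_threshold presence).

    Alternates matching (all arbors against the working template) with
    re-estimation of per-entry mean descriptors and presence frequencies
    until assignments stabilize (at most ``max_rounds`` rounds); unmatched
    observed branches seed new entries.  A final re-match against the
    pruned template removes the dependence on the initialization arbor.
    """
    params = params or ConsensusParams()
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("cohort must be nonempty")
    n = len(cohort)
    all_desc = [branch_descriptors(t) for t in cohort]
    all_parents = [{b.id: b.parent_id for b in t.branches} for t in cohort]

    entries: dict[int, _Entry] = {}
    next_key = 0
    # seed from the first arbor
    first_keys: dict[str, int] = {}
    for bid, d in all_desc[0].items():
        entries[next_key] = _Entry(descriptor=d, parent_key=None)
        first_keys[bid] = next_key
        next_key += 1
    for bid, key in first_keys.items():
        pid = all_parents[0][bid]
        entries[key].parent_key = first_keys.get(pid) if pid is not None else None

    prev_assign: Optional[list[dict[int, Optional[str]]]] = None
    converged = False
    for _round in range(params.max_rounds):
        for e in entries.values():
            e.matches = []
            e.freq_count = 0
        round_assign: list[dict[int, Optional[str]]] = []
        new_entries: list[tuple[BranchDescriptor, Optional[str], int]] = []
        for ai, desc in enumerate(all_desc):
            tmpl = {k: e.descriptor for k, e in entries.items()}
            res = _match_descriptors(tmpl, desc, params, assigner)
            obs_to_key = {o: k for k, o in res.assignments.items() if o is not None}
            for key, oid in res.assignments.items():
                if oid is not None:
                    pid = all_parents[ai][oid]
                    parent_key = obs_to_key.get(pid) if pid is not None else None
                    entries[key].matches.append((desc[oid], parent_key))
                    entries[key].freq_count += 1
            for oid in res.unmatched_observed:
                new_entries.append((desc[oid], all_parents[ai][oid], ai))
            round_assign.append(dict(res.assignments))
        # re-estimate matched entries
        for e in entries.values():
            if e.matches:
                e.descriptor = _mean_descriptor([m[0] for m in e.matches])
                pkeys = [m[1] for m in e.matches if m[1] is not None]
                if pkeys:
                    e.parent_key = max(set(pkeys), key=pkeys.count)
        merged_any = _merge_duplicate_entries(entries, params, n)
        if (prev_assign is not None and round_assign == prev_assign
                and not new_entries and not merged_any):
            converged = True
            break
        prev_assign = round_assign
        for d, _pid, _ai in new_entries:
            entries[next_key] = _Entry(descriptor=d, parent_key=None)
            next_key += 1

    # clean frequency count against the merged entry set, then prune strictly
    _merge_duplicate_entries(entries, params, n)
    _recount(entries, all_desc, all_parents, params, assigner)
    kept = {k: e for k, e in entries.items() if e.freq_count / n > params.freq_threshold}
    if not kept:  # degenerate cohort: keep the most frequent entry set
        best = max(e.freq_count for e in entries.values())
        kept = {k: e for k, e in entries.items() if e.freq_count == best}

    # final re-match passes against the pruned template, iterated to a fixed
    # point so the result does not depend on the initialization arbor
    prev_sets: Optional[list] = None
    for _ in range(params.max_rounds):
        _recount(kept, all_desc, all_parents, params, assigner)
        for e in kept.values():
            if e.matches:
                e.descriptor = _mean_descriptor([m[0] for m in e.matches])
                pkeys = [m[1] for m in e.matches if m[1] is not None]
                e.parent_key = max(set(pkeys), key=pkeys.count) if pkeys else None
        sig = tuple(
            (k, e.freq_count, round(e.descriptor.attach_fraction, 12),
             round(e.descriptor.length, 9))
            for k, e in sorted(kept.items())
        )
        if prev_sets == sig:
            break
        prev_sets = sig

    return _entries_to_template(kept, n, params, converged)


def _recount(
    entries: dict[int, _Entry],
    all_desc: list[dict[str, BranchDescriptor]],
    all_parents: list[dict[str, Optional[str]]],
    params: ConsensusParams,
    assigner: Assigner,
) -> None:
    """Re-match every arbor against the given entry set, refreshing counts."""
    for e in entries.values():
        e.matches = []
        e.freq_count = 0
    for ai, desc in enumerate(all_desc):
        tmpl = {k: e.descriptor for k, e in entries.items()}
        res = _match_descriptors(tmpl, desc, params, assigner)
        obs_to_key = {o: k for k, o in res.assignments.items() if o is not None}
        for key, oid in res.assignments.items():
            if oid is not None:
                pid = all_parents[ai][oid]
                parent_key = obs_to_key.get(pid) if pid is not None else None
                entries[key].matches.append((desc[oid], parent_key))
                entries[key].freq_count += 1


def _merge_duplicate_entries(
    entries: dict[int, _Entry], params: ConsensusParams, n: int
) -> bool:
    """Merge working-template entries that describe the same branch.

    Iterative matching can split one true branch across two entries (an
    instance that misses the gate seeds a fresh entry); left unmerged, the
    split dilutes the presence frequency below threshold.  Entries whose
    mutual descriptor cost is below ``merge_cost`` are pooled (frequency
    capped at the cohort size).
    """
    keys = sorted(entries, key=lambda k: -entries[k].freq_count)
    if len(keys) < 2:
        return False
    descs = [entries[k].descriptor for k in keys]
    cost, _ = _cost_matrices(descs, descs, params)
    merged_any = False
    absorbed: set[int] = set()
    for i, ki in enumerate(keys):
        if ki in absorbed:
            continue
        for j in range(i + 1, len(keys)):
            kj = keys[j]
            if kj in absorbed:
                continue
            if min(cost[i, j], cost[j, i]) < params.merge_cost:
                a, b = entries[ki], entries[kj]
                a.matches.extend(b.matches)
                a.freq_count = min(n, a.freq_count + b.freq_count)
                if a.matches:
                    a.descriptor = _mean_descriptor([m[0] for m in a.matches])
                absorbed.add(kj)
                merged_any = True
    for k in absorbed:
        del entries[k]
    return merged_any


def _mean_descriptor(ds: list[BranchDescriptor]) -> BranchDescriptor:
    af = float(np.mean([d.attach_fraction for d in ds]))
    depth = int(round(np.mean([d.depth for d in ds])))
    vec = np.mean([np.asarray(d.direction) for d in ds], axis=0)
    norm = np.linalg.norm(vec)
    vec = vec / norm if norm > 0 else np.array([1.0, 0.0])
    length = float(np.exp(np.mean([math.log(d.length) for d in ds])))
    return BranchDescriptor(attach_fraction=af, depth=depth,
                            direction=(float(vec[0]), float(vec[1])), length=length)


def _entries_to_template(
    kept: dict[int, _Entry], n: int, params: ConsensusParams, converged: bool
) -> SkeletonTemplate:
    # canonical ordering: by depth, then attachment position, then length
    order = sorted(
        kept,
        key=lambda k: (kept[k].descriptor.depth, kept[k].descriptor.attach_fraction,
                       -kept[k].descriptor.length),
    )
    names = {k: f"c{i + 1:02d}" for i, k in enumerate(order)}
    # re-parent to surviving entries only; root = shallowest entry
    root_key = order[0]
    branches = []
    for k in order:
        e = kept[k]
        pk = e.parent_key
        if k == root_key:
            pk = None
        elif pk not in kept or pk == k:
            pk = root_key
        lens = [m[0].length for m in e.matches] or [e.descriptor.length]
        sd = float(np.std(lens, ddof=1)) if len(lens) > 1 else 0.0
        branches.append(
            TemplateBranch(
                id=names[k],
                parent_id=names[pk] if pk is not None else None,
                attach_fraction=e.descriptor.attach_fraction,
                direction=e.descriptor.direction,
                mean_length=float(np.mean(lens)),
                sd_length=sd,
                presence_prob=e.freq_count / n,
            )
        )
    name = "consensus" if converged else "consensus-unconverged"
    return SkeletonTemplate(branches=tuple(branches), freq_threshold=params.freq_threshold,
                            name=name)


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _arc_position(branch, point: np.ndarray) -> float:
    poly = branch.polyline
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    best_arc, best_d = 0.0, np.inf
    for i in range(len(seg)):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((point - a) @ ab / denom, 0.0, 1.0))
        proj = a + t * ab
        d = float(np.linalg.norm(proj - point))
        if d < best_d:
            best_d, best_arc = d, cum[i] + t * seg[i]
    return best_arc


def _initial_heading(poly: np.ndarray, span_um: float = 6.0) -> np.ndarray:
    """Unit heading over the first few μm (robust to vertex noise)."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = min(span_um, cum[-1])
    i = int(np.searchsorted(cum, arc, side="right") - 1)
    i = min(max(i, 0), len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (arc - cum[i]) / seg[i]
    end = poly[i] + t * (poly[i + 1] - poly[i])
    d = end - poly[0]
    norm = np.linalg.norm(d)
    return d / norm if norm > 0 else np.array([1.0, 0.0])
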