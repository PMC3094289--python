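"""Size normalization, the 4 μm branch filter, and per-arbor metrics.

Branch measurements are normalized to the width of the thoracic ganglion
to remove animal-size, fixation and imaging-angle differences; only
branches strictly longer than 4 μm (after normalization) count toward
branch number and total arbor length.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import ArborMetrics, ArborTree, MorphometryParams, ValidationError

__all__ = [
    "filter_and_normalize",
    "summarize_arbor",
    "summarize_cohort",
    "metrics_frame",
]


def filter_and_normalize(
    tree: ArborTree, params: Optional[MorphometryParams] = None,
    reference_width: Optional[float] = None,
) -> ArborTree:
    """Scale coordinates to the reference ganglion width and drop short branches.

    Normalization is multiplicative on coordinates (about the origin), so
    downstream geometry stays consistent; varicosity arc positions scale
    with their branch.  Branches at or below ``min_branch_len`` after
    scaling are removed together with their varicosities; children of a
    removed branch are re-parented to its nearest surviving ancestor so the
    remaining tree stays connected for matching.  Idempotent: the scaled
    tree records the reference as its own width.
    """
    params = params or MorphometryParams()
    if tree.ganglion_width <= 0:
        raise ValidationError("ganglion_width must be positive")
    ref = reference_width if reference_width is not None else params.reference_ganglion_width
    if ref is None:
        ref = tree.ganglion_width  # lone arbor: already its own reference
    factor = ref / tree.ganglion_width

    out = tree.copy()
    out.ganglion_width = ref
    out.entry_point = out.entry_point * factor
    for b in out.branches:
        b.polyline = b.polyline * factor
        for v in b.varicosities:
            v.arc_position *= factor

    removed: set[str] = set()
    parent_of = {b.id: b.parent_id for b in out.branches}
    keep = []
    for b in out.branches:
        if b.length > params.min_branch_len:
            keep.append(b)
        else:
            removed.add(b.id)
    for b in keep:
        pid = b.parent_id
        while pid is not None and pid in removed:
            pid = parent_of[pid]
        b.parent_id = pid
    out.branches = keep
    out.flags["normalized"] = True
    return out


def cohort_reference_width(cohort: Iterable[ArborTree]) -> float:
    """Default normalization reference: the cohort mean ganglion width."""
    widths = [t.ganglion_width for t in cohort]
    if not widths:
        raise ValidationError("empty cohort has no reference width")
    return float(np.mean(widths))


def summarize_arbor(tree: ArborTree) -> ArborMetrics:
    """Per-arbor metrics; expects a filtered/normalized tree."""
    n = len(tree.branches)
    total = tree.total_length
    vari = tree.varicosity_count
    n_skel = sum(1 for b in tree.branches
                 if b.label.startswith("skeletal:") and not b.routing_error)
    n_routing = sum(1 for b in tree.branches if b.routing_error)
    n_variable = n - n_skel
    return ArborMetrics(
        branch_count=n,
        total_length=float(total),
        varicosity_count=vari,
        varicosities_per_branch=float(vari) / n if n else 0.0,
        n_skeletal=n_skel,
        n_variable=n_variable,
        n_missing_skeletal=tree.flags.get("n_missing_skeletal", 0),
        n_routing_errors=n_routing,
        guidance_error=tree.guidance_error,
        genotype=tree.genotype,
    )


def summarize_cohort(
    cohort: Iterable[ArborTree], params: Optional[MorphometryParams] = None,
) -> list[ArborMetrics]:
    """Normalize a whole cohort against its mean width, filter, summarize."""
    cohort = list(cohort)
    params = params or MorphometryParams()
    ref = params.reference_ganglion_width
    if ref is None:
        ref = cohort_reference_width(cohort)
    return [summarize_arbor(filter_and_normalize(t, params, reference_width=ref))
            for t in cohort]


def metrics_frame(metrics: Iterable[ArborMetrics]) -> pd.DataFrame:
    """One row per neuron; columns mirror the cohort summary table."""
    return pd.DataFrame(
        [
            {
                "genotype": m.genotype,
                "branch_count": m.branch_count,
                "total_length_um": m.total_length,
                "varicosity_count": m.varicosity_count,
                "varicosities_per_branch": m.varicosities_per_branch,
                "n_skeletal": m.n_skeletal,
                "n_variable": m.n_variable,
                "n_missing_skeletal": m.n_missing_skeletal,
                "n_routing_errors": m.n_routing_errors,
                "guidance_error": m.guidance_error,
            }
            for m in metrics
        ]
    )
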