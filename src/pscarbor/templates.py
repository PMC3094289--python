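"""Skeleton-template construction, canonical geometry, and template IO.

A :class:`~pscarbor.types.SkeletonTemplate` describes the prototypical
("core") branch set of a stereotyped arbor: for each branch, where it
attaches on its parent, its initial heading, its mean/SD length and its
per-animal presence frequency.  The packaged wildtype template has 16
branches whose mean lengths span 13-151 μm.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .types import (
    ArborTree,
    Branch,
    SkeletonTemplate,
    StructuralError,
    TemplateBranch,
)

__all__ = [
    "make_template",
    "load_wildtype_template",
    "read_template",
    "write_template",
    "instantiate_template",
    "canonical_entry_point",
    "template_polylines",
    "min_clearance",
]

#: Canonical arbor entry point into the ganglion (μm, mesothoracic band).
CANONICAL_ENTRY = (12.0, 55.0)

Row = Union[Mapping[str, object], Sequence[object]]

_COLUMNS = (
    "id",
    "parent_id",
    "attach_fraction",
    "dir_x",
    "dir_y",
    "mean_length",
    "sd_length",
    "presence_prob",
)


def make_template(
    spec_table: Iterable[Row],
    freq_threshold: float = 0.8,
    name: str = "template",
) -> SkeletonTemplate:
    """Build a :class:`SkeletonTemplate` from per-branch rows.

    Rows may be mappings with the keys ``id, parent_id, attach_fraction,
    dir_x, dir_y, mean_length, sd_length, presence_prob`` or sequences in
    that order.  ``parent_id`` of ``None``/``"-"`` marks the root.
    Structural problems (duplicate ids, unknown parents, cycles) raise
    :class:`StructuralError`; invalid values raise :class:`ValidationError`.
    """
    branches = []
    for row in spec_table:
        if isinstance(row, Mapping):
            vals = {k: row.get(k) for k in _COLUMNS}
        else:
            vals = dict(zip(_COLUMNS, row))
        parent = vals["parent_id"]
        if parent in ("-", "", None):
            parent = None
        branches.append(
            TemplateBranch(
                id=str(vals["id"]),
                parent_id=None if parent is None else str(parent),
                attach_fraction=float(vals["attach_fraction"]),
                direction=(float(vals["dir_x"]), float(vals["dir_y"])),
                mean_length=float(vals["mean_length"]),
                sd_length=float(vals["sd_length"]),
                presence_prob=float(vals["presence_prob"]),
            )
        )
    return SkeletonTemplate(branches=tuple(branches), freq_threshold=freq_threshold, name=name)


def read_template(path_or_text, name: Optional[str] = None) -> SkeletonTemplate:
    """Read a template from the plain-text tab-separated schema."""
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        with open(path_or_text, "r", encoding="utf-8") as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise StructuralError(f"template row has {len(parts)} fields, expected {len(_COLUMNS)}")
        rows.append(parts)
    return make_template(rows, name=name or "template")


def write_template(template: SkeletonTemplate, path) -> None:
    """Serialize a template to the same schema :func:`read_template` reads."""
    lines = ["# columns: " + " ".join(_COLUMNS)]
    for b in template.branches:
        lines.append(
            "\t".join(
                [
                    b.id,
                    b.parent_id if b.parent_id is not None else "-",
                    f"{b.attach_fraction:.4f}",
                    f"{b.direction[0]:.4f}",
                    f"{b.direction[1]:.4f}",
                    f"{b.mean_length:.4f}",
                    f"{b.sd_length:.4f}",
                    f"{b.presence_prob:.4f}",
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_wildtype_template() -> SkeletonTemplate:
    """The packaged 16-branch wildtype pSc skeleton template."""
    ref = resources.files("pscarbor").joinpath("data/wildtype_template.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        tmpl = read_template(fh, name="wildtype")
    return tmpl


def canonical_entry_point() -> np.ndarray:
    return np.asarray(CANONICAL_ENTRY, dtype=float)


def template_polylines(
    template: SkeletonTemplate,
    lengths: Optional[Mapping[str, float]] = None,
    directions: Optional[Mapping[str, np.ndarray]] = None,
    entry_point: Optional[np.ndarray] = None,
    points_per_branch: int = 9,
) -> dict[str, np.ndarray]:
    """Realize template branches as straight polylines in μm.

    ``lengths``/``directions`` override the template means (used by the
    generator to inject per-animal variability); children attach at their
    ``attach_fraction`` of the parent's *realized* arc length.
    """
    entry = canonical_entry_point() if entry_point is None else np.asarray(entry_point, float)
    by_id = {b.id: b for b in template.branches}
    order = _topological_order(template)
    polys: dict[str, np.ndarray] = {}
    for bid in order:
        tb = by_id[bid]
        length = tb.mean_length if lengths is None else float(lengths.get(bid, tb.mean_length))
        if directions is not None and bid in directions:
            d = np.asarray(directions[bid], float)
        else:
            d = np.asarray(tb.direction, float)
        d = d / np.linalg.norm(d)
        if tb.parent_id is None:
            origin = entry
        else:
            parent_poly = polys[tb.parent_id]
            seg = np.linalg.norm(np.diff(parent_poly, axis=0), axis=1)
            arc = tb.attach_fraction * float(seg.sum())
            origin = _point_at(parent_poly, arc)
        t = np.linspace(0.0, length, points_per_branch)
        polys[bid] = origin[None, :] + t[:, None] * d[None, :]
    return polys


def instantiate_template(
    template: SkeletonTemplate,
    ganglion_width: float = 180.0,
    genotype: str = "",
) -> ArborTree:
    """The noiseless canonical arbor: every branch present at its mean length."""
    polys = template_polylines(template)
    branches = [
        Branch(id=tb.id, parent_id=tb.parent_id, polyline=polys[tb.id],
               label=f"skeletal:{tb.id}")
        for tb in template.branches
    ]
    tree = ArborTree(
        entry_point=canonical_entry_point(),
        ganglion_width=ganglion_width,
        branches=branches,
        genotype=genotype,
    )
    tree.validate_structure(tol=1e-3)
    return tree


def min_clearance(tree: ArborTree, exclusion_um: float = 6.0) -> float:
    """Smallest projected distance between points of non-adjacent branches.

    Points within ``exclusion_um`` arc length of a branch attachment are
    ignored (junction neighbourhoods necessarily touch).  Used to verify
    that generated arbors remain resolvable in projection.
    """
    dense: dict[str, np.ndarray] = {}
    for b in tree.branches:
        seg = np.linalg.norm(np.diff(b.polyline, axis=0), axis=1)
        total = float(seg.sum())
        if total == 0:
            continue
        n = max(int(total / 0.5), 2)
        arcs = np.linspace(0.0, total, n)
        pts = np.array([b.point_at(a) for a in arcs])
        keep = (arcs > exclusion_um) & (arcs < total - min(exclusion_um, total / 2))
        if b.parent_id is None:
            keep = arcs < total  # root has no attachment at its origin
        dense[b.id] = pts[keep] if keep.any() else pts[:0]
    best = np.inf
    ids = [b.id for b in tree.branches]
    parent = {b.id: b.parent_id for b in tree.branches}
    for i, a in enumerate(ids):
        for bid in ids[i + 1:]:
            if parent.get(a) == bid or parent.get(bid) == a:
                continue
            pa, pb = dense.get(a), dense.get(bid)
            if pa is None or pb is None or len(pa) == 0 or len(pb) == 0:
                continue
            d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
            best = min(best, float(np.sqrt(d2.min())))
    return best


def _topological_order(template: SkeletonTemplate) -> list[str]:
    by_id = {b.id: b for b in template.branches}
    order: list[str] = []
    placed: set[str] = set()
    pending = list(template.branches)
    while pending:
        progressed = False
        rest = []
        for tb in pending:
            if tb.parent_id is None or tb.parent_id in placed:
                order.append(tb.id)
                placed.add(tb.id)
                progressed = True
            else:
                rest.append(tb)
        if not progressed:
            raise StructuralError("unresolvable parent ordering")
        pending = rest
    return order


def _point_at(polyline: np.ndarray, arc: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = float(np.clip(arc, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, arc, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (arc - cum[i]) / seg[i]
    return polyline[i] + t * (polyline[i + 1] - polyline[i])
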