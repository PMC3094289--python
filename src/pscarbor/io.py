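"""File formats: SWC morphology, varicosity sidecar CSV, genotype configs, TIFF.

SWC carries the branch polylines (one node per polyline vertex, type 2 =
axon); because SWC has no bouton field, varicosities travel in a sidecar
CSV ``(branch_id, arc_position_um, diameter_um, intensity_gain)``.  Branch
identity and labels are preserved in structured ``#@`` comment lines so an
arbor round-trips exactly; serialization uses fixed decimal formatting so
identical arbors produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
from typing import Optional

import numpy as np
import tifffile

from .types import ArborTree, Branch, GenotypeConfig, ImageStack, Varicosity

__all__ = [
    "write_swc",
    "read_swc",
    "arbor_to_swc_text",
    "write_varicosity_csv",
    "read_varicosity_csv",
    "read_genotype_config",
    "write_genotype_config",
    "write_tiff",
    "read_tiff",
]

_F = "{:.4f}"


def arbor_to_swc_text(tree: ArborTree) -> str:
    """Serialize an arbor to SWC with structured header/branch comments."""
    lines = [
        "# SWC axonal arbor",
        f"#@ genotype {tree.genotype or '-'}",
        f"#@ entry_point {_F.format(tree.entry_point[0])} {_F.format(tree.entry_point[1])}",
        f"#@ entry_region {tree.entry_region}",
        f"#@ ganglion_width {_F.format(tree.ganglion_width)}",
        f"#@ guidance_error {int(tree.guidance_error)}",
    ]
    node_idx = 0
    last_node_of: dict[str, list[int]] = {}
    node_xy: list[np.ndarray] = []
    for b in tree.branches:
        lines.append(
            f"#@ branch {b.id} parent {b.parent_id or '-'} label {b.label} "
            f"routing {int(b.routing_error)}"
        )
        parent_node = -1
        if b.parent_id is not None and b.parent_id in last_node_of:
            cand = last_node_of[b.parent_id]
            d = [float(np.linalg.norm(node_xy[i - 1] - b.polyline[0])) for i in cand]
            parent_node = cand[int(np.argmin(d))]
        my_nodes = []
        for j, pt in enumerate(b.polyline):
            node_idx += 1
            par = parent_node if j == 0 else node_idx - 1
            lines.append(
                f"{node_idx} 2 {_F.format(pt[0])} {_F.format(pt[1])} 0.0000 0.7500 {par}"
            )
            node_xy.append(np.asarray(pt, float))
            my_nodes.append(node_idx)
        last_node_of[b.id] = my_nodes
    return "\n".join(lines) + "\n"


def write_swc(tree: ArborTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(arbor_to_swc_text(tree))


def read_swc(path) -> ArborTree:
    """Read an arbor written by :func:`write_swc` (uses the #@ annotations)."""
    header: dict[str, str] = {}
    branch_meta: list[dict] = []
    nodes: dict[int, np.ndarray] = {}
    node_owner: dict[int, int] = {}  # node index -> branch_meta position
    with open(path, "r", encoding="utf-8") as fh:
        current = -1
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#@ branch "):
                parts = line.split()
                branch_meta.append(
                    {
                        "id": parts[2],
                        "parent_id": None if parts[4] == "-" else parts[4],
                        "label": parts[6],
                        "routing": bool(int(parts[8])),
                        "nodes": [],
                    }
                )
                current += 1
                continue
            if line.startswith("#@ "):
                key, _, val = line[3:].partition(" ")
                header[key] = val
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            idx = int(parts[0])
            nodes[idx] = np.array([float(parts[2]), float(parts[3])])
            node_owner[idx] = current
            branch_meta[current]["nodes"].append(idx)
    branches = [
        Branch(
            id=m["id"],
            parent_id=m["parent_id"],
            polyline=np.array([nodes[i] for i in m["nodes"]]),
            label=m["label"],
            routing_error=m["routing"],
        )
        for m in branch_meta
    ]
    ex, ey = header.get("entry_point", "0 0").split()
    return ArborTree(
        entry_point=np.array([float(ex), float(ey)]),
        ganglion_width=float(header.get("ganglion_width", "180")),
        branches=branches,
        entry_region=header.get("entry_region", "mesothoracic"),
        genotype="" if header.get("genotype", "-") == "-" else header["genotype"],
        guidance_error=bool(int(header.get("guidance_error", "0"))),
    )


def write_varicosity_csv(tree: ArborTree, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["branch_id", "arc_position_um", "diameter_um", "intensity_gain"])
        for b in tree.branches:
            for v in b.varicosities:
                w.writerow(
                    [b.id, _F.format(v.arc_position), _F.format(v.diameter),
                     _F.format(v.intensity_gain)]
                )


def read_varicosity_csv(tree: ArborTree, path) -> ArborTree:
    """Attach sidecar varicosities onto a (copied) arbor."""
    out = tree.copy()
    for b in out.branches:
        b.varicosities = []
    by_id = {b.id: b for b in out.branches}
    with open(path, "r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            b = by_id.get(row["branch_id"])
            if b is not None:
                b.varicosities.append(
                    Varicosity(
                        arc_position=float(row["arc_position_um"]),
                        diameter=float(row["diameter_um"]),
                        intensity_gain=float(row["intensity_gain"]),
                    )
                )
    return out


# --------------------------------------------------------------------------
# genotype config files (plain-text key = value)
# --------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "name": str,
    "n_animals": int,
    "target_branch_mean": float,
    "target_branch_sem": float,
    "target_total_len_mean": float,
    "target_total_len_sem": float,
    "target_varicosity_mean": float,
    "target_varicosity_sem": float,
    "guidance_error_rate": float,
    "routing_error_rate": float,
    "skeleton_presence_scale": float,
    "variable_branch_mean_len": float,
    "variable_branch_sd_len": float,
    "seed": int,
}


def read_genotype_config(path) -> GenotypeConfig:
    values: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in _CONFIG_FIELDS:
                raise ValueError(f"unknown config key '{key}' in {path}")
            values[key] = _CONFIG_FIELDS[key](val.strip())
    return GenotypeConfig(**values)


def write_genotype_config(config: GenotypeConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in _CONFIG_FIELDS:
            fh.write(f"{key} = {getattr(config, key)}\n")


# --------------------------------------------------------------------------
# TIFF stacks
# --------------------------------------------------------------------------

def write_tiff(stack: ImageStack, path) -> None:
    """Multi-page TIFF, one page per z-slice; channel axis first if present."""
    meta = dict(stack.metadata)
    meta["pixel_size_um"] = stack.pixel_size
    meta["z_step_um"] = stack.z_step
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta, default=float),
    )


def read_tiff(path) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    try:
        meta = json.loads(desc)
    except (ValueError, TypeError):
        pass
    pixel_size = float(meta.pop("pixel_size_um", 1.0))
    z_step = float(meta.pop("z_step_um", 1.0))
    return ImageStack(voxels=np.asarray(data, float), pixel_size=pixel_size,
                      z_step=z_step, metadata=meta)
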