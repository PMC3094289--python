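"""Core domain types for arbor morphometry.

All geometry lives in continuous 2-D micrometre coordinates with the origin
at the anterior-left corner of the thoracic ganglion and y increasing
posteriorly.  Image analysis operates on maximum-intensity projections of
rendered z-stacks, so branches are planar polylines; the z dimension exists
only in the renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TemplateBranch",
    "SkeletonTemplate",
    "GenotypeConfig",
    "Varicosity",
    "Branch",
    "ArborTree",
    "RenderParams",
    "ImageStack",
    "MorphometryParams",
    "ArborMetrics",
    "ConsensusParams",
    "BranchDescriptor",
    "MatchResult",
    "TraceParams",
    "IhcParams",
    "RoiMeasurement",
    "CohortSummary",
    "TestResult",
    "StructuralError",
    "ValidationError",
    "CalibrationError",
    "InfeasibleTargetsError",
    "polyline_length",
]


class StructuralError(ValueError):
    """Tree structure is inconsistent (bad parent references, cycles)."""


class ValidationError(ValueError):
    """A value violates a documented invariant."""


class CalibrationError(ValueError):
    """A genotype configuration was used before calibration (or drifted)."""


class InfeasibleTargetsError(ValueError):
    """Moment-matching cannot reach the requested cohort targets."""


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an (n, 2) polyline in μm."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass(frozen=True)
class TemplateBranch:
    """One prototypical (skeletal) branch of the consensus template.

    ``attach_fraction`` positions the branch origin along its parent's arc
    length; ``direction`` is the unit initial heading; lengths are in μm.
    ``presence_prob`` is the per-animal probability that the branch exists
    (conditional on its parent existing).
    """

    id: str
    parent_id: Optional[str]
    attach_fraction: float
    direction: tuple[float, float]
    mean_length: float
    sd_length: float
    presence_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_length <= 0:
            raise ValidationError(f"branch {self.id}: mean_length must be > 0")
        if not 0.0 <= self.attach_fraction <= 1.0:
            raise ValidationError(f"branch {self.id}: attach_fraction outside [0, 1]")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise ValidationError(f"branch {self.id}: presence_prob outside [0, 1]")
        if self.sd_length < 0:
            raise ValidationError(f"branch {self.id}: sd_length must be >= 0")
        norm = float(np.hypot(*self.direction))
        if not np.isfinite(norm) or norm == 0:
            raise ValidationError(f"branch {self.id}: direction must be a nonzero vector")
        if abs(norm - 1.0) > 1e-6:
            object.__setattr__(
                self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
            )


@dataclass(frozen=True)
class SkeletonTemplate:
    """The prototypical 'core' branch set of a stereotyped arbor."""

    branches: tuple[TemplateBranch, ...]
    freq_threshold: float = 0.8
    name: str = "template"

    def __post_init__(self) -> None:
        if not 0.0 < self.freq_threshold < 1.0:
            raise ValidationError("freq_threshold must lie in (0, 1)")
        ids = [b.id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise StructuralError("template branch ids must be unique")
        known = set(ids)
        roots = 0
        for b in self.branches:
            if b.parent_id is None:
                roots += 1
            elif b.parent_id not in known:
                raise StructuralError(f"branch {b.id} references unknown parent {b.parent_id}")
        if self.branches and roots != 1:
            raise StructuralError(f"template must have exactly one root, found {roots}")
        # reject parent cycles (root-reachability check)
        by_id = {b.id: b for b in self.branches}
        for b in self.branches:
            seen = set()
            cur: Optional[TemplateBranch] = b
            while cur is not None and cur.parent_id is not None:
                if cur.id in seen:
                    raise StructuralError(f"cyclic parent chain at branch {b.id}")
                seen.add(cur.id)
                cur = by_id[cur.parent_id]

    def __len__(self) -> int:
        return len(self.branches)

    def branch(self, branch_id: str) -> TemplateBranch:
        for b in self.branches:
            if b.id == branch_id:
                return b
        raise KeyError(branch_id)

    def depth(self, branch_id: str) -> int:
        """Topological level: 0 for the root trunk, 1 for secondaries, ..."""
        by_id = {b.id: b for b in self.branches}
        d, cur = 0, by_id[branch_id]
        while cur.parent_id is not None:
            cur = by_id[cur.parent_id]
            d += 1
        return d


@dataclass
class GenotypeConfig:
    """Generative parameters for one genotype cohort.

    The ``target_*`` fields carry the published cohort statistics
    (mean ± SEM at the published n); the remaining generative parameters
    are either packaged (rates) or filled in by :func:`calibrate_config`.
    """

    name: str
    n_animals: int
    target_branch_mean: float
    target_branch_sem: float
    target_total_len_mean: float
    target_total_len_sem: float
    target_varicosity_mean: float
    target_varicosity_sem: float
    guidance_error_rate: float = 0.0
    routing_error_rate: float = 0.0
    skeleton_presence_scale: float = 1.0
    # --- calibrated generative parameters (filled by calibrate_config) ---
    variable_branch_rate: Optional[float] = None
    variable_branch_count_sd: Optional[float] = None
    variable_branch_mean_len: float = 25.0
    variable_branch_sd_len: float = 5.0
    length_scale: Optional[float] = None
    arbor_scale_sd: Optional[float] = None
    varicosity_density: Optional[float] = None
    varicosity_dispersion: Optional[float] = None  # Var(h) of the gamma rate multiplier
    varicosity_retention: float = 1.0  # placed/drawn fraction under the hard-core gap
    seed: int = 0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")
        for attr in ("target_branch_mean", "target_total_len_mean", "target_varicosity_mean"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")
        for attr in ("guidance_error_rate", "routing_error_rate", "skeleton_presence_scale"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{attr} must lie in [0, 1]")

    def copy(self, **changes) -> "GenotypeConfig":
        return replace(self, **changes)


@dataclass
class Varicosity:
    """A local axonal swelling (putative synaptic bouton)."""

    arc_position: float  # μm along the owning branch
    diameter: float  # μm
    intensity_gain: float = 2.0  # multiplier over the axon shaft intensity


@dataclass
class Branch:
    """A single arbor branch: a polyline from its origin to its tip."""

    id: str
    parent_id: Optional[str]
    polyline: np.ndarray  # (n, 2) μm
    varicosities: list[Varicosity] = field(default_factory=list)
    label: str = "unassigned"  # "skeletal:<template_id>" | "variable" | "unassigned"
    routing_error: bool = False

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 2:
            raise ValidationError(f"branch {self.id}: polyline must be (n, 2)")

    @property
    def length(self) -> float:
        return polyline_length(self.polyline)

    def point_at(self, arc: float) -> np.ndarray:
        """Point on the polyline at a given arc-length position."""
        seg = np.linalg.norm(np.diff(self.polyline, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        arc = float(np.clip(arc, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, arc, side="right") - 1)
        i = min(i, len(seg) - 1)
        t = 0.0 if seg[i] == 0 else (arc - cum[i]) / seg[i]
        return self.polyline[i] + t * (self.polyline[i + 1] - self.polyline[i])


@dataclass
class ArborTree:
    """Rooted geometric tree of one axonal arbor."""

    entry_point: np.ndarray  # (2,) μm
    ganglion_width: float  # μm
    branches: list[Branch] = field(default_factory=list)
    entry_region: str = "mesothoracic"
    genotype: str = ""
    guidance_error: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entry_point = np.asarray(self.entry_point, dtype=float)
        if self.ganglion_width <= 0:
            raise ValidationError("ganglion_width must be positive")

    def validate_structure(self, tol: float = 1e-6) -> None:
        ids = [b.id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise StructuralError("branch ids must be unique")
        by_id = {b.id: b for b in self.branches}
        roots = [b for b in self.branches if b.parent_id is None]
        if self.branches and len(roots) != 1:
            raise StructuralError(f"arbor must have exactly one root branch, found {len(roots)}")
        for b in self.branches:
            if b.parent_id is not None:
                if b.parent_id not in by_id:
                    raise StructuralError(f"branch {b.id} references unknown parent")
                parent = by_id[b.parent_id]
                d = _point_to_polyline_distance(b.polyline[0], parent.polyline)
                if d > max(tol, 1e-3):
                    raise StructuralError(
                        f"branch {b.id} origin is {d:.4f} μm off its parent's polyline"
                    )

    def branch_by_id(self, branch_id: str) -> Branch:
        for b in self.branches:
            if b.id == branch_id:
                return b
        raise KeyError(branch_id)

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    @property
    def varicosity_count(self) -> int:
        return int(sum(len(b.varicosities) for b in self.branches))

    def copy(self) -> "ArborTree":
        return ArborTree(
            entry_point=self.entry_point.copy(),
            ganglion_width=self.ganglion_width,
            branches=[
                Branch(
                    id=b.id,
                    parent_id=b.parent_id,
                    polyline=b.polyline.copy(),
                    varicosities=[Varicosity(v.arc_position, v.diameter, v.intensity_gain)
                                  for v in b.varicosities],
                    label=b.label,
                    routing_error=b.routing_error,
                )
                for b in self.branches
            ],
            entry_region=self.entry_region,
            genotype=self.genotype,
            guidance_error=self.guidance_error,
            flags=dict(self.flags),
        )


def _point_to_polyline_distance(point: np.ndarray, polyline: np.ndarray) -> float:
    p = np.asarray(point, dtype=float)
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = np.sum(ab * ab, axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


@dataclass
class RenderParams:
    """Physical and optical parameters of the synthetic epifluorescence stack.

    Defaults emulate a 40x epifluorescence acquisition of a whole arbor
    (~135 x 245 μm field) as a series of focal planes; the pixel size is
    chosen so that branches just above the 4 μm counting cutoff remain
    resolvable after the PSF blur.
    """

    field_of_view: tuple[float, float] = (135.0, 245.0)  # (x, y) μm
    pixel_size: float = 0.5  # μm / px
    n_slices: int = 16
    z_step: float = 1.0  # μm
    axon_width: float = 1.5  # μm, tube FWHM
    psf_sigma: float = 0.6  # μm
    background_level: float = 10.0
    noise_sd: float = 8.0
    amplitude: float = 100.0  # on-axon peak intensity before blur
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")


@dataclass
class ImageStack:
    """A voxel grid with physical calibration; one or two channels.

    ``voxels`` is (z, y, x) for single channel or (c, z, y, x) for two.
    """

    voxels: np.ndarray
    pixel_size: float
    z_step: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValidationError("calibration must be positive")
        if np.any(self.voxels < 0):
            raise ValidationError("intensities must be nonnegative")
        if self.voxels.ndim not in (3, 4):
            raise ValidationError("voxels must be (z, y, x) or (c, z, y, x)")

    @property
    def channels(self) -> int:
        return 1 if self.voxels.ndim == 3 else self.voxels.shape[0]

    def channel(self, c: int) -> np.ndarray:
        if self.voxels.ndim == 3:
            if c != 0:
                raise IndexError("single-channel stack")
            return self.voxels
        return self.voxels[c]

    def max_projection(self, c: int = 0) -> np.ndarray:
        return self.channel(c).max(axis=0)


@dataclass
class MorphometryParams:
    """Filtering and normalization rules for per-arbor metrics."""

    min_branch_len: float = 4.0  # μm, strictly-greater retention
    reference_ganglion_width: Optional[float] = None  # None -> cohort mean

    def __post_init__(self) -> None:
        if self.min_branch_len <= 0:
            raise ValidationError("min_branch_len must be positive")


@dataclass
class ArborMetrics:
    """Per-arbor summary metrics (one table row per neuron)."""

    branch_count: int
    total_length: float
    varicosity_count: int
    varicosities_per_branch: float
    n_skeletal: int = 0
    n_variable: int = 0
    n_missing_skeletal: int = 0
    n_routing_errors: int = 0
    guidance_error: bool = False
    genotype: str = ""


@dataclass
class ConsensusParams:
    """Parameters of branch correspondence and consensus extraction.

    The descriptor distance has four terms (attachment position, topological
    depth, initial direction, log-length); ``descriptor_weights`` weight them
    in that order.  ``gate_distance`` bounds the *non-direction* part of the
    cost for a pair to be assignable, so that a geometrically matching branch
    with an aberrant trajectory is still assigned but flagged as a routing
    error (direction term alone above the gate).
    """

    freq_threshold: float = 0.8  # strict: > threshold
    descriptor_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.5)
    gate_distance: float = 0.8
    attach_scale: float = 0.1  # |Δ attach_fraction| unit
    direction_scale_deg: float = 60.0  # degrees per unit direction cost
    length_scale: float = 0.45  # |log length ratio| unit
    merge_cost: float = 1.1  # consensus entries closer than this are duplicates
    max_rounds: int = 10

    def __post_init__(self) -> None:
        w = self.descriptor_weights
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValidationError("descriptor weights must be nonnegative, not all zero")
        if not 0.0 < self.freq_threshold < 1.0:
            raise ValidationError("freq_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class BranchDescriptor:
    """Geometric signature used for branch correspondence."""

    attach_fraction: float
    depth: int
    direction: tuple[float, float]
    length: float


@dataclass
class MatchResult:
    """Template-to-observed branch assignment."""

    assignments: dict[str, Optional[str]]  # template id -> observed branch id or None
    unmatched_observed: list[str]
    cost: float
    routing_errors: list[str] = field(default_factory=list)  # observed ids

    def __post_init__(self) -> None:
        assigned = [v for v in self.assignments.values() if v is not None]
        if len(assigned) != len(set(assigned)):
            raise ValidationError("assignments must be injective over non-None values")


@dataclass
class TraceParams:
    """Operator settings for segmentation, tracing and varicosity detection."""

    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.0
    min_component_px: int = 20
    prune_spur_um: float = 3.8
    varicosity_width_factor: float = 1.5
    varicosity_intensity_factor: float = 1.5
    min_varicosity_separation_um: float = 2.0
    junction_exclusion_um: float = 2.5
    neighbor_exclusion_um: float = 3.5
    merge_collinear_deg: float = 55.0
    collapse_internal_um: float = 6.0

    def __post_init__(self) -> None:
        if self.varicosity_width_factor <= 1 or self.varicosity_intensity_factor <= 1:
            raise ValidationError("varicosity factors must exceed 1")
        if not 0 <= self.prune_spur_um < 4.0:
            raise ValidationError("prune_spur_um must lie in [0, 4) μm")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class IhcParams:
    """ROI sampling settings for two-channel intensity quantification."""

    n_rois: int = 4
    roi_size: tuple[float, float] = (20.0, 20.0)  # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValidationError("n_rois must be >= 1")


@dataclass
class RoiMeasurement:
    """Integrated intensities of one ROI on both channels."""

    bounds: tuple[float, float, float, float]  # (x0, y0, x1, y1) μm
    integrated_a: float
    integrated_b: float

    @property
    def ratio(self) -> float:
        return self.integrated_a / self.integrated_b if self.integrated_b > 0 else float("nan")


@dataclass
class CohortSummary:
    """One summary-table row per genotype (mean ± SEM convention)."""

    genotype: str
    n: int
    guidance_error_freq: float
    branch_mean_sem: tuple[float, float]
    total_len_mean_sem: tuple[float, float]
    varicosity_mean_sem: tuple[float, float]
    vpb_mean_sem: tuple[float, float] = (0.0, 0.0)  # varicosities per branch
    degenerate: bool = False


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    adjusted: bool = False
    degenerate: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")
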