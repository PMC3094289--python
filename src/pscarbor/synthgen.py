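"""Synthetic arbor generation calibrated to published cohort statistics.

Each genotype is a :class:`GenotypeConfig` carrying the published cohort
targets (mean ± SEM of branch count, total arbor length and varicosity
count at the published n).  :func:`calibrate_config` moment-matches the
free generative parameters so that the analytic expectations of the three
metrics equal the targets, and the per-arbor dispersions reproduce the
published SEMs under the SD = SEM·√n reading.

Generative model (per arbor):

* skeletal branches are included top-down: a branch exists iff its parent
  exists and an independent Bernoulli(presence_prob × presence_scale)
  succeeds; the root trunk always exists,
* skeletal lengths are truncated-normal around template mean/SD, scaled by
  a per-genotype ``length_scale`` and a per-animal lognormal size factor,
* variable (non-skeletal) branch count is a rounded Gaussian whose mean
  and SD are calibrated; variable branches attach at random positions with
  headings at least ~30° off the parent and are rejection-placed to avoid
  crossing existing geometry in projection,
* varicosities form a hard-core (minimum gap) point process along each
  branch with per-arbor gamma-distributed rate multiplier, avoiding branch
  ends and junction neighbourhoods,
* guidance errors relocate the entry annotation to the metathoracic band;
  routing errors rotate a skeletal branch's heading by 60-120°.
"""

from __future__ import annotations

import functools
import math
import zlib
from typing import Optional

import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import cdist

from .types import (
    ArborTree,
    Branch,
    CalibrationError,
    GenotypeConfig,
    InfeasibleTargetsError,
    SkeletonTemplate,
    Varicosity,
)
from .templates import canonical_entry_point, template_polylines

__all__ = [
    "calibrate_config",
    "expected_metrics",
    "sample_arbor",
    "sample_cohort",
    "REFERENCE_GANGLION_WIDTH",
    "GANGLION_WIDTH_SD",
    "METATHORACIC_SHIFT",
    "MESOTHORACIC_BAND",
    "METATHORACIC_BAND",
]

#: Reference ganglion width (μm); sampled widths are Normal(ref, sd).
REFERENCE_GANGLION_WIDTH = 180.0
GANGLION_WIDTH_SD = 9.0

#: Posterior translation (μm) of the entry point for guidance errors.
METATHORACIC_SHIFT = 130.0
MESOTHORACIC_BAND = (20.0, 120.0)
METATHORACIC_BAND = (150.0, 250.0)

#: Varicosity geometry: diameters comfortably above the rendered axon tube
#: (1.5 μm FWHM) so that generated varicosities are detectable by the
#: two-factor width/intensity rule; hard-core gap keeps detections separable.
VARICOSITY_DIAMETER_RANGE = (3.3, 4.5)
VARICOSITY_GAIN_RANGE = (2.0, 3.0)
VARICOSITY_MIN_GAP = 4.0
VARICOSITY_END_MARGIN = 4.5

_DIRECTION_JITTER_DEG = 6.0
_ATTACH_JITTER = 0.02
_CURVATURE_SD_DEG = 5.0
_VARIABLE_CLEARANCE = 7.0
_POINTS_PER_BRANCH = 9


# --------------------------------------------------------------------------
# analytic moments
# --------------------------------------------------------------------------

@functools.lru_cache(maxsize=4096)
def _trunc_moments(mean: float, sd: float) -> tuple[float, float]:
    """Mean and variance of a normal truncated at zero."""
    if sd == 0:
        return mean, 0.0
    a = (0.0 - mean) / sd
    d = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return float(d.mean()), float(d.var())


def _path_sets(template: SkeletonTemplate) -> dict[str, frozenset[str]]:
    """Root-path branch-id sets (excluding the root) per branch."""
    by_id = {b.id: b for b in template.branches}
    out = {}
    for b in template.branches:
        path = []
        cur = b
        while cur.parent_id is not None:
            path.append(cur.id)
            cur = by_id[cur.parent_id]
        out[b.id] = frozenset(path)
    return out


def _presence_moments(
    template: SkeletonTemplate, presence_scale: float, length_scale: float = 1.0
) -> dict:
    """Exact mean/variance of skeletal branch count and summed length.

    The inclusion indicator of branch i is the product of independent
    Bernoulli(p_k·scale) along its root path (root excluded, always on),
    so pair expectations are products over unions of path sets.
    """
    paths = _path_sets(template)
    probs = {b.id: min(1.0, b.presence_prob * presence_scale) for b in template.branches}
    lm = {}
    for b in template.branches:
        m, v = _trunc_moments(b.mean_length, b.sd_length)
        lm[b.id] = (length_scale * m, length_scale ** 2 * v)

    def incl(path: frozenset[str]) -> float:
        out = 1.0
        for k in path:
            out *= probs[k]
        return out

    ids = [b.id for b in template.branches]
    q = {i: incl(paths[i]) for i in ids}
    mean_n = sum(q.values())
    mean_len = sum(q[i] * lm[i][0] for i in ids)
    var_n = 0.0
    var_len = 0.0
    for i in ids:
        var_n += q[i] * (1 - q[i])
        var_len += q[i] * (lm[i][0] ** 2 + lm[i][1]) - (q[i] * lm[i][0]) ** 2
    for a_i, i in enumerate(ids):
        for j in ids[a_i + 1:]:
            qij = incl(paths[i] | paths[j])
            cov = qij - q[i] * q[j]
            var_n += 2 * cov
            var_len += 2 * cov * lm[i][0] * lm[j][0]
    return {
        "q": q,
        "mean_count": mean_n,
        "var_count": var_n,
        "mean_length": mean_len,
        "var_length": var_len,
    }


def _rounded_gauss_pmf(mean: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """PMF of max(0, round(Normal(mean, sd))) on an integer grid."""
    hi = int(math.ceil(mean + 10 * sd + 5))
    k = np.arange(0, hi + 1)
    upper = stats.norm.cdf(k + 0.5, loc=mean, scale=sd)
    lower = stats.norm.cdf(k - 0.5, loc=mean, scale=sd)
    p = upper - lower
    p[0] = upper[0]  # all mass below 0.5 collapses to zero
    return k, p


def _rounded_gauss_moments(mean: float, sd: float) -> tuple[float, float]:
    if sd <= 1e-9:
        v = round(mean)
        return float(max(0, v)), 0.0
    k, p = _rounded_gauss_pmf(mean, sd)
    m = float(np.sum(k * p))
    v = float(np.sum(k * k * p) - m * m)
    return m, v


def _solve_count_params(target_mean: float, target_var: float) -> tuple[float, float]:
    """Gaussian (mean, sd) whose rounded-clipped moments match the targets.

    A counting distribution with fractional mean m cannot have variance
    below frac(1-frac) (the floor/ceil two-point law), so the variance
    target is floored there.
    """
    frac = target_mean - math.floor(target_mean)
    if frac > 1e-9:
        target_var = max(target_var, frac * (1.0 - frac) + 1e-6)

    def mean_err(mu, sd):
        return _rounded_gauss_moments(mu, sd)[0] - target_mean

    def solve_mu(sd):
        lo, hi = max(0.0, target_mean - 3 * sd - 2), target_mean + 3 * sd + 2
        if mean_err(lo, sd) > 0:
            return lo
        return optimize.brentq(lambda m: mean_err(m, sd), lo, hi, xtol=1e-10)

    if target_var <= 1e-6:
        return solve_mu(1e-9), 0.0

    def var_err(sd):
        mu = solve_mu(sd)
        return _rounded_gauss_moments(mu, sd)[1] - target_var

    lo, hi = 1e-4, max(4.0 * math.sqrt(target_var) + 1.0, 1.0)
    if var_err(lo) > 0:
        sd = lo
    else:
        sd = optimize.brentq(var_err, lo, hi, xtol=1e-8)
    return solve_mu(sd), sd


def expected_metrics(config: GenotypeConfig, template: SkeletonTemplate) -> dict:
    """Analytic expectations (and variances) of the three cohort metrics."""
    if config.length_scale is None or config.variable_branch_rate is None:
        raise CalibrationError(f"config '{config.name}' is not calibrated")
    pm = _presence_moments(template, config.skeleton_presence_scale, config.length_scale)
    mv, vv = _trunc_moments(config.variable_branch_mean_len, config.variable_branch_sd_len)
    nm, nv = _rounded_gauss_moments(
        config.variable_branch_rate, config.variable_branch_count_sd or 0.0
    )
    mean_count = pm["mean_count"] + nm
    var_count = pm["var_count"] + nv
    var_x = pm["var_length"] + nm * vv + nv * mv ** 2
    mean_x = pm["mean_length"] + nm * mv
    sg2 = (config.arbor_scale_sd or 0.0) ** 2
    mean_len = mean_x
    var_len = (1 + sg2) * var_x + sg2 * mean_x ** 2
    # effective density after hard-core placement thinning
    rho = (config.varicosity_density or 0.0) * (config.varicosity_retention or 1.0)
    vh = config.varicosity_dispersion or 0.0
    mean_var = rho * mean_len
    var_var = mean_var + rho ** 2 * ((1 + vh) * (var_len + mean_len ** 2) - mean_len ** 2)
    return {
        "branch_count": mean_count,
        "total_length": mean_len,
        "varicosity_count": mean_var,
        "var_branch_count": var_count,
        "var_total_length": var_len,
        "var_varicosity_count": var_var,
    }


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibrate_config(config: GenotypeConfig, template: SkeletonTemplate) -> GenotypeConfig:
    """Moment-match the free generative parameters to the cohort targets.

    Deterministic given (config, template).  The mean of each metric is
    matched exactly; the per-arbor variance is matched to (SEM·√n)² where
    a nonnegative solution exists (clamped at the structural floor
    otherwise, recorded in ``flags``).  Raises
    :class:`InfeasibleTargetsError` naming the binding constraint when the
    targets cannot be reached.
    """
    n = config.n_animals
    tgt_var_count = n * config.target_branch_sem ** 2
    tgt_var_len = n * config.target_total_len_sem ** 2
    tgt_var_vari = n * config.target_varicosity_sem ** 2

    pm0 = _presence_moments(template, config.skeleton_presence_scale, 1.0)
    base_count = pm0["mean_count"]
    lam_target = config.target_branch_mean - base_count
    if lam_target < -1e-9:
        raise InfeasibleTargetsError(
            f"target branch count {config.target_branch_mean} is below the expected "
            f"skeletal count {base_count:.2f} at presence scale "
            f"{config.skeleton_presence_scale} (binding constraint: skeletal floor)"
        )
    lam_target = max(0.0, lam_target)

    need_var_count = tgt_var_count - pm0["var_count"]
    flags = {}
    if need_var_count < 0:
        flags["underdispersed_count"] = True
        need_var_count = 0.0
    mu_n, sd_n = _solve_count_params(lam_target, need_var_count)
    nm, nv = _rounded_gauss_moments(mu_n, sd_n)

    mv, vv = _trunc_moments(config.variable_branch_mean_len, config.variable_branch_sd_len)
    skel_len_unit = pm0["mean_length"]  # at length_scale 1
    s = (config.target_total_len_mean - nm * mv) / skel_len_unit
    if s <= 0.2 or s >= 3.0:
        raise InfeasibleTargetsError(
            f"required length scale {s:.3f} outside plausible range "
            "(binding constraint: total length vs variable-branch load)"
        )

    pm = _presence_moments(template, config.skeleton_presence_scale, s)
    mean_x = pm["mean_length"] + nm * mv
    var_x = pm["var_length"] + nm * vv + nv * mv ** 2
    sg2 = (tgt_var_len - var_x) / (mean_x ** 2 + var_x)
    if sg2 < 0:
        flags["underdispersed_length"] = True
        sg2 = 0.0
    var_len = (1 + sg2) * var_x + sg2 * mean_x ** 2

    rho = config.target_varicosity_mean / config.target_total_len_mean
    vh = (tgt_var_vari - config.target_varicosity_mean - rho ** 2 * var_len) / (
        rho ** 2 * (var_len + mean_x ** 2)
    )
    if vh < 0:
        flags["underdispersed_varicosity"] = True
        vh = 0.0

    out = config.copy(
        variable_branch_rate=mu_n,
        variable_branch_count_sd=sd_n,
        length_scale=s,
        arbor_scale_sd=math.sqrt(sg2),
        varicosity_density=rho,
        varicosity_dispersion=vh,
        varicosity_retention=1.0,
        calibrated=True,
    )
    out = _calibrate_varicosity_retention(out, template, mean_x)
    exp = expected_metrics(out, template)
    for key, tgt in (
        ("branch_count", config.target_branch_mean),
        ("total_length", config.target_total_len_mean),
        ("varicosity_count", config.target_varicosity_mean),
    ):
        if abs(exp[key] - tgt) > 0.01 * tgt:
            raise InfeasibleTargetsError(
                f"calibration residual on {key}: {exp[key]:.3f} vs target {tgt}"
            )
    return out


def _calibrate_varicosity_retention(
    config: GenotypeConfig, template: SkeletonTemplate, mean_len: float,
    n_mc: int = 150, n_iter: int = 3,
) -> GenotypeConfig:
    """Compensate the hard-core placement thinning in the varicosity density.

    The strict minimum-gap rule drops a fraction of drawn varicosities on
    crowded branches, so the Poisson density is raised until the *placed*
    expectation matches the target.  The retention fraction is estimated
    by a short internal Monte-Carlo with a fixed seed derived from the
    genotype name, keeping calibration deterministic.
    """
    target = config.target_varicosity_mean
    rho = config.varicosity_density
    retention = 1.0
    seed = zlib.crc32(f"retention:{config.name}".encode()) % (2 ** 31)
    for _ in range(n_iter):
        trial = config.copy(varicosity_density=rho, varicosity_retention=retention)
        trial._calibration_checked = template  # internal trial, skip the 5% gate
        rng = np.random.default_rng(seed)
        drawn = placed = 0
        for _k in range(n_mc):
            tree = sample_arbor(trial, template, rng)
            drawn += tree.flags.get("varicosities_drawn", tree.varicosity_count)
            placed += tree.varicosity_count
        retention = placed / drawn if drawn else 1.0
        rho = target / (mean_len * retention)
    out = config.copy(varicosity_density=rho, varicosity_retention=retention)
    return out


def _check_calibrated(config: GenotypeConfig, template: SkeletonTemplate) -> None:
    if getattr(config, "_calibration_checked", None) is template:
        return
    _check_calibrated_full(config, template)
    config._calibration_checked = template


def _check_calibrated_full(config: GenotypeConfig, template: SkeletonTemplate) -> None:
    if not config.calibrated:
        raise CalibrationError(
            f"config '{config.name}' must pass through calibrate_config before sampling"
        )
    exp = expected_metrics(config, template)
    for key, tgt in (
        ("branch_count", config.target_branch_mean),
        ("total_length", config.target_total_len_mean),
        ("varicosity_count", config.target_varicosity_mean),
    ):
        if tgt > 0 and abs(exp[key] - tgt) > 0.05 * tgt:
            raise CalibrationError(
                f"config '{config.name}': expected {key} {exp[key]:.2f} deviates >5% "
                f"from target {tgt}"
            )


# --------------------------------------------------------------------------
# sampling
# --------------------------------------------------------------------------

def _rot(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _curved_polyline(
    origin: np.ndarray, direction: np.ndarray, length: float, curvature_deg: float,
    n_points: int = _POINTS_PER_BRANCH,
) -> np.ndarray:
    """Unit-speed path whose heading drifts linearly by ``curvature_deg``."""
    theta0 = math.atan2(direction[1], direction[0])
    t = np.linspace(0.0, 1.0, n_points)
    thetas = theta0 + math.radians(curvature_deg) * t
    # integrate heading between consecutive samples (midpoint rule)
    mid = 0.5 * (thetas[:-1] + thetas[1:])
    step = length / (n_points - 1)
    dx = np.cos(mid) * step
    dy = np.sin(mid) * step
    pts = np.zeros((n_points, 2))
    pts[0] = origin
    pts[1:, 0] = origin[0] + np.cumsum(dx)
    pts[1:, 1] = origin[1] + np.cumsum(dy)
    return pts


def _seg_min_dist(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    d2 = np.sum((pts_a[:, None, :] - pts_b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def _densify(poly: np.ndarray, step: float = 1.0) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return poly[:1]
    s = np.linspace(0.0, total, max(int(total / step) + 1, 2))
    return np.column_stack([np.interp(s, cum, poly[:, 0]), np.interp(s, cum, poly[:, 1])])


def _draw_trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    return max(mean, 1e-3)


def sample_arbor(
    config: GenotypeConfig,
    template: SkeletonTemplate,
    rng: np.random.Generator,
) -> ArborTree:
    """Draw one ground-truth arbor from a calibrated genotype configuration."""
    _check_calibrated(config, template)
    entry = canonical_entry_point()
    by_id = {b.id: b for b in template.branches}

    width = float(np.clip(rng.normal(REFERENCE_GANGLION_WIDTH, GANGLION_WIDTH_SD),
                          0.5 * REFERENCE_GANGLION_WIDTH, 1.5 * REFERENCE_GANGLION_WIDTH))
    sg = config.arbor_scale_sd or 0.0
    if sg > 0:
        sigma2 = math.log(1.0 + sg ** 2)
        g = float(rng.lognormal(-0.5 * sigma2, math.sqrt(sigma2)))
    else:
        g = 1.0
    s = config.length_scale

    # --- skeletal presence, lengths, geometry (template order is topological) ---
    present: dict[str, bool] = {}
    order = [b.id for b in template.branches]
    depth_of: dict[str, int] = {}
    for bid in order:
        tb = by_id[bid]
        if tb.parent_id is None:
            present[bid] = True
            depth_of[bid] = 0
            continue
        depth_of[bid] = depth_of[tb.parent_id] + 1
        p = min(1.0, tb.presence_prob * config.skeleton_presence_scale)
        present[bid] = present[tb.parent_id] and (rng.random() < p)

    lengths, dirs, afs, routing = {}, {}, {}, {}
    for bid in order:
        tb = by_id[bid]
        lengths[bid] = g * s * _draw_trunc_normal(rng, tb.mean_length, tb.sd_length)
        jitter = rng.normal(0.0, _DIRECTION_JITTER_DEG)
        d = _rot(np.asarray(tb.direction, float), jitter)
        routed = False
        if tb.parent_id is not None and present[bid] and config.routing_error_rate > 0:
            routed = rng.random() < config.routing_error_rate
        dirs[bid] = d / np.linalg.norm(d)
        routing[bid] = routed
        if tb.parent_id is None:
            afs[bid] = 0.0
        else:
            afs[bid] = float(np.clip(tb.attach_fraction + rng.normal(0.0, _ATTACH_JITTER),
                                     0.02, 0.99))
    curvatures = {bid: float(rng.normal(0.0, _CURVATURE_SD_DEG)) for bid in order}

    # reference geometry for clearance tests: canonical positions of all
    # template branches (later branches are not built yet when an earlier,
    # misrouted one must pick a trajectory)
    canonical = template_polylines(template)
    canon_dense = {bid: _densify(canonical[bid], step=2.0) for bid in order}

    branches: list[Branch] = []
    polys: dict[str, np.ndarray] = {}
    dense_built: dict[str, np.ndarray] = {}
    for bid in order:
        if not present[bid]:
            continue
        tb = by_id[bid]
        if tb.parent_id is None:
            origin = entry.copy()
        else:
            parent_poly = polys[tb.parent_id]
            seg = np.linalg.norm(np.diff(parent_poly, axis=0), axis=1)
            arc = afs[bid] * float(seg.sum())
            origin = _poly_point_at(parent_poly, arc)
        if routing[bid]:
            # misrouted branch: aberrant heading (60-120° off), chosen among
            # candidates to keep projected clearance from the rest of the arbor;
            # branches not yet built stand in at their canonical positions
            refs = [dense_built[b] for b in dense_built if b != bid]
            refs += [canon_dense[b] for b in order
                     if present[b] and b != bid and b not in dense_built]
            cloud_r = np.vstack(refs) if refs else np.zeros((0, 2))
            cands = [(float(rng.uniform(60.0, 120.0)),
                      1.0 if rng.random() < 0.5 else -1.0) for _ in range(10)]
            poly = None
            best, best_clear = None, -1.0
            for mag, sign in cands:
                d = _rot(dirs[bid], sign * mag)
                cand = _curved_polyline(origin, d, lengths[bid], curvatures[bid])
                clear = _cloud_clearance(_densify(cand, step=2.0), cloud_r, origin)
                if clear >= _VARIABLE_CLEARANCE:
                    poly = cand
                    break
                if clear > best_clear:
                    best, best_clear = cand, clear
            if poly is None:
                poly = best
        else:
            poly = _curved_polyline(origin, dirs[bid], lengths[bid], curvatures[bid])
        polys[bid] = poly
        dense_built[bid] = _densify(poly, step=2.0)
        branches.append(
            Branch(id=bid, parent_id=tb.parent_id, polyline=poly,
                   label=f"skeletal:{bid}", routing_error=routing[bid])
        )

    # --- variable branches -------------------------------------------------
    n_var = int(max(0, round(rng.normal(config.variable_branch_rate,
                                        config.variable_branch_count_sd or 0.0))))
    cloud = (np.vstack([_densify(b.polyline, step=2.0) for b in branches])
             if branches else np.zeros((0, 2)))
    skeletal = list(branches)
    weights = np.array([b.length for b in skeletal], float)
    weights = weights / weights.sum() if weights.sum() > 0 else None
    cum_w = np.cumsum(weights) if weights is not None else None
    for k in range(n_var):
        vid = f"v{k + 1:02d}"
        vlen = g * _draw_trunc_normal(
            rng, config.variable_branch_mean_len, config.variable_branch_sd_len
        )
        placed = None
        best = None
        best_clear = -1.0
        for _attempt in range(25):
            pi = int(np.searchsorted(cum_w, rng.random())) if cum_w is not None else 0
            parent = skeletal[min(pi, len(skeletal) - 1)]
            af = rng.uniform(0.10, 0.92)
            arc = af * parent.length
            origin = parent.point_at(arc)
            # local parent heading at the attachment
            h = _local_heading(parent.polyline, arc)
            ang = rng.uniform(35.0, 110.0) * (1.0 if rng.random() < 0.5 else -1.0)
            d = _rot(h, ang)
            cand = _curved_polyline(origin, d, vlen, float(rng.normal(0, _CURVATURE_SD_DEG)))
            cand_dense = _densify(cand, step=2.0)
            clear = _cloud_clearance(cand_dense, cloud, origin)
            # crowded arbors: relax the requirement as attempts accumulate
            need = _VARIABLE_CLEARANCE if _attempt < 12 else 0.75 * _VARIABLE_CLEARANCE
            if clear >= need:
                placed = (parent.id, cand, cand_dense)
                break
            if clear > best_clear:
                best, best_clear = (parent.id, cand, cand_dense), clear
        if placed is None:  # crowded arbor: keep the best-clearance candidate
            placed = best
        pid, poly, pdense = placed
        vb = Branch(id=vid, parent_id=pid, polyline=poly, label="variable")
        branches.append(vb)
        cloud = np.vstack([cloud, pdense])

    # --- varicosities ------------------------------------------------------
    vh = config.varicosity_dispersion or 0.0
    h_mult = float(rng.gamma(1.0 / vh, vh)) if vh > 0 else 1.0
    rho = config.varicosity_density or 0.0
    child_attach: dict[str, list[float]] = {b.id: [] for b in branches}
    for b in branches:
        if b.parent_id is not None and b.parent_id in child_attach:
            parent = next(x for x in branches if x.id == b.parent_id)
            arc = _arc_of_nearest(parent, b.polyline[0])
            child_attach[b.parent_id].append(arc)
    n_drawn = 0
    for b in branches:
        lam = rho * h_mult * b.length
        n_vari = int(rng.poisson(lam)) if lam > 0 else 0
        n_drawn += n_vari
        positions = _place_varicosities(rng, b.length, n_vari, child_attach[b.id])
        for pos in positions:
            b.varicosities.append(
                Varicosity(
                    arc_position=pos,
                    diameter=float(rng.uniform(*VARICOSITY_DIAMETER_RANGE)),
                    intensity_gain=float(rng.uniform(*VARICOSITY_GAIN_RANGE)),
                )
            )

    guidance = rng.random() < config.guidance_error_rate

    # scale to the animal's ganglion width (normalization later inverts this)
    factor = width / REFERENCE_GANGLION_WIDTH
    for b in branches:
        b.polyline = b.polyline * factor
        for v in b.varicosities:
            v.arc_position *= factor
    tree = ArborTree(
        entry_point=entry * factor + (np.array([0.0, METATHORACIC_SHIFT]) if guidance else 0.0),
        ganglion_width=width,
        branches=branches,
        entry_region="metathoracic" if guidance else "mesothoracic",
        genotype=config.name,
        guidance_error=guidance,
        flags={"size_factor": g, "varicosities_drawn": n_drawn},
    )
    return tree


def sample_cohort(
    config: GenotypeConfig,
    template: SkeletonTemplate,
    rng: np.random.Generator,
    n: Optional[int] = None,
) -> list[ArborTree]:
    """Draw an independent cohort (default size ``config.n_animals``)."""
    count = config.n_animals if n is None else n
    if count < 1:
        raise CalibrationError("cohort size must be >= 1")
    return [sample_arbor(config, template, rng) for _ in range(count)]


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _cloud_clearance(
    cand_dense: np.ndarray, cloud: np.ndarray, origin: np.ndarray
) -> float:
    """Projected distance from a candidate polyline to the arbor point cloud.

    Points within the clearance radius of the candidate's own origin (the
    attachment junction neighbourhood, which necessarily touches) are
    excluded on both sides.
    """
    if len(cloud) == 0:
        return np.inf
    test = cand_dense[cdist(cand_dense, origin[None, :])[:, 0] > _VARIABLE_CLEARANCE]
    if len(test) == 0:
        return np.inf
    ref = cloud[cdist(cloud, origin[None, :])[:, 0] > _VARIABLE_CLEARANCE]
    if len(ref) == 0:
        return np.inf
    return float(cdist(test, ref).min())


def _poly_point_at(poly: np.ndarray, arc: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = float(np.clip(arc, 0.0, cum[-1]))
    i = min(int(np.searchsorted(cum, arc, side="right") - 1), len(seg) - 1)
    t = 0.0 if seg[i] == 0 else (arc - cum[i]) / seg[i]
    return poly[i] + t * (poly[i + 1] - poly[i])


def _local_heading(poly: np.ndarray, arc: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    i = min(int(np.searchsorted(cum, arc, side="right") - 1), len(seg) - 1)
    d = poly[i + 1] - poly[i]
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([1.0, 0.0])


def _arc_of_nearest(branch: Branch, point: np.ndarray) -> float:
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
            best_d = d
            best_arc = cum[i] + t * seg[i]
    return best_arc


def _place_varicosities(
    rng: np.random.Generator, length: float, n: int, junction_arcs: list[float]
) -> list[float]:
    """Positions with a strict hard-core gap, away from ends and junctions.

    The gap is a resolvability constraint: swellings closer than the gap
    are not separable in projection, so a branch saturates at its packing
    capacity and excess draws are dropped (only relevant in the extreme
    upper tail of the per-animal varicosity-rate distribution).
    """
    if n <= 0:
        return []
    if length <= 2 * VARICOSITY_END_MARGIN:
        lo, hi = 0.3 * length, 0.7 * length
    else:
        lo, hi = VARICOSITY_END_MARGIN, length - VARICOSITY_END_MARGIN
    placed: list[float] = []
    for _ in range(n):
        for _try in range(60):
            pos = float(rng.uniform(lo, hi))
            if any(abs(pos - p) < VARICOSITY_MIN_GAP for p in placed):
                continue
            if any(abs(pos - j) < VARICOSITY_END_MARGIN for j in junction_arcs):
                continue
            placed.append(pos)
            break
        # no break: branch is at packing capacity; the draw is dropped
    return sorted(placed)
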