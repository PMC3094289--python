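"""Synthetic epifluorescence rendering of arbors and IHC fiber fields.

The renderer draws each branch as a tube with Gaussian cross-section
(FWHM = ``axon_width``) by exponentiating a Euclidean distance transform
of the rasterized centerline, adds varicosities as Gaussian blobs of
their own diameter and intensity gain, distributes each branch across
z-slices with a Gaussian focal profile, then applies the PSF blur and
additive Gaussian noise over a constant background.  Maximum-intensity
projection therefore recovers an image close to the 2-D scene, matching
the projection-based analysis downstream.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .types import ArborTree, ImageStack, RenderParams

__all__ = ["render_stack", "render_ihc_pair", "FWHM_TO_SIGMA"]

#: FWHM = 2·sqrt(2 ln 2)·sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_MARGIN_UM = 8.0

#: pixel size at which ``RenderParams.amplitude`` is defined; intensity per
#: pixel scales with pixel area (photon integration over the pixel)
_REFERENCE_PIXEL = 0.5


def _area_amplitude(params: RenderParams) -> float:
    return params.amplitude * (params.pixel_size / _REFERENCE_PIXEL) ** 2


def _dense_points(poly: np.ndarray, step: float) -> np.ndarray:
    out = [poly[:1]]
    for a, b in zip(poly[:-1], poly[1:]):
        seg = float(np.linalg.norm(b - a))
        n = max(int(seg / step), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(a + t[:, None] * (b - a))
    return np.vstack(out)


def _tube_image(
    poly_um: np.ndarray, shape: tuple[int, int], origin: np.ndarray,
    pixel_size: float, sigma_um: float, amplitude: float,
) -> np.ndarray:
    """Gaussian-profile tube around a polyline, on the pixel grid."""
    ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    pts = _dense_points(poly_um, step=pixel_size * 0.5)
    cols = np.clip(((pts[:, 0] - origin[0]) / pixel_size).astype(int), 0, nx - 1)
    rows = np.clip(((pts[:, 1] - origin[1]) / pixel_size).astype(int), 0, ny - 1)
    mask[rows, cols] = True
    d_px = ndimage.distance_transform_edt(~mask)
    sigma_px = max(sigma_um / pixel_size, 0.3)
    return amplitude * np.exp(-0.5 * (d_px / sigma_px) ** 2)


def _add_blob(
    img: np.ndarray, center_um: np.ndarray, origin: np.ndarray,
    pixel_size: float, sigma_um: float, amplitude: float,
) -> None:
    ny, nx = img.shape
    cx = (center_um[0] - origin[0]) / pixel_size
    cy = (center_um[1] - origin[1]) / pixel_size
    sigma_px = max(sigma_um / pixel_size, 0.3)
    r = int(math.ceil(4 * sigma_px))
    x0, x1 = max(0, int(cx) - r), min(nx, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(ny, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-0.5 * ((ys[:, None] ** 2 + xs[None, :] ** 2) / sigma_px ** 2))
    img[y0:y1, x0:x1] += amplitude * g


def render_stack(
    arbor: ArborTree, params: RenderParams, rng: np.random.Generator
) -> ImageStack:
    """Render one arbor to a single-channel z-stack with recorded calibration.

    The arbor is centered in the field of view; if it does not fit, the
    field is expanded (flagged in metadata).  A ``degraded`` flag is set
    when ``pixel_size`` exceeds ``axon_width`` (tracing not guaranteed).
    """
    fov = list(params.field_of_view)
    flags = {}
    if params.pixel_size > params.axon_width:
        flags["degraded"] = True

    if arbor.branches:
        all_pts = np.vstack([b.polyline for b in arbor.branches])
        lo = all_pts.min(axis=0) - _MARGIN_UM
        hi = all_pts.max(axis=0) + _MARGIN_UM
        extent = hi - lo
        for ax in (0, 1):
            if extent[ax] > fov[ax]:
                fov[ax] = float(extent[ax])
                flags["fov_expanded"] = True
        center = 0.5 * (lo + hi)
        origin = center - 0.5 * np.array(fov)
    else:
        origin = np.zeros(2)

    nx = int(round(fov[0] / params.pixel_size))
    ny = int(round(fov[1] / params.pixel_size))
    sigma_w = params.axon_width * FWHM_TO_SIGMA
    n_z = params.n_slices
    stack = np.zeros((n_z, ny, nx))
    z_centers = np.arange(n_z)
    amp = _area_amplitude(params)

    for b in arbor.branches:
        img = _tube_image(b.polyline, (ny, nx), origin, params.pixel_size,
                          sigma_w, amp)
        for v in b.varicosities:
            center = b.point_at(v.arc_position)
            _add_blob(img, center, origin, params.pixel_size,
                      v.diameter * FWHM_TO_SIGMA, v.intensity_gain * amp)
        zc = float(np.clip(rng.normal(0.5 * (n_z - 1), 0.1 * n_z), 1.0, n_z - 2.0))
        wz = np.exp(-0.5 * ((z_centers - zc) / 1.2) ** 2)
        stack += wz[:, None, None] * img[None, :, :]

    psf_px = params.psf_sigma / params.pixel_size
    for k in range(n_z):
        stack[k] = ndimage.gaussian_filter(stack[k], psf_px)
    stack += params.background_level
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, None, out=stack)

    meta = {
        "origin_um": [float(origin[0]), float(origin[1])],
        "ganglion_width": float(arbor.ganglion_width),
        "entry_point_um": [float(arbor.entry_point[0]), float(arbor.entry_point[1])],
        "genotype": arbor.genotype,
        "guidance_error": bool(arbor.guidance_error),
        "entry_region": arbor.entry_region,
        **flags,
    }
    return ImageStack(voxels=stack, pixel_size=params.pixel_size,
                      z_step=params.z_step, metadata=meta)


def render_ihc_pair(
    expression_level: float, params: RenderParams, rng: np.random.Generator,
    n_fibers: int = 35,
) -> ImageStack:
    """Two-channel IHC stack: a structural fiber field (channel B, MAP1B-like)
    and a punctate signal along the same fibers scaled by ``expression_level``
    (channel A).

    All geometry and per-punctum variation are drawn before the expression
    level is applied, so channel B — and channel A up to the global scale —
    is identical across expression levels at a fixed seed.
    """
    if not 0.0 <= expression_level <= 1.0:
        raise ValueError("expression_level must lie in [0, 1]")
    fov = params.field_of_view
    nx = int(round(fov[0] / params.pixel_size))
    ny = int(round(fov[1] / params.pixel_size))
    origin = np.zeros(2)
    sigma_w = params.axon_width * FWHM_TO_SIGMA
    n_z = params.n_slices

    z_weights = []
    fiber_imgs_b = []
    fiber_imgs_a = []
    for _ in range(n_fibers):
        start = rng.uniform([0, 0], [fov[0], fov[1]])
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(60.0, 200.0)
        d = np.array([math.cos(theta), math.sin(theta)])
        poly = np.vstack([start, start + d * length])
        amp_b = _area_amplitude(params) * rng.uniform(0.7, 1.3)
        img_b = _tube_image(poly, (ny, nx), origin, params.pixel_size, sigma_w, amp_b)
        img_a = np.zeros((ny, nx))
        arc = rng.exponential(4.0)
        while arc < length:
            center = start + d * arc
            amp_a = _area_amplitude(params) * rng.uniform(0.8, 1.2)
            _add_blob(img_a, center, origin, params.pixel_size, 0.8, amp_a)
            arc += 1.0 + rng.exponential(4.0)
        zc = float(np.clip(rng.normal(0.5 * (n_z - 1), 0.15 * n_z), 0.5, n_z - 1.5))
        z_weights.append(np.exp(-0.5 * ((np.arange(n_z) - zc) / 1.2) ** 2))
        fiber_imgs_b.append(img_b)
        fiber_imgs_a.append(img_a)

    stack = np.zeros((2, n_z, ny, nx))
    for wz, ib, ia in zip(z_weights, fiber_imgs_b, fiber_imgs_a):
        stack[1] += wz[:, None, None] * ib[None, :, :]
        stack[0] += wz[:, None, None] * (expression_level * ia)[None, :, :]

    psf_px = params.psf_sigma / params.pixel_size
    for c in range(2):
        for k in range(n_z):
            stack[c, k] = ndimage.gaussian_filter(stack[c, k], psf_px)
    stack += params.background_level
    if params.noise_sd > 0:
        stack += rng.normal(0.0, params.noise_sd, size=stack.shape)
    np.clip(stack, 0.0, None, out=stack)
    meta = {"origin_um": [0.0, 0.0], "expression_level": float(expression_level),
            "channels": ["plexin_like", "map1b_like"]}
    return ImageStack(voxels=stack, pixel_size=params.pixel_size,
                      z_step=params.z_step, metadata=meta)
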