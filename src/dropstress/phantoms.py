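"""Synthetic droplets, images, aspiration ramps and channel layouts.

Every downstream stage of the toolkit is testable against these phantoms
because each comes with closed-form ground truth:

* a two-harmonic polar contour family r(theta) = R0 (1 + a1 cos(theta -
  phase) + a2 cos 2(theta - phase)) whose curvature follows the polar
  formula exactly — the minimal family that reproduces a single flattened
  contact region like the pear shape a migrating cell imprints on a
  droplet;
* a pancake contour (disc truncated by flat channel walls) whose curvature
  is exactly 1/R on the arcs and 0 on the flats;
* fluorescence-like renderings of any contour at a chosen pixel size;
* micropipette aspiration ramps following the spherical-cap equilibrium,
  with the droplet entering the pipette at the critical suction
  dP_c = 2 gamma (1/R_P - 1/R_D);
* random microchannel layouts of droplet and cell axial positions.

Rendering samples the *blurred continuous scene* (supersampled indicator,
Gaussian blur at sub-pixel resolution, block-mean integration over each
pixel) rather than blurring a rasterized mask.  Centre-point rasterization
carries an orientation-dependent edge bias of order 0.01 um which, once
amplified by the m^2 factor of spectral curvature, would dominate the
stress estimate; scene sampling keeps the phantom edge position faithful
to the analytic contour at any orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian

from .contour_geometry import Contour, GeometryError
from .population import ChannelLayout
from .segmentation import Image2D
from .tension import AspirationRamp

__all__ = [
    "ParametricContour",
    "PancakeContour",
    "make_parametric_contour",
    "parametric_curvature",
    "make_pancake_contour",
    "pancake_curvature",
    "render_contour_image",
    "simulate_aspiration_ramp",
    "make_channel_layout",
]

_DEFAULT_BACKGROUND = 20.0
_DEFAULT_FOREGROUND = 200.0


@dataclass
class ParametricContour:
    """Two-harmonic polar contour: r = R0 (1 + a1 cos t + a2 cos 2t).

    t = theta - phase.  a1 shifts mass to one side (egg asymmetry), a2
    elongates the shape and flattens its flanks; together they produce one
    distinctly flattened region, a stand-in for the deformed droplet shape
    during a cell crossing.  The radius must stay positive for all theta.
    """

    R0: float
    a1: float = 0.0
    a2: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    n_points: int = 512
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.n_points < 64:
            raise ValueError("n_points must be >= 64")
        t = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        if np.min(self._radial(t)) <= 0:
            raise ValueError(
                f"radius non-positive for a1={self.a1}, a2={self.a2}: "
                "the polar family must satisfy r(theta) > 0 everywhere"
            )

    def _radial(self, theta: np.ndarray) -> np.ndarray:
        t = np.asarray(theta) - self.phase
        return self.R0 * (1.0 + self.a1 * np.cos(t) + self.a2 * np.cos(2 * t))

    def radius(self, theta: np.ndarray) -> np.ndarray:
        """Polar radius r(theta) about the centre."""
        return self._radial(theta)


@dataclass
class PancakeContour:
    """Disc of radius R truncated by flat channel walls at y = +/- w/2.

    Models the in-plane outline of a droplet squeezed between the side
    walls of a microchannel of width w: straight wall-contact flats joined
    by circular arcs.  If 2R <= w the walls never touch the droplet and
    the shape is an untruncated circle.
    """

    R: float
    w: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.R <= 0 or self.w <= 0:
            raise ValueError("R and w must be positive")

    @property
    def truncated(self) -> bool:
        return 2 * self.R > self.w


def make_parametric_contour(p: ParametricContour) -> Contour:
    """Sample the polar family at uniform theta, counter-clockwise."""
    theta = np.linspace(0, 2 * np.pi, p.n_points, endpoint=False)
    r = p.radius(theta)
    pts = np.column_stack(
        [p.center[0] + r * np.cos(theta), p.center[1] + r * np.sin(theta)]
    )
    c = Contour(pts)
    c.meta["theta"] = theta
    return c


def parametric_curvature(
    p: ParametricContour, theta: np.ndarray | None = None
) -> np.ndarray:
    """Analytic curvature of the polar family.

    Uses kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2) with the
    derivatives of r(theta) taken in closed form.  Positive for convex
    regions of a counter-clockwise contour.
    """
    if theta is None:
        theta = np.linspace(0, 2 * np.pi, p.n_points, endpoint=False)
    t = np.asarray(theta, dtype=float) - p.phase
    r = p.R0 * (1 + p.a1 * np.cos(t) + p.a2 * np.cos(2 * t))
    rp = p.R0 * (-p.a1 * np.sin(t) - 2 * p.a2 * np.sin(2 * t))
    rpp = p.R0 * (-p.a1 * np.cos(t) - 4 * p.a2 * np.cos(2 * t))
    return (r**2 + 2 * rp**2 - r * rpp) / (r**2 + rp**2) ** 1.5


def make_pancake_contour(p: PancakeContour, n_points: int = 512) -> Contour:
    """Sample a pancake outline; arcs and flats at roughly uniform spacing.

    The returned contour's ``meta['kappa']`` holds the exact per-point
    curvature (1/R on arcs, 0 on flats).
    """
    if not p.truncated:
        circ = ParametricContour(R0=p.R, center=p.center, n_points=n_points)
        c = make_parametric_contour(circ)
        c.meta["kappa"] = np.full(n_points, 1.0 / p.R)
        return c
    half = p.w / 2.0
    # contact angle: arc exists where |R sin t| < w/2
    t0 = np.arcsin(half / p.R)
    # right arc spans (-(pi/2 - ... )) -> use angles in (-t0, t0) about +x? No:
    # flats at y = +/- half, so arcs live where |y| < half: t in (-t0, t0)
    # (right arc) and (pi - t0, pi + t0) (left arc).
    arc_len = 2 * t0 * p.R
    flat_len = 2 * np.sqrt(p.R**2 - half**2)
    total = 2 * arc_len + 2 * flat_len
    n_arc = max(int(round(n_points * arc_len / total)), 8)
    n_flat = max((n_points - 2 * n_arc) // 2, 4)
    xf = np.sqrt(p.R**2 - half**2)

    t_right = np.linspace(-t0, t0, n_arc, endpoint=False)
    right = np.column_stack([p.R * np.cos(t_right), p.R * np.sin(t_right)])
    top = np.column_stack(
        [np.linspace(xf, -xf, n_flat, endpoint=False), np.full(n_flat, half)]
    )
    t_left = np.linspace(np.pi - t0, np.pi + t0, n_arc, endpoint=False)
    left = np.column_stack([p.R * np.cos(t_left), p.R * np.sin(t_left)])
    bottom = np.column_stack(
        [np.linspace(-xf, xf, n_flat, endpoint=False), np.full(n_flat, -half)]
    )
    pts = np.vstack([right, top, left, bottom]) + p.center
    kappa = np.concatenate(
        [
            np.full(n_arc, 1.0 / p.R),
            np.zeros(n_flat),
            np.full(n_arc, 1.0 / p.R),
            np.zeros(n_flat),
        ]
    )
    c = Contour(pts)
    c.meta["kappa"] = kappa
    return c


def pancake_curvature(p: PancakeContour, contour: Contour) -> np.ndarray:
    """Exact curvature for a contour built by :func:`make_pancake_contour`."""
    if "kappa" not in contour.meta:
        raise ValueError("contour does not carry pancake ground truth")
    return contour.meta["kappa"]


def render_contour_image(
    c: Contour,
    pixel_size: float,
    noise_sd: float = 2.0,
    blur_sigma: float = 1.0,
    margin_um: float = 2.0,
    oversample: int = 8,
    background: float = _DEFAULT_BACKGROUND,
    foreground: float = _DEFAULT_FOREGROUND,
    seed: int | None = None,
) -> Image2D:
    """Render a contour as an 8-bit fluorescence-like image.

    Interior bright, exterior dark.  When ``blur_sigma > 0`` (in original
    pixels) the indicator function of the contour is sampled on an
    ``oversample``-times finer grid, blurred there, and integrated over
    each pixel, emulating optics followed by pixel integration.  With
    ``blur_sigma = 0`` the scene is sampled pointwise at pixel centres and
    the image takes exactly two intensity levels.  Gaussian noise of
    standard deviation ``noise_sd`` (intensity counts) is added last and
    the result clipped to the 8-bit range.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    pts = c.points
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    if margin_um < 2 * pixel_size:
        raise GeometryError("contour must fit in the frame with >= 2 px margin")
    origin = (xmin - margin_um, ymin - margin_um)
    w = int(np.ceil((xmax - xmin + 2 * margin_um) / pixel_size)) + 1
    h = int(np.ceil((ymax - ymin + 2 * margin_um) / pixel_size)) + 1

    ss = int(oversample) if blur_sigma > 0 else 1
    # vertex positions on the supersampled pixel grid (row-down image frame)
    cols_ss = ((pts[:, 0] - origin[0]) / pixel_size + 0.5) * ss - 0.5
    rows_ss = ((h - 1) - (pts[:, 1] - origin[1]) / pixel_size + 0.5) * ss - 0.5
    ind = np.zeros((h * ss, w * ss), dtype=float)
    rr, cc = draw_polygon(rows_ss, cols_ss, ind.shape)
    ind[rr, cc] = 1.0
    if blur_sigma > 0:
        ind = gaussian(ind, blur_sigma * ss)
        ind = ind.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = background + (foreground - background) * ind
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Image2D(
        pixels=img,
        pixel_size_um=pixel_size,
        bit_depth=8,
        origin_um=origin,
        meta={"frame_index": c.frame_index},
    )


def critical_entry_pressure(gamma: float, R_P: float, R_D: float) -> float:
    """Critical suction dP_c = 2 gamma (1/R_P - 1/R_D), in Pa.

    gamma in mN/m, radii in um; 1 mN/m / um = 1000 Pa.
    """
    if not 0 < R_P < R_D:
        raise GeometryError("need 0 < R_P < R_D for a finite critical pressure")
    return 2.0 * gamma * (1.0 / R_P - 1.0 / R_D) * 1000.0


def simulate_aspiration_ramp(
    gamma: float,
    R_P: float,
    R_D: float,
    p_step: float = 50.0,
    p_max: float = 6000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> AspirationRamp:
    """Simulate a micropipette pressure ramp on one droplet.

    For each suction dP below the critical value the tongue-cap radius
    follows the spherical-cap equilibrium 1/R_C = dP / (2 gamma) + 1/R_D
    (optionally with Gaussian measurement noise on R_C); at the first step
    at or above dP_c = 2 gamma (1/R_P - 1/R_D) the droplet enters the
    pipette and no cap radius is recorded any more.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if p_step <= 0:
        raise ValueError("p_step must be positive")
    if not 0 < R_P < R_D:
        raise GeometryError("need 0 < R_P < R_D (no finite critical pressure)")
    dpc = 0.0 if gamma == 0 else critical_entry_pressure(gamma, R_P, R_D)
    pressures = np.arange(p_step, p_max + 0.5 * p_step, p_step)
    entered = pressures >= dpc
    cap = np.full_like(pressures, np.nan)
    below = ~entered
    if gamma > 0:
        cap[below] = 1.0 / (pressures[below] / (2000.0 * gamma) + 1.0 / R_D)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cap[below] += rng.normal(0.0, noise_sd, below.sum())
    return AspirationRamp(pressures_pa=pressures, cap_radii_um=cap, entered=entered)


def make_channel_layout(
    n_droplets: int,
    n_cells: int,
    length_um: float = 2000.0,
    seed: int | None = None,
    window_um: float = 700.0,
    channel_id: str = "",
    condition: str = "",
    cell_bias_before: float | None = None,
) -> ChannelLayout:
    """Random microchannel layout with uniform axial positions.

    Droplet and cell positions are drawn uniformly on [0, length_um] and
    sorted; a seed makes the draw reproducible.  ``cell_bias_before``
    optionally places that fraction of the cells uniformly *before* the
    first droplet (emulating a population that cannot pass the obstacle);
    the remainder stay uniform over the whole channel.
    """
    if length_um <= 0:
        raise ValueError("length_um must be positive")
    if n_droplets < 0 or n_cells < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    droplets = np.sort(rng.uniform(0.0, length_um, n_droplets))
    if cell_bias_before is not None and n_droplets > 0:
        if not 0.0 <= cell_bias_before <= 1.0:
            raise ValueError("cell_bias_before must lie in [0, 1]")
        first = droplets[0]
        n_before = int(round(cell_bias_before * n_cells))
        before = rng.uniform(0.0, max(first, 1e-9), n_before)
        rest = rng.uniform(0.0, length_um, n_cells - n_before)
        cells = np.sort(np.concatenate([before, rest]))
    else:
        cells = np.sort(rng.uniform(0.0, length_um, n_cells))
    return ChannelLayout(
        droplet_positions_um=droplets,
        cell_positions_um=cells,
        window_um=window_um,
        channel_id=channel_id,
        condition=condition,
    )
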