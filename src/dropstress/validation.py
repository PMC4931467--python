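"""Self-validation protocols built on the analytic phantoms.

These routines exercise the full measurement chain under controlled
conditions: render a resting disc and a deformed (pear) droplet with a
known contact-curvature drop, run segmentation, spectral filtering and
curvature, and invert into a stress that can be compared against the
constructed ground truth.  They are used by the test suite and by the
acceptance script, and are exposed so users can re-validate the pipeline
under their own imaging parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .phantoms import ParametricContour, make_parametric_contour, parametric_curvature, render_contour_image
from .pipeline import contour_to_profile
from .segmentation import segment_droplet
from .stress import contact_stress

__all__ = [
    "solve_a2_for_delta_kappa",
    "StressRecovery",
    "stress_recovery_grid",
    "cutoff_sweep_stress",
]

_DENSE_THETA = np.linspace(0, 2 * np.pi, 4096, endpoint=False)


def _delta_kappa(R0: float, a2: float) -> float:
    """Curvature drop at the flattened flank of an a2-only pear."""
    p = ParametricContour(R0=R0, a2=a2, n_points=64)
    return 1.0 / R0 - float(parametric_curvature(p, _DENSE_THETA).min())


def solve_a2_for_delta_kappa(R0: float, dk_target: float, tol: float = 1e-10) -> float:
    """Second-harmonic amplitude producing a given contact-curvature drop.

    Bisection on the analytic curvature of the polar family; the drop is
    monotone in a2 over the bracket used.
    """
    lo, hi = 1e-6, 0.25
    if not _delta_kappa(R0, lo) < dk_target < _delta_kappa(R0, hi):
        raise ValueError(f"dk_target {dk_target} outside attainable range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _delta_kappa(R0, mid) < dk_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class StressRecovery:
    gamma_mN_per_m: float
    delta_kappa_true: float
    delta_sigma_true_pa: float
    delta_sigma_measured_pa: float

    @property
    def relative_error(self) -> float:
        return self.delta_sigma_measured_pa / self.delta_sigma_true_pa - 1.0


def _segment_and_profile(contour, pixel_size, seed, config):
    img = render_contour_image(contour, pixel_size, seed=seed)
    return contour_to_profile(segment_droplet(img, snake=config.snake_params()), config)


def stress_recovery_grid(
    gammas: tuple[float, ...] = (5.0, 8.4, 12.0),
    delta_kappas: tuple[float, ...] = (0.03, 0.06, 0.09),
    R0: float = 6.5,
    pixel_size: float = 0.1,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> list[StressRecovery]:
    """End-to-end stress recovery over a (gamma, delta-kappa) grid.

    One resting disc and one pear per delta-kappa are rendered and pushed
    through the full image pipeline; the stress for each gamma is then a
    rescaling of the same curvature drop, mirroring how the interfacial
    tension enters the physics (it never touches the imaging).
    """
    cfg = config or PipelineConfig(pixel_size_um=pixel_size)
    rest = make_parametric_contour(ParametricContour(R0=R0))
    rest_profile = _segment_and_profile(rest, pixel_size, seed, cfg)
    out: list[StressRecovery] = []
    for i, dk in enumerate(delta_kappas):
        a2 = solve_a2_for_delta_kappa(R0, dk)
        pear = make_parametric_contour(ParametricContour(R0=R0, a2=a2))
        def_profile = _segment_and_profile(pear, pixel_size, seed + 100 + i, cfg)
        for gamma in gammas:
            m = contact_stress(gamma, rest_profile, def_profile, cfg.contact_window_rad)
            out.append(
                StressRecovery(
                    gamma_mN_per_m=gamma,
                    delta_kappa_true=dk,
                    delta_sigma_true_pa=1000.0 * gamma * dk,
                    delta_sigma_measured_pa=m.delta_sigma_pa,
                )
            )
    return out


def cutoff_sweep_stress(
    rest_contour,
    def_contour,
    gamma: float = 8.4,
    harmonics: tuple[int, ...] = (8, 12, 16, 24, 32),
    config: PipelineConfig | None = None,
) -> dict[int, float]:
    """Stress from the same segmented pair across FFT low-pass cutoffs."""
    base = config or PipelineConfig()
    out = {}
    for nh in harmonics:
        cfg = PipelineConfig.from_dict({**base.to_dict(), "fft_harmonics": nh})
        rest_p = contour_to_profile(rest_contour, cfg)
        def_p = contour_to_profile(def_contour, cfg)
        m = contact_stress(gamma, rest_p, def_p, cfg.contact_window_rad)
        out[nh] = m.delta_sigma_pa
    return out
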