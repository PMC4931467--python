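"""Normal mechanical stress from resting-vs-deformed droplet curvature.

At equilibrium the Young-Laplace relation ties the pressure jump across
the droplet interface to gamma times the total curvature.  The Laplace
excess pressure is uniform over the droplet and the out-of-plane
curvature of a channel-confined (pancake) droplet does not change while a
cell squeezes past, so the extra normal stress the cell applies at the
contact is carried entirely by the *in-plane* curvature change:

    delta_sigma_NN = gamma * (kappa_rest(theta*) - kappa_def(theta*))

evaluated at theta*, the angle where the deformed (constrained) droplet's
curvature is minimal — the centre of the flattened contact region.  With
gamma in mN/m and curvature in 1/um the stress comes out in Pa after a
factor 1000, and 1 Pa is numerically identical to 1 pN/um^2.

A compressive push flattens the contact (kappa_def < kappa_rest), so
delta_sigma_NN > 0 for a cell pressing into the droplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np

from .contour_geometry import Contour, CurvatureProfile
from .tension import EstimationError

__all__ = [
    "DropletState",
    "ContactPoint",
    "StressMeasurement",
    "CohortStress",
    "PairingError",
    "match_states",
    "locate_contact",
    "contact_stress",
    "cohort_stress",
    "PA_PER_MN_PER_M_PER_UM",
]

# 1 mN/m * 1/um = 1e-3 N/m / 1e-6 m = 1000 N/m^2
PA_PER_MN_PER_M_PER_UM = 1000.0


class PairingError(RuntimeError):
    """Raised when resting/deformed frames cannot be attributed to one droplet."""


@dataclass
class DropletState:
    """A droplet observed in one frame, with its curvature profile."""

    contour: Contour
    profile: CurvatureProfile
    label: Literal["resting", "deformed"]
    frame_index: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("resting", "deformed"):
            raise ValueError("label must be 'resting' or 'deformed'")

    @property
    def centroid(self) -> np.ndarray:
        return self.profile.centroid

    def radius_equivalent(self) -> float:
        """Radius of the circle with the same enclosed area."""
        return float(np.sqrt(self.contour.area() / np.pi))


@dataclass
class ContactPoint:
    """Location of minimal curvature within the inspection window."""

    theta_star: float
    kappa_min: float
    distinct: bool = True  # False when the profile is flat (no clear contact)


@dataclass
class StressMeasurement:
    """One resting/deformed pair inverted into a normal stress."""

    gamma_mN_per_m: float
    theta_star_rad: float
    kappa_rest_per_um: float
    kappa_def_min_per_um: float
    delta_sigma_pa: float
    window_rad: tuple[float, float]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def delta_sigma_pn_per_um2(self) -> float:
        """The same stress in pN/um^2 (numerically identical to Pa)."""
        return self.delta_sigma_pa


@dataclass
class CohortStress:
    mean_pa: float
    sd_pa: float | None
    n: int


def _in_window(theta: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Membership of angles in a window, supporting wrap-around (lo > hi)."""
    lo, hi = window
    if hi - lo >= 2 * np.pi:
        return np.ones(len(theta), dtype=bool)
    th = np.mod(theta + np.pi, 2 * np.pi) - np.pi
    lo = np.mod(lo + np.pi, 2 * np.pi) - np.pi
    hi = np.mod(hi + np.pi, 2 * np.pi) - np.pi
    if lo <= hi:
        return (th >= lo) & (th <= hi)
    return (th >= lo) | (th <= hi)


def match_states(
    states: list[DropletState],
) -> list[tuple[DropletState, DropletState]]:
    """Pair each deformed state with the same droplet's nearest resting frame.

    Droplet identity is decided by centroid proximity: a resting partner
    whose centroid lies farther than one equivalent droplet radius belongs
    to a different droplet and raises :class:`PairingError`.  Among the
    resting frames of the same droplet the temporally closest one is used
    (the droplet relaxes to the same shape before and after the crossing,
    so either side of the event is acceptable).
    """
    resting = [s for s in states if s.label == "resting"]
    deformed = [s for s in states if s.label == "deformed"]
    if not resting or not deformed:
        raise PairingError("need at least one resting and one deformed state")
    pairs = []
    for d in deformed:
        dists = [float(np.hypot(*(r.centroid - d.centroid))) for r in resting]
        radius = d.radius_equivalent()
        near = [
            (abs(r.frame_index - d.frame_index), dist, i)
            for i, (r, dist) in enumerate(zip(resting, dists))
            if dist <= radius
        ]
        if not near:
            raise PairingError(
                f"deformed frame {d.frame_index}: no resting state within one "
                f"droplet radius ({radius:.2f} um); closest is {min(dists):.2f} um away"
            )
        _, _, best = min(near)
        pairs.append((resting[best], d))
    return pairs


def locate_contact(
    def_profile: CurvatureProfile,
    window: tuple[float, float] = (0.0, np.pi),
    flat_tol: float = 1e-9,
) -> ContactPoint:
    """Angle of minimal curvature of the constrained droplet.

    The search is restricted to ``window`` (default: the upper half of the
    contour, the side facing the approaching cell).  Ties are broken by
    the smallest |theta|.  A profile that is constant over the window
    within ``flat_tol`` has no distinct contact; the tie-break result is
    returned with ``distinct=False``.
    """
    mask = _in_window(def_profile.theta, window)
    if mask.sum() < 8:
        raise ValueError("contact window contains fewer than 8 profile samples")
    th = def_profile.theta[mask]
    ka = def_profile.kappa[mask]
    kmin = ka.min()
    distinct = bool(ka.max() - kmin > flat_tol)
    at_min = np.isclose(ka, kmin, rtol=0.0, atol=flat_tol)
    cand = th[at_min]
    theta_star = float(cand[np.argmin(np.abs(cand))])
    return ContactPoint(theta_star=theta_star, kappa_min=float(kmin), distinct=distinct)


def contact_stress(
    gamma: float,
    rest: CurvatureProfile,
    deform: CurvatureProfile,
    window: tuple[float, float] = (0.0, np.pi),
) -> StressMeasurement:
    """Invert the in-plane curvature change into the normal stress in Pa.

    kappa_rest is interpolated (periodic, linear) on the resting profile
    at the deformed profile's minimal-curvature angle theta*; angles on
    both profiles are measured about each contour's own area centroid, so
    a rigid translation between the frames drops out.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    contact = locate_contact(deform, window)
    kappa_rest = float(rest.kappa_at(contact.theta_star))
    delta_kappa = kappa_rest - contact.kappa_min
    delta_sigma = PA_PER_MN_PER_M_PER_UM * gamma * delta_kappa
    meta = {}
    if not contact.distinct:
        meta["no_distinct_contact"] = True
    return StressMeasurement(
        gamma_mN_per_m=gamma,
        theta_star_rad=contact.theta_star,
        kappa_rest_per_um=kappa_rest,
        kappa_def_min_per_um=contact.kappa_min,
        delta_sigma_pa=delta_sigma,
        window_rad=(float(window[0]), float(window[1])),
        meta=meta,
    )


def cohort_stress(measurements: list[StressMeasurement]) -> CohortStress:
    """Unweighted mean and sample SD across independent droplets."""
    if not measurements:
        raise EstimationError("no stress measurements to pool")
    vals = np.asarray([m.delta_sigma_pa for m in measurements])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return CohortStress(mean_pa=float(vals.mean()), sd_pa=sd, n=len(vals))
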