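"""Interfacial tension from micropipette aspiration ramps.

A droplet of radius R_D aspirated by a pipette of inner radius R_P < R_D
forms a spherical tongue cap of radius R_C at the pipette tip.  At
equilibrium the cap radius decreases as the suction dP increases; once
R_C reaches R_P the configuration becomes unstable and the droplet
suddenly enters the pipette.  That critical suction gives the interfacial
tension directly:

    gamma = dP_c / (2 (1/R_P - 1/R_D))

Units are Pa for pressures, um for radii, and mN/m for gamma
(1 Pa * um = 1e-3 mN/m, so gamma[mN/m] = dP_c[Pa] / (2 dk[1/um]) / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AspirationRamp",
    "PipetteGeometry",
    "CriticalPressure",
    "IFTEstimate",
    "EstimationError",
    "critical_pressure",
    "ift_from_critical",
    "ift_estimate",
]


class EstimationError(RuntimeError):
    """Raised when a quantity cannot be estimated from the data given."""


@dataclass
class AspirationRamp:
    """One droplet-pipette pressure ramp.

    ``pressures_pa`` must be strictly increasing.  ``cap_radii_um`` holds
    the tongue-cap radius at each step (NaN once the droplet has entered
    the pipette); ``entered`` flags the entry event and must be monotone
    (once true, stays true).  ``entered`` may be None when only cap radii
    were recorded; entry is then inferred from the cap radius reaching the
    pipette radius.
    """

    pressures_pa: np.ndarray
    cap_radii_um: np.ndarray | None = None
    entered: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pressures_pa = np.asarray(self.pressures_pa, dtype=float)
        if self.pressures_pa.ndim != 1 or len(self.pressures_pa) == 0:
            raise ValueError("pressures_pa must be a non-empty 1D array")
        if np.any(np.diff(self.pressures_pa) <= 0):
            raise ValueError("pressures must be strictly increasing")
        if self.cap_radii_um is not None:
            self.cap_radii_um = np.asarray(self.cap_radii_um, dtype=float)
            if self.cap_radii_um.shape != self.pressures_pa.shape:
                raise ValueError("cap_radii_um must match pressures_pa in length")
        if self.entered is not None:
            self.entered = np.asarray(self.entered, dtype=bool)
            if self.entered.shape != self.pressures_pa.shape:
                raise ValueError("entered must match pressures_pa in length")
            d = np.diff(self.entered.astype(int))
            if np.any(d < 0):
                raise ValueError("entered must be monotone (once true, stays true)")
        if self.entered is None and self.cap_radii_um is None:
            raise ValueError("need either entered flags or cap radii")


@dataclass
class PipetteGeometry:
    """Pipette inner radius and droplet radius, both in um."""

    R_P_um: float
    R_D_um: float

    def __post_init__(self) -> None:
        if not 0 < self.R_P_um < self.R_D_um:
            raise ValueError("need 0 < R_P < R_D")

    def curvature_gap(self) -> float:
        """1/R_P - 1/R_D in 1/um; the geometric factor of the gamma formula."""
        return 1.0 / self.R_P_um - 1.0 / self.R_D_um


@dataclass
class CriticalPressure:
    """Critical suction estimate with its bracketing uncertainty."""

    value_pa: float
    uncertainty_pa: float
    lower_bound_only: bool = False


@dataclass
class IFTEstimate:
    """Cohort interfacial tension: unweighted mean over droplets."""

    gamma_mN_per_m: float
    sd_mN_per_m: float | None
    n: int
    n_excluded: int = 0
    per_ramp: tuple[float, ...] = ()


def _entry_flags(ramp: AspirationRamp, geometry: PipetteGeometry | None) -> np.ndarray:
    if ramp.entered is not None:
        return ramp.entered
    if geometry is None:
        raise EstimationError(
            "ramp has no entry flags; pipette geometry is needed to infer entry"
        )
    # entry = the cap radius has shrunk to the pipette radius (or the
    # measurement disappeared because the droplet is inside the pipette)
    cap = ramp.cap_radii_um
    flags = np.isnan(cap) | (cap <= geometry.R_P_um)
    # make monotone: everything after the first entry counts as entered
    idx = np.argmax(flags) if flags.any() else len(flags)
    out = np.zeros(len(flags), dtype=bool)
    out[idx:] = True
    return out


def critical_pressure(
    ramp: AspirationRamp, geometry: PipetteGeometry | None = None
) -> CriticalPressure:
    """Bracket the critical suction from the entry event.

    Returns the midpoint between the last non-entered and the first
    entered pressure, with half the local step as uncertainty.  Entry at
    the very first step yields only an upper bracket: the result is
    flagged ``lower_bound_only`` (the true dP_c lies somewhere below).
    """
    flags = _entry_flags(ramp, geometry)
    if not flags.any():
        raise EstimationError("ramp did not reach the critical pressure (no entry)")
    i = int(np.argmax(flags))
    p = ramp.pressures_pa
    if i == 0:
        return CriticalPressure(
            value_pa=float(p[0]), uncertainty_pa=float(p[0]), lower_bound_only=True
        )
    mid = 0.5 * (p[i - 1] + p[i])
    half = 0.5 * (p[i] - p[i - 1])
    return CriticalPressure(value_pa=float(mid), uncertainty_pa=float(half))


def ift_from_critical(dPc_pa: float, g: PipetteGeometry) -> float:
    """Interfacial tension in mN/m from the critical suction in Pa."""
    if dPc_pa <= 0:
        raise ValueError("critical pressure must be positive")
    gap = g.curvature_gap()  # 1/um; positive by construction
    return dPc_pa / (2.0 * gap) / 1000.0


def ift_estimate(
    ramps: list[tuple[AspirationRamp, PipetteGeometry]],
) -> IFTEstimate:
    """Pool independent ramps into a mean interfacial tension.

    Each ramp yields one gamma via its critical pressure; ramps whose
    entry happened at the very first step carry no usable bracket and are
    excluded (counted in ``n_excluded``).  The cohort value is the
    unweighted mean with the sample standard deviation (absent for n = 1).
    """
    if not ramps:
        raise EstimationError("no ramps provided")
    gammas: list[float] = []
    n_excluded = 0
    for ramp, geom in ramps:
        cp = critical_pressure(ramp, geom)
        if cp.lower_bound_only:
            n_excluded += 1
            continue
        gammas.append(ift_from_critical(cp.value_pa, geom))
    if not gammas:
        raise EstimationError("no valid ramps (all entries at the first step)")
    arr = np.asarray(gammas)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else None
    return IFTEstimate(
        gamma_mN_per_m=float(arr.mean()),
        sd_mN_per_m=sd,
        n=len(arr),
        n_excluded=n_excluded,
        per_ramp=tuple(gammas),
    )
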