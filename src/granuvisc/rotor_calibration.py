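"""Lifetime <-> viscosity calibration for a BODIPY molecular rotor.

A molecular rotor loses excited-state energy through an intramolecular
rotation whose rate falls as the medium gets more viscous, so its fluorescence
lifetime grows with viscosity.  Above ~20 cP the relationship is an empirical
power law (Forster-Hoffmann behaviour),

    tau = a * eta**x,        20 cP <= eta <= domain_max,

which is linear in log-log space and is fitted here by ordinary least squares
on log(lifetime) vs log(viscosity).  The restriction to eta >= 20 cP is part
of the calibration contract: the rotor is not a reliable viscometer below it,
and conversions outside the fitted domain are clipped and flagged.

The module also supplies glycerol-water viscosity standards (the classical way
to build such a calibration) and relative quantum-yield computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "QuantumYieldInputs",
    "DomainError",
    "InsufficientDataError",
    "glycerol_water_viscosity",
    "fit_forster_hoffmann",
    "lifetime_from_viscosity",
    "viscosity_from_lifetime",
    "quantum_yield",
    "default_calibration",
]


class DomainError(ValueError):
    """Input outside the physically supported domain."""


class InsufficientDataError(ValueError):
    """Too few calibration points inside the fitting domain."""


# ---------------------------------------------------------------------------
# Glycerol-water viscosity standards
# ---------------------------------------------------------------------------
# Dynamic viscosity (cP) of glycerol-water mixtures vs glycerol WEIGHT percent,
# from Segur & Oberstar, Ind. Eng. Chem. 43 (1951) 2117, at 20 and 30 degC.
_GLYC_WEIGHT_PCT = np.arange(0.0, 101.0, 10.0)
_GLYC_CP_20C = np.array(
    [1.005, 1.31, 1.76, 2.50, 3.72, 6.00, 10.8, 22.5, 60.1, 219.0, 1412.0]
)
_GLYC_CP_30C = np.array(
    [0.8007, 1.03, 1.35, 1.87, 2.72, 4.21, 7.19, 14.1, 33.9, 109.0, 612.0]
)
_RHO_GLYCEROL = 1.261  # g/mL, ~20 degC
_RHO_WATER = 0.998


def glycerol_water_viscosity(
    glycerol_volume_fraction: float, temperature: float = 20.0
) -> float:
    """Viscosity (cP) of a glycerol-water mixture.

    Parameters
    ----------
    glycerol_volume_fraction : float in [0, 1]
        Volume fraction of glycerol (mixtures are prepared volumetrically in
        10% increments; any fraction in [0, 1] is accepted).
    temperature : float
        Mixture temperature in degC, supported range [15, 30].

    Interpolates the embedded reference table log-linearly in viscosity, both
    along the composition axis and between the 20/30 degC anchor columns
    (log-linear extrapolation down to 15 degC).  Monotonically increasing in
    the glycerol fraction.
    """
    phi = float(glycerol_volume_fraction)
    if not 0.0 <= phi <= 1.0:
        raise DomainError(f"glycerol volume fraction {phi} outside [0, 1]")
    if not 15.0 <= float(temperature) <= 30.0:
        raise DomainError(f"temperature {temperature} degC outside [15, 30]")
    # volume -> weight fraction via component densities
    m_g = phi * _RHO_GLYCEROL
    w_pct = 100.0 * m_g / (m_g + (1.0 - phi) * _RHO_WATER)
    log_eta_20 = np.interp(w_pct, _GLYC_WEIGHT_PCT, np.log(_GLYC_CP_20C))
    log_eta_30 = np.interp(w_pct, _GLYC_WEIGHT_PCT, np.log(_GLYC_CP_30C))
    frac = (float(temperature) - 20.0) / 10.0
    return float(np.exp(log_eta_20 + frac * (log_eta_30 - log_eta_20)))


# ---------------------------------------------------------------------------
# Calibration curve
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CalibrationPoint:
    viscosity: float  # cP
    lifetime: float  # ns
    label: Optional[str] = None

    def __post_init__(self):
        if self.viscosity <= 0 or self.lifetime <= 0:
            raise DomainError("calibration points need positive viscosity and lifetime")


@dataclass(frozen=True)
class CalibrationCurve:
    """Power law tau = a * eta**x with an explicit validity domain (cP)."""

    a: float  # ns * cP**(-x)
    x: float  # dimensionless
    domain_min: float = 20.0
    domain_max: float = 1500.0
    fit_r2: Optional[float] = None
    n_points_excluded: int = 0

    def __post_init__(self):
        if self.a <= 0:
            raise DomainError("prefactor a must be positive")
        if not 0.0 <= self.x < 1.0:
            raise DomainError("exponent x must lie in [0, 1)")
        if not self.domain_min < self.domain_max:
            raise DomainError("domain_min must be below domain_max")

    # vectorised forward/inverse maps -------------------------------------
    def lifetime(self, viscosity):
        """Forward map eta -> tau; eta is clipped into the domain first."""
        eta = np.asarray(viscosity, dtype=float)
        if np.any(eta <= 0):
            raise DomainError("viscosity must be positive")
        eta = np.clip(eta, self.domain_min, self.domain_max)
        out = self.a * eta**self.x
        return float(out) if np.isscalar(viscosity) else out

    def viscosity(self, lifetime, return_flag: bool = False):
        """Inverse map tau -> eta, clipped to the domain.

        With ``return_flag=True`` also returns a boolean out-of-domain mask.
        """
        tau = np.asarray(lifetime, dtype=float)
        if np.any(tau <= 0):
            raise DomainError("lifetime must be positive")
        if self.x == 0:
            raise DomainError("flat calibration (x = 0) cannot be inverted")
        eta = (tau / self.a) ** (1.0 / self.x)
        # boundary values are in-domain; tolerate round-trip float noise
        flag = (eta < self.domain_min * (1 - 1e-9)) | (eta > self.domain_max * (1 + 1e-9))
        eta = np.clip(eta, self.domain_min, self.domain_max)
        if np.isscalar(lifetime):
            eta, flag = float(eta), bool(flag)
        if return_flag:
            return eta, flag
        return eta

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "x": self.x,
            "domain_min": self.domain_min,
            "domain_max": self.domain_max,
            "fit_r2": self.fit_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            a=d["a"],
            x=d["x"],
            domain_min=d.get("domain_min", 20.0),
            domain_max=d.get("domain_max", 1500.0),
            fit_r2=d.get("fit_r2"),
        )


def default_calibration() -> CalibrationCurve:
    """Simulator default: a = 0.4545 ns, x = 0.37, valid on [20, 1500] cP.

    Chosen so the granule viscosity presets map into the 2.5-5.0 ns lifetime
    range observed for the rotor in cells (164 cP -> 3.0 ns, 521 cP -> 4.6 ns).
    These are declared package defaults, not values fitted to any instrument.
    """
    return CalibrationCurve(a=0.4545, x=0.37, domain_min=20.0, domain_max=1500.0, fit_r2=1.0)


def fit_forster_hoffmann(
    points: Sequence[CalibrationPoint],
    domain_min: float = 20.0,
    domain_max: float = 1500.0,
) -> CalibrationCurve:
    """OLS fit of log(tau) on log(eta), restricted to eta >= domain_min.

    Points below ``domain_min`` are excluded (their count is recorded on the
    returned curve).  Requires >= 3 in-domain points.
    """
    pts = [p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points]
    in_dom = [p for p in pts if p.viscosity >= domain_min]
    n_excluded = len(pts) - len(in_dom)
    if len(in_dom) < 3:
        raise InsufficientDataError(
            f"need >= 3 calibration points with viscosity >= {domain_min} cP, got {len(in_dom)}"
        )
    log_eta = np.log([p.viscosity for p in in_dom])
    log_tau = np.log([p.lifetime for p in in_dom])
    slope, intercept = np.polyfit(log_eta, log_tau, 1)
    fitted = intercept + slope * log_eta
    sst = float(np.sum((log_tau - log_tau.mean()) ** 2))
    ssr = float(np.sum((log_tau - fitted) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
    # numerically-zero slopes (constant lifetimes) collapse to x = 0 exactly
    if abs(slope) < 1e-12:
        slope = 0.0
        intercept = float(np.mean(log_tau))
    return CalibrationCurve(
        a=float(np.exp(intercept)),
        x=float(slope),
        domain_min=domain_min,
        domain_max=domain_max,
        fit_r2=r2,
        n_points_excluded=n_excluded,
    )


def lifetime_from_viscosity(curve: CalibrationCurve, viscosity) -> float:
    """Forward conversion eta (cP) -> tau (ns); see CalibrationCurve.lifetime."""
    return curve.lifetime(viscosity)


def viscosity_from_lifetime(
    curve: CalibrationCurve, lifetime, return_flag: bool = False
):
    """Inverse conversion tau (ns) -> eta (cP), clipped to the calibration
    domain; with ``return_flag=True`` also returns the out-of-domain mask."""
    return curve.viscosity(lifetime, return_flag=return_flag)


# ---------------------------------------------------------------------------
# Quantum yield (relative method, fluorescein standard)
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class QuantumYieldInputs:
    """Inputs of the relative quantum-yield determination.

    ``Q_ref`` is the reference standard's yield (fluorescein in 0.1 M NaOH,
    0.95), ``n``/``n_ref`` solvent refractive indices, ``I``/``I_ref``
    integrated emission intensities on a common scale, ``A``/``A_ref``
    absorbances at the excitation wavelength.
    """

    Q_ref: float
    n: float
    n_ref: float
    I: float
    I_ref: float
    A: float
    A_ref: float

    def __post_init__(self):
        if not 0.0 < self.Q_ref <= 1.0:
            raise DomainError("Q_ref must be in (0, 1]")
        if self.n <= 0 or self.n_ref <= 0:
            raise DomainError("refractive indices must be positive")
        if self.I < 0 or self.I_ref < 0:
            raise DomainError("integrated intensities must be nonnegative")
        if self.A <= 0 or self.A_ref <= 0:
            raise DomainError("absorbances must be positive (degenerate at 0)")


FLUORESCEIN_Q_REF = 0.95  # fluorescein in 0.1 M NaOH


def quantum_yield(inp: QuantumYieldInputs) -> float:
    """Relative quantum yield

        Q = Q_ref * (n^2/n_ref^2) * (I/I_ref) * (1 - 10^-A_ref)/(1 - 10^-A).

    The absorptance factors use negative exponents (fraction of light absorbed
    at absorbance A is 1 - 10^-A); a printed form with positive exponents is a
    sign typo, as it would produce negative factors for any A > 0.
    """
    absorptance = -np.expm1(-inp.A * np.log(10.0))
    absorptance_ref = -np.expm1(-inp.A_ref * np.log(10.0))
    q = (
        inp.Q_ref
        * (inp.n**2 / inp.n_ref**2)
        * (inp.I / inp.I_ref)
        * (absorptance_ref / absorptance)
    )
    return float(q)
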