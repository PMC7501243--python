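"""Force and length calibration for flow magnetic tweezers.

In the flow-magnetic-tweezers geometry a DNA tether is stretched by the
combination of a vertical magnetic force and a lateral drag force, and only
the lateral (projected) bead position is observed.  Force is obtained from
the equipartition theorem applied to bead fluctuations orthogonal to flow,

    F = k_B * T * l / <dy^2>,

which requires the (unobserved) end-to-end extension ``l``.  Extension and
force are therefore solved simultaneously with the worm-like-chain (WLC)
interpolation formula,

    F*P/(k_B*T) = 1/4 * (1 - l/l0)^-2 - 1/4 + l/l0,

where ``P`` is the persistence length and ``l0`` the contour length.  Finite
camera integration time attenuates the measured variance (motion blur); the
attenuation factor ``S(alpha)`` with ``alpha = W/tau`` (exposure time over
trap relaxation time) is inverted self-consistently because ``tau = gamma*l/F``
itself depends on the solution.

All internal quantities are SI (m, N, s, K).  Helper accessors convert to
the conventional lab units (um, pN) at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

#: Boltzmann constant, J/K.
K_B = 1.380649e-23


class CalibrationError(ValueError):
    """Raised when a force/length solve cannot be completed."""


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters for a double-stranded DNA tether.

    Defaults describe a 21 kb construct: persistence length 46 nm,
    contour length 6.8 um, at 296 K.
    """

    persistence: float = 46e-9  # m
    contour: float = 6.8e-6     # m
    temperature: float = 296.0  # K

    def __post_init__(self) -> None:
        if not (0.0 < self.persistence < self.contour):
            raise ValueError("require 0 < persistence < contour length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kbt(self) -> float:
        return K_B * self.temperature


@dataclass(frozen=True)
class BeadModel:
    """Spherical bead in water: radius and medium viscosity.

    ``gamma`` is the Stokes friction factor 6*pi*eta*R.
    """

    radius: float = 0.5e-6      # m
    viscosity: float = 8.9e-4   # Pa s

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.viscosity <= 0:
            raise ValueError("radius and viscosity must be positive")

    @property
    def gamma(self) -> float:
        return 6.0 * math.pi * self.viscosity * self.radius


@dataclass(frozen=True)
class VarianceMeasurement:
    """Measured lateral variance orthogonal to flow.

    Attributes
    ----------
    var_y : float
        Mean-squared displacement <dy^2> in m^2.
    integration_time : float
        Camera integration (exposure) time W in seconds; 0 means no blur.
    n_samples : int
        Number of camera samples the variance was computed from.
    """

    var_y: float
    integration_time: float = 0.0
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.var_y <= 0:
            raise ValueError("var_y must be positive")
        if self.integration_time < 0:
            raise ValueError("integration time must be non-negative")


@dataclass(frozen=True)
class FlowCellGeometry:
    """Rectangular flow lane: width w, height h, volumetric flow Q (SI)."""

    width: float = 3e-3     # m
    height: float = 100e-6  # m
    flow: float = 0.0       # m^3/s

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.flow < 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def v_max(self) -> float:
        """Peak (centerline) velocity of the parabolic laminar profile."""
        return 3.0 * self.flow / (2.0 * self.width * self.height)


#: Conversion factor: 1 ul/min in m^3/s.
UL_PER_MIN = 1e-9 / 60.0


@dataclass(frozen=True)
class GeometryResult:
    """Tether angle with the surface, bead height, and projected length."""

    theta: float  # rad
    z: float      # m
    l_xy: float   # m


@dataclass
class ForceLengthSolution:
    """Self-consistent force/extension solution from lateral fluctuations."""

    force: float            # N
    extension: float        # m
    alpha: float = 0.0      # W / tau
    blur_factor: float = 1.0
    var_corrected: float = 0.0   # m^2
    tau: float = 0.0        # s, gamma / k with k = F / l
    iterations: int = 0

    @property
    def force_pn(self) -> float:
        return self.force * 1e12

    @property
    def extension_um(self) -> float:
        return self.extension * 1e6


def wlc_force(extension: float, params: WLCParams | None = None) -> float:
    """Entropic WLC force (N) at a given end-to-end extension (m).

    Uses the standard interpolation formula; it carries a known 5-7 %
    error at mid extension which is accepted here.
    """
    p = params or WLCParams()
    if extension < 0:
        raise ValueError("extension must be non-negative")
    if extension >= p.contour:
        raise ValueError("extension must be below the contour length")
    x = extension / p.contour
    return p.kbt / p.persistence * (0.25 * (1.0 - x) ** -2 - 0.25 + x)


def wlc_extension(force: float, params: WLCParams | None = None) -> float:
    """Invert the WLC interpolation: extension (m) at a given force (N)."""
    p = params or WLCParams()
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0.0:
        return 0.0
    eps = 1e-12
    lo, hi = eps, p.contour - eps
    return brentq(lambda l: wlc_force(l, p) - force, lo, hi, xtol=1e-15, rtol=8.9e-16)


def equipartition_force(var_y: float, extension: float, temperature: float = 296.0) -> float:
    """Equipartition force F = k_B*T*l / <dy^2> (all SI)."""
    if var_y <= 0 or extension <= 0 or temperature <= 0:
        raise ValueError("var_y, extension and temperature must be positive")
    return K_B * temperature * extension / var_y


def solve_force_length(var_y: float, params: WLCParams | None = None) -> ForceLengthSolution:
    """Solve equipartition + WLC simultaneously for (force, extension).

    The root of ``wlc_force(l) - k_B*T*l/var_y`` is bracketed on
    ``(0, l0)``; it is unique because the WLC force is convex while the
    equipartition force is linear in ``l``.

    Raises
    ------
    CalibrationError
        If no root is bracketed (variance too large for any tether state).
    """
    p = params or WLCParams()
    if var_y <= 0:
        raise ValueError("var_y must be positive")

    def g(l: float) -> float:
        return wlc_force(l, p) - p.kbt * l / var_y

    eps = 1e-12
    lo, hi = eps, p.contour - eps
    if g(lo) >= 0 or g(hi) <= 0:
        raise CalibrationError(
            f"no force/length root bracketed for var_y={var_y:.4g} m^2"
        )
    l = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    f = p.kbt * l / var_y
    sol = ForceLengthSolution(force=f, extension=l, var_corrected=var_y)
    resid = abs(wlc_force(l, p) - f) / f
    if resid > 1e-9:
        raise CalibrationError(f"solver residual {resid:.3g} exceeds 1e-9")
    return sol


def blur_factor(alpha: float) -> float:
    """Motion-blur variance attenuation S(alpha) for boxcar exposure.

    S = 2/alpha - 2/alpha^2 * (1 - exp(-alpha)); S -> 1 as alpha -> 0.
    A Taylor series is used for very small alpha to avoid cancellation.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if alpha < 1e-4:
        # S = 1 - a/3 + a^2/12 - a^3/60 + ...
        return 1.0 - alpha / 3.0 + alpha**2 / 12.0 - alpha**3 / 60.0
    return 2.0 / alpha - 2.0 / alpha**2 * (1.0 - math.exp(-alpha))


def solve_force_length_blurred(
    measurement: VarianceMeasurement,
    bead: BeadModel | None = None,
    params: WLCParams | None = None,
    max_iter: int = 200,
    rtol: float = 1e-9,
) -> ForceLengthSolution:
    """Blur-corrected force/length solve.

    Fixed-point iteration: starting from the uncorrected solution,
    alpha = F*W/(l*gamma) sets S(alpha); the corrected variance
    var_y / S feeds back into the unblurred solver until the force
    converges.  With W = 0 this reduces exactly to
    :func:`solve_force_length`.  Blur correction always lowers the
    force estimate relative to the uncorrected solve.
    """
    p = params or WLCParams()
    b = bead or BeadModel()
    w = measurement.integration_time
    sol = solve_force_length(measurement.var_y, p)
    if w == 0.0:
        sol.tau = b.gamma * sol.extension / sol.force
        return sol

    f_prev = sol.force
    for it in range(1, max_iter + 1):
        alpha = f_prev * w / (sol.extension * b.gamma)
        s = blur_factor(alpha)
        var_c = measurement.var_y / s
        sol = solve_force_length(var_c, p)
        sol.alpha = alpha
        sol.blur_factor = s
        sol.iterations = it
        if abs(sol.force - f_prev) <= rtol * abs(sol.force):
            break
        f_prev = sol.force
    else:
        raise CalibrationError(
            f"blur-corrected solver did not converge in {max_iter} iterations"
        )
    # report alpha/S consistent with the converged state
    sol.alpha = sol.force * w / (sol.extension * b.gamma)
    sol.blur_factor = blur_factor(sol.alpha)
    sol.tau = b.gamma * sol.extension / sol.force
    return sol


def bead_geometry(l_xy: float, extension: float) -> GeometryResult:
    """Tether angle and bead height from projected and true extension.

    theta = arccos(l_xy / l), z = l * sin(theta).
    """
    if extension <= 0:
        raise ValueError("extension must be positive")
    if l_xy < 0 or l_xy > extension:
        raise ValueError("projected length must lie in [0, extension]")
    theta = math.acos(l_xy / extension)
    return GeometryResult(theta=theta, z=extension * math.sin(theta), l_xy=l_xy)


def drag_force(z: float, cell: FlowCellGeometry, bead: BeadModel | None = None) -> float:
    """Stokes drag on a bead at height z in a laminar channel flow (N).

    F_d = 6*pi*eta*R*v with v = 2*v_max*(z/h)*(1 - z/h); zero at the
    walls, maximal at mid-height.
    """
    b = bead or BeadModel()
    if z < 0 or z > cell.height:
        raise ValueError("bead height must lie inside the channel")
    zh = z / cell.height
    v = 2.0 * cell.v_max * zh * (1.0 - zh)
    return b.gamma * v
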