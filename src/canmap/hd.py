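"""Ring attractor of conjunctive head-direction-by-rotation cells.

Each unit carries a coordinate (theta, nu): theta in [0, 2*pi) is the internal
head direction (periodic ring), nu in [-L_r, L_r] a dimensionless rotation
coordinate.  The recurrent weight from a presynaptic unit (theta', nu') to a
postsynaptic unit (theta, nu) is

    J = J0 + J1 * cos(theta - theta' - nu') * cos(lambda * (nu - nu')),

so the postsynaptic unit maximally driven by theta' is shifted to
theta' + nu': the asymmetry makes the bump travel around the ring at a speed
set by its position on the rotation axis.  A Gaussian velocity-tuned input
centred at u(V) = arctan(tau * V) selects that position, which is how the
network path-integrates angular velocity.  Heading and rotation are read out
as the angles of first-order population Fourier sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HDConfig
from .errors import DivergenceError, UndecodableStateError, VelocityRangeError

__all__ = [
    "HDState",
    "HDDecoding",
    "WeightKernel",
    "theta_coords",
    "nu_coords",
    "build_hd_weight_kernel",
    "angular_velocity_input",
    "hd_step",
    "decode_heading",
    "phase_to_angular_velocity",
    "initial_state",
    "settle",
]

#: normalized-integral resultant below which decoding is refused
RESULTANT_FLOOR = 1e-9


def theta_coords(config: HDConfig) -> np.ndarray:
    """Direction lattice: theta_i = 2*pi*i / n_theta (periodic)."""
    return 2.0 * np.pi * np.arange(config.n_theta) / config.n_theta


def nu_coords(config: HDConfig) -> np.ndarray:
    """Rotation lattice: n_nu points spanning [-L_r, L_r] (non-periodic)."""
    return np.linspace(-config.L_r, config.L_r, config.n_nu)


def nu_quadrature(n_nu: int) -> np.ndarray:
    """Trapezoid weights of the normalized measure (1/2L) * integral dnu.

    The endpoint-inclusive lattice has spacing 2L/(n-1); trapezoid weights
    c_i/(n-1) with c = [1/2, 1, ..., 1, 1/2] sum exactly to one, matching the
    continuum normalization.  (The periodic theta axis uses plain 1/n, which
    is exact there.)
    """
    w = np.ones(n_nu)
    w[0] = w[-1] = 0.5
    return w / (n_nu - 1)


@dataclass
class HDState:
    """Non-negative firing-rate field m(theta, nu) at simulation time t."""

    rates: np.ndarray  # shape (n_theta, n_nu)
    t: float = 0.0


@dataclass
class HDDecoding:
    """Population-vector readout of the ring state."""

    psi: float             # heading phase in [0, 2*pi)
    phi: float             # rotation phase in (-L_r, L_r)
    resultant_psi: float   # modulus of the normalized Fourier integral for psi
    resultant_phi: float   # modulus of the normalized Fourier integral for phi


class WeightKernel:
    """Shift-structured recurrent weights of a conjunctive attractor.

    Stores the full (n_units, n_units) matrix for the drive computation and
    exposes ``evaluate`` for pointwise inspection.  The normalized double
    integral over presynaptic coordinates is discretized with weight 1/n on
    the periodic theta axis and trapezoid weights on the nu axis
    (``presyn_weights`` holds the combined per-unit weights, summing to 1).
    """

    def __init__(self, matrix: np.ndarray, presyn_weights: np.ndarray, evaluate) -> None:
        self.matrix = matrix
        self.presyn_weights = presyn_weights  # same shape as the rate field
        self._evaluate = evaluate
        self.n_units = matrix.shape[0]

    def evaluate(self, theta, nu, theta_p, nu_p):
        """Weight from presynaptic (theta_p, nu_p) to postsynaptic (theta, nu)."""
        return self._evaluate(theta, nu, theta_p, nu_p)

    def drive(self, rates: np.ndarray) -> np.ndarray:
        """Quadrature of J * m over presynaptic units, shaped like ``rates``."""
        weighted = (self.presyn_weights * rates).reshape(-1)
        return (self.matrix @ weighted).reshape(rates.shape)


def build_hd_weight_kernel(config: HDConfig) -> WeightKernel:
    """Construct the ring-attractor weights J0 + J1 cos(dtheta - nu') cos(lambda dnu)."""
    th = theta_coords(config)
    nu = nu_coords(config)

    def evaluate(theta, nu_, theta_p, nu_p):
        return config.J0 + config.J1 * np.cos(
            np.asarray(theta) - theta_p - nu_p
        ) * np.cos(config.lambda_v * (np.asarray(nu_) - nu_p))

    # postsynaptic axes first: (theta, nu, theta', nu')
    dtheta = th[:, None, None, None] - th[None, None, :, None] - nu[None, None, None, :]
    dnu = nu[None, :, None, None] - nu[None, None, None, :]
    J = config.J0 + config.J1 * np.cos(dtheta) * np.cos(config.lambda_v * dnu)
    n = config.n_units
    w = nu_quadrature(config.n_nu)[None, :] / config.n_theta  # (1, n_nu) -> broadcast
    weights = np.broadcast_to(w, (config.n_theta, config.n_nu)).copy()
    return WeightKernel(J.reshape(n, n), weights, evaluate)


def angular_velocity_input(V: float, config: HDConfig) -> np.ndarray:
    """Gaussian rotation-tuned input field for angular velocity V [rad/s].

    The field is constant along theta and peaks at u(V) = arctan(tau * V) on
    the nu axis, with amplitude I_r * (1 - eps + eps * exp(...)).
    """
    u = np.arctan(config.tau * V)
    if abs(u) >= config.L_r:
        raise VelocityRangeError(
            f"angular velocity {V} rad/s maps to nu={u:.4g}, outside (-L_r, L_r)"
            f" with L_r={config.L_r}"
        )
    nu = nu_coords(config)
    tuning = np.exp(-((nu - u) ** 2) / (2.0 * config.sigma_r**2))
    field = config.I_r * (1.0 - config.epsilon + config.epsilon * tuning)
    return np.broadcast_to(field[None, :], (config.n_theta, config.n_nu)).copy()


def hd_step(
    state: HDState,
    ext_input: np.ndarray,
    view_input: np.ndarray | float,
    config: HDConfig,
    kernel: WeightKernel,
) -> HDState:
    """One explicit-Euler update of tau*dm/dt = -m + [J*m + I_nu + I_view]+."""
    m = state.rates
    drive = kernel.drive(m) + ext_input + view_input
    m_new = m + (config.dt / config.tau) * (-m + np.maximum(drive, 0.0))
    # exponentially decaying rates reach subnormal range and stall the BLAS
    # kernels; anything below 1e-12 is numerically zero for this model
    m_new[m_new < 1e-12] = 0.0
    if not np.all(np.isfinite(m_new)):
        raise DivergenceError(
            f"non-finite rates in hd_step at t={state.t + config.dt:.4f}s"
        )
    return HDState(rates=m_new, t=state.t + config.dt)


def decode_heading(
    state: HDState, config: HDConfig, floor: float = RESULTANT_FLOOR
) -> HDDecoding:
    """Fourier readout: psi = arg of the D-measure integral of m e^{i theta};
    phi = arg of the integral of m e^{i lambda nu}, divided by lambda."""
    m = state.rates
    th = theta_coords(config)
    nu = nu_coords(config)
    w = nu_quadrature(config.n_nu) / config.n_theta
    mw = m * w[None, :]
    z_psi = np.sum(mw * np.exp(1j * th)[:, None])
    z_phi = np.sum(mw * np.exp(1j * config.lambda_v * nu)[None, :])
    r_psi = abs(z_psi)
    r_phi = abs(z_phi)
    if r_psi < floor or r_phi < floor:
        raise UndecodableStateError(
            f"resultant ({r_psi:.3g}, {r_phi:.3g}) below floor {floor:.3g}"
        )
    psi = float(np.angle(z_psi)) % (2.0 * np.pi)
    phi = float(np.angle(z_phi)) / config.lambda_v
    return HDDecoding(psi=psi, phi=phi, resultant_psi=r_psi, resultant_phi=r_phi)


def phase_to_angular_velocity(phi: float, config: HDConfig) -> float:
    """Invert the velocity-to-phase map: V = tan(phi) / tau."""
    if not abs(phi) < np.pi / 2:
        raise ValueError("rotation phase must satisfy |phi| < pi/2")
    return float(np.tan(phi) / config.tau)


def initial_state(config: HDConfig, seed: int = 0) -> HDState:
    """Small random rates, uniform in [0, 0.01]."""
    rng = np.random.default_rng(seed)
    return HDState(rates=rng.uniform(0.0, 0.01, (config.n_theta, config.n_nu)), t=0.0)


def settle(
    config: HDConfig,
    kernel: WeightKernel,
    seed: int = 0,
    n_steps: int = 500,
) -> HDState:
    """Let the attractor select a bump: random init, then n_steps at V = 0."""
    state = initial_state(config, seed)
    ext = angular_velocity_input(0.0, config)
    for _ in range(n_steps):
        state = hd_step(state, ext, 0.0, config, kernel)
    return state
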