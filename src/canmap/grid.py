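"""Torus attractor of conjunctive grid-by-translation cells.

Units live on a four-dimensional lattice (theta_x, theta_y, nu_x, nu_y):
spatial phases on the periodic torus and translation-velocity coordinates on
the non-periodic [-L_t, L_t] axes.  The recurrent weight

    J = J0 + Jk * cos(k * |circ(dtheta - nu')|) * cos(lambda * |dnu|)

packs k activity bumps per spatial axis (k = 2 by default) and shifts the
postsynaptic target by the presynaptic velocity coordinate nu', so the whole
grid pattern translates at a speed set by the position of the activity on the
velocity axes.  A Gaussian velocity-tuned input centred at
u(V) = (1/k) * arctan(2*pi*tau*V / S) selects that position; S [m] is the
physical distance mapped onto one torus period (the grid spacing).

The pattern phase is read out by projecting the activity onto three grid
axes (Fourier sums), two of which determine the torus position; the third is
kept as a redundancy diagnostic.  Wrapped phases are unwrapped over time and
scaled by S/(2*pi/k) to give position in metres.

The recurrent drive is evaluated as a circular convolution over the spatial
axes (FFT) contracted with a dense velocity-coupling matrix, which is exact
for the difference-only weight structure and avoids materialising the
n_units^2 matrix; ``GridKernel.dense_matrix`` builds the explicit matrix as a
reference path for small lattices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import GridConfig
from .errors import DivergenceError, UndecodableStateError, VelocityRangeError

__all__ = [
    "GridState",
    "GridDecoding",
    "ProjectionAxes",
    "PositionTracker",
    "GridKernel",
    "theta_coords",
    "nu_coords",
    "circ_dist",
    "build_grid_weight_kernel",
    "translational_velocity_input",
    "grid_step",
    "decode_grid_phases",
    "unwrap_phase",
    "phases_to_position",
    "decode_grid_velocity",
    "heading_speed_to_velocity",
    "initial_state",
    "settle",
]

RESULTANT_FLOOR = 1e-9


def theta_coords(config: GridConfig) -> np.ndarray:
    """Spatial lattice per axis: theta_i = 2*pi*i / n_theta (periodic)."""
    return 2.0 * np.pi * np.arange(config.n_theta) / config.n_theta


def nu_coords(config: GridConfig) -> np.ndarray:
    """Velocity lattice per axis: n_nu points spanning [-L_t, L_t]."""
    return np.linspace(-config.L_t, config.L_t, config.n_nu)


def nu_quadrature(n_nu: int) -> np.ndarray:
    """Trapezoid weights of (1/2L) * integral dnu on the endpoint-inclusive lattice."""
    w = np.ones(n_nu)
    w[0] = w[-1] = 0.5
    return w / (n_nu - 1)


def circ_dist(d: np.ndarray | float) -> np.ndarray | float:
    """Signed distance on the circle: mod(d + pi, 2*pi) - pi."""
    return np.mod(np.asarray(d) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class GridState:
    """Non-negative rate field m(theta_x, theta_y, nu_x, nu_y) at time t."""

    rates: np.ndarray  # shape (n_theta, n_theta, n_nu, n_nu)
    t: float = 0.0


@dataclass
class ProjectionAxes:
    """Unit vectors and wavelengths of the three grid projection axes.

    For the square torus the second grid axis makes an angle
    alpha = arctan(2) with the first; the wavelengths along the oblique axes
    shrink by sin(alpha) = 2/sqrt(5).
    """

    alpha: float = float(np.arctan(2.0))
    e: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.0, 1.0],
                [np.sin(np.arctan(2.0)), -np.cos(np.arctan(2.0))],
                [-np.sin(np.arctan(2.0)), -np.cos(np.arctan(2.0))],
            ]
        )
    )
    l: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.0, np.sin(np.arctan(2.0)), np.sin(np.arctan(2.0))]
        )
    )

    @classmethod
    def square_torus(cls) -> "ProjectionAxes":
        return cls()


@dataclass
class GridDecoding:
    """Projection-phase readout of the torus state.

    Wrapped phases psi_j live in [0, 2*pi/k); the k-fold ambiguity of the
    k-bump pattern is resolved only through unwrapping continuity.
    """

    psi1: float
    psi2: float
    psi3: float
    theta_x_hat: float       # wrapped bump centre, [0, 2*pi/k)
    theta_y_hat: float
    phi_x: float             # velocity phases in (-L_t, L_t)
    phi_y: float
    resultants: np.ndarray   # normalized Fourier-integral moduli (psi1..3, phi_x, phi_y)


class GridKernel:
    """FFT-based evaluation of the recurrent drive of the torus attractor.

    Precomputes, per presynaptic velocity label nu', the spatial profile
    G_nu'(dtheta) = cos(k * |circ(dtheta - nu')|) (rfft2) and the dense
    velocity coupling W[nu, nu'] = cos(lambda * |nu - nu'|).
    """

    def __init__(self, config: GridConfig) -> None:
        self.config = config
        nth, nnu = config.n_theta, config.n_nu
        th = theta_coords(config)
        nu = nu_coords(config)
        dth = th  # lattice of offsets, same coordinates
        # spatial profiles, one per presynaptic (nu_x', nu_y') pair
        nux = nu[:, None, None, None]
        nuy = nu[None, :, None, None]
        dx = circ_dist(dth[None, None, :, None] - nux)
        dy = circ_dist(dth[None, None, None, :] - nuy)
        G = np.cos(config.k * np.sqrt(dx**2 + dy**2))  # (nnu, nnu, nth, nth)
        self._Ghat = np.fft.rfft2(G.reshape(nnu * nnu, nth, nth))
        # velocity coupling
        dvx = nu[:, None, None, None] - nu[None, None, :, None]
        dvy = nu[None, :, None, None] - nu[None, None, None, :]
        Wv = np.cos(config.lambda_v * np.sqrt(dvx**2 + dvy**2))
        self._Wv = Wv.reshape(nnu * nnu, nnu * nnu)
        self.n_units = config.n_units
        # quadrature: 1/n per periodic theta axis, trapezoid on each nu axis
        wq = nu_quadrature(nnu)
        self._wq_pairs = np.outer(wq, wq).reshape(-1) / nth**2  # per nu'-slice
        self.presyn_weights = np.broadcast_to(
            np.outer(wq, wq)[None, None, :, :] / nth**2, (nth, nth, nnu, nnu)
        ).copy()

    def evaluate(self, theta, nu, theta_p, nu_p):
        """Pointwise weight from (theta_p, nu_p) to (theta, nu); 2-vectors each."""
        cfg = self.config
        theta = np.asarray(theta, dtype=float)
        nu = np.asarray(nu, dtype=float)
        theta_p = np.asarray(theta_p, dtype=float)
        nu_p = np.asarray(nu_p, dtype=float)
        dsp = np.sqrt(np.sum(circ_dist(theta - theta_p - nu_p) ** 2, axis=-1))
        dvel = np.sqrt(np.sum((nu - nu_p) ** 2, axis=-1))
        return cfg.J0 + cfg.Jk * np.cos(cfg.k * dsp) * np.cos(cfg.lambda_v * dvel)

    def drive(self, rates: np.ndarray) -> np.ndarray:
        """Quadrature of J * m over presynaptic units, shaped like ``rates``."""
        cfg = self.config
        nth, nnu = cfg.n_theta, cfg.n_nu
        # (thx, thy, nux, nuy) -> (nu'-pairs, thx, thy), weighted by quadrature
        m = rates.transpose(2, 3, 0, 1).reshape(nnu * nnu, nth, nth)
        mw = m * self._wq_pairs[:, None, None]
        Hhat = self._Ghat * np.fft.rfft2(mw)
        Dhat = np.tensordot(self._Wv, Hhat, axes=1)
        conv = np.fft.irfft2(Dhat, s=(nth, nth))  # integrates over theta', nu'
        total = float(mw.sum())  # D-measure integral of m
        out = cfg.J0 * total + cfg.Jk * conv
        return out.reshape(nnu, nnu, nth, nth).transpose(2, 3, 0, 1)

    def dense_matrix(self) -> np.ndarray:
        """Explicit (n_units, n_units) weight matrix; reference path for small lattices."""
        cfg = self.config
        th = theta_coords(cfg)
        nu = nu_coords(cfg)
        # coordinate list in (thx, thy, nux, nuy) order, matching rates.reshape(-1)
        coords_t = np.stack(
            np.meshgrid(th, th, indexing="ij"), axis=-1
        ).reshape(-1, 2)
        coords_v = np.stack(
            np.meshgrid(nu, nu, indexing="ij"), axis=-1
        ).reshape(-1, 2)
        tt = np.repeat(coords_t, len(coords_v), axis=0)
        vv = np.tile(coords_v, (len(coords_t), 1))
        dsp = np.sqrt(
            np.sum(circ_dist(tt[:, None, :] - tt[None, :, :] - vv[None, :, :]) ** 2, axis=-1)
        )
        dvel = np.sqrt(np.sum((vv[:, None, :] - vv[None, :, :]) ** 2, axis=-1))
        return cfg.J0 + cfg.Jk * np.cos(cfg.k * dsp) * np.cos(cfg.lambda_v * dvel)


def build_grid_weight_kernel(config: GridConfig) -> GridKernel:
    """Construct the torus-attractor weight kernel."""
    return GridKernel(config)


def velocity_to_nu(V: np.ndarray, config: GridConfig) -> np.ndarray:
    """Desired bump position on the velocity axes: u = arctan(2*pi*tau*V/S)/k."""
    V = np.asarray(V, dtype=float)
    return np.arctan(2.0 * np.pi * config.tau * V / config.S) / config.k


def translational_velocity_input(V, config: GridConfig) -> np.ndarray:
    """Gaussian velocity-tuned input for translational velocity V = (Vx, Vy) [m/s].

    Returns a field of shape (1, 1, n_nu, n_nu), broadcastable over the
    spatial axes of the state.
    """
    u = velocity_to_nu(V, config)
    if np.any(np.abs(u) >= config.L_t):
        raise VelocityRangeError(
            f"velocity {np.asarray(V)} m/s maps to nu={u}, outside (-L_t, L_t)"
            f" with L_t={config.L_t}"
        )
    nu = nu_coords(config)
    d2 = (nu[:, None] - u[0]) ** 2 + (nu[None, :] - u[1]) ** 2
    tuning = np.exp(-d2 / (2.0 * config.sigma_t**2))
    field_ = config.I_t * (1.0 - config.epsilon + config.epsilon * tuning)
    return field_[None, None, :, :]


def grid_step(
    state: GridState,
    ext_input: np.ndarray,
    view_input: np.ndarray | float,
    config: GridConfig,
    kernel: GridKernel,
) -> GridState:
    """One explicit-Euler update of tau*dm/dt = -m + [J*m + I_nu + I_view]+."""
    m = state.rates
    drive = kernel.drive(m) + ext_input + view_input
    m_new = m + (config.dt / config.tau) * (-m + np.maximum(drive, 0.0))
    m_new[m_new < 1e-12] = 0.0  # flush subnormals, see hd_step
    if not np.all(np.isfinite(m_new)):
        raise DivergenceError(
            f"non-finite rates in grid_step at t={state.t + config.dt:.4f}s"
        )
    return GridState(rates=m_new, t=state.t + config.dt)


def _wrap_period(x: float, period: float) -> float:
    return float(np.mod(x, period))


def decode_grid_phases(
    state: GridState,
    axes: ProjectionAxes,
    config: GridConfig,
    floor: float = RESULTANT_FLOOR,
) -> GridDecoding:
    """Fourier projection readout of the grid pattern phase and velocity phases.

    psi_j is the angle of sum m * exp(i*k*theta.e_j/l_j) divided by k, giving a
    wrapped phase in [0, 2*pi/k).  The torus centre estimate uses psi1 and
    psi2; psi3 serves as a redundancy check and triggers a warning when its
    reconstruction disagrees by more than two lattice spacings.
    """
    cfg = config
    m = state.rates
    th = theta_coords(cfg)
    nu = nu_coords(cfg)
    period = 2.0 * np.pi / cfg.k
    thx = th[:, None]
    thy = th[None, :]
    wq = nu_quadrature(cfg.n_nu)
    wpair = np.outer(wq, wq)
    mw = m * wpair[None, None, :, :] / cfg.n_theta**2  # D-measure weighted
    m_sp = mw.sum(axis=(2, 3))  # spatial marginal of the weighted field

    z = np.empty(3, dtype=complex)
    for j in range(3):
        proj = (thx * axes.e[j, 0] + thy * axes.e[j, 1]) / axes.l[j]
        z[j] = np.sum(m_sp * np.exp(1j * cfg.k * proj))
    zvx = np.sum(mw.sum(axis=(0, 1, 3)) * np.exp(1j * cfg.lambda_v * nu))
    zvy = np.sum(mw.sum(axis=(0, 1, 2)) * np.exp(1j * cfg.lambda_v * nu))

    resultants = np.abs(np.r_[z, zvx, zvy])
    if np.any(resultants[:2] < floor) or np.any(resultants[3:] < floor):
        raise UndecodableStateError(
            f"projection resultants {resultants} below floor {floor:.3g}"
        )

    psi = [_wrap_period(float(np.angle(zj)) / cfg.k, period) for zj in z]
    theta_y_hat = _wrap_period(psi[0] * axes.l[0], period)
    theta_x_hat = _wrap_period(
        psi[1] * axes.l[1] / np.sin(axes.alpha) + psi[0] * axes.l[0] / np.tan(axes.alpha),
        period,
    )
    # redundant third axis: reconstruct theta_x from (psi1, psi3)
    theta_x_alt = _wrap_period(
        -psi[2] * axes.l[2] / np.sin(axes.alpha) - psi[0] * axes.l[0] / np.tan(axes.alpha),
        period,
    )
    spacing = 2.0 * np.pi / cfg.n_theta
    mismatch = abs(circ_dist((theta_x_hat - theta_x_alt) * cfg.k)) / cfg.k
    if mismatch > 2.0 * spacing:
        warnings.warn(
            f"projection-axis disagreement {mismatch:.3f} rad exceeds two "
            f"lattice spacings ({2*spacing:.3f} rad)",
            RuntimeWarning,
            stacklevel=2,
        )

    phi_x = float(np.angle(zvx)) / cfg.lambda_v
    phi_y = float(np.angle(zvy)) / cfg.lambda_v
    return GridDecoding(
        psi1=psi[0],
        psi2=psi[1],
        psi3=psi[2],
        theta_x_hat=theta_x_hat,
        theta_y_hat=theta_y_hat,
        phi_x=phi_x,
        phi_y=phi_y,
        resultants=resultants,
    )


def unwrap_phase(prev_cum: float, new_wrapped: float, k: int) -> float:
    """Nearest-branch unwrapping on the period 2*pi/k.

    Returns the member of {new_wrapped + m * 2*pi/k} closest to ``prev_cum``.
    Valid while the true per-step phase change stays below half a period;
    a violation of that sampling contract is undetectable by construction.
    """
    period = 2.0 * np.pi / k
    n = np.round((prev_cum - new_wrapped) / period)
    return float(new_wrapped + n * period)


class PositionTracker:
    """Accumulates unwrapped torus phases and maps them to metres.

    The projection phases psi1 and psi2 are unwrapped over time (period
    2*pi/k each) and only then combined into the cumulative torus phases;
    combining first and unwrapping the per-axis phases instead would break
    at the wrap boundary, because the k-bump pattern is also symmetric
    under the staggered translation (pi/k, 2*pi/k), which couples the two
    axes' branch choices.

    Position satisfies (x, y) = S / (2*pi/k) * (cum_theta_x, cum_theta_y)
    at all times; callers subtract the anchor position of the settled
    pattern to obtain displacement from the origin.
    """

    def __init__(self, config: GridConfig, axes: ProjectionAxes | None = None) -> None:
        self.config = config
        self.axes = axes or ProjectionAxes.square_torus()
        self.cum_psi1 = 0.0
        self.cum_psi2 = 0.0
        self._started = False

    def begin(self, decoding: GridDecoding) -> None:
        self.cum_psi1 = decoding.psi1
        self.cum_psi2 = decoding.psi2
        self._started = True

    def update(self, decoding: GridDecoding) -> tuple[float, float]:
        if not self._started:
            self.begin(decoding)
        else:
            self.cum_psi1 = unwrap_phase(self.cum_psi1, decoding.psi1, self.config.k)
            self.cum_psi2 = unwrap_phase(self.cum_psi2, decoding.psi2, self.config.k)
        return self.position

    @property
    def cum_theta_y(self) -> float:
        return self.cum_psi1 * self.axes.l[0]

    @property
    def cum_theta_x(self) -> float:
        a = self.axes
        return (
            self.cum_psi2 * a.l[1] / np.sin(a.alpha)
            + self.cum_psi1 * a.l[0] / np.tan(a.alpha)
        )

    @property
    def position(self) -> tuple[float, float]:
        return phases_to_position(self, self.config)

    @property
    def x_hat(self) -> float:
        return self.position[0]

    @property
    def y_hat(self) -> float:
        return self.position[1]


def phases_to_position(tracker: PositionTracker, config: GridConfig) -> tuple[float, float]:
    """Map cumulative phases to metres: (x, y) = S/(2*pi/k) * cum_theta."""
    scale = config.S / (2.0 * np.pi / config.k)
    return (scale * tracker.cum_theta_x, scale * tracker.cum_theta_y)


def decode_grid_velocity(decoding: GridDecoding, config: GridConfig) -> np.ndarray:
    """Map velocity phases to metres/second: V_j = S * tan(k * phi_j) / (2*pi*tau)."""
    phi = np.array([decoding.phi_x, decoding.phi_y])
    if np.any(np.abs(config.k * phi) >= np.pi / 2):
        raise ValueError("velocity phase out of the invertible range |k*phi| < pi/2")
    return config.S * np.tan(config.k * phi) / (2.0 * np.pi * config.tau)


def heading_speed_to_velocity(speed: float, psi: float) -> np.ndarray:
    """Project running speed onto the world axes of the decoded heading."""
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return speed * np.array([np.cos(psi), np.sin(psi)])


def pattern_current(
    anchor: tuple[float, float],
    config: GridConfig,
    axes: ProjectionAxes,
    amplitude: float,
    baseline: float,
) -> np.ndarray:
    """Spatially periodic current imprinting the triad pattern at ``anchor``.

    I(theta) = amplitude * [ (1/3) sum_j cos(k (theta - anchor).e_j / l_j)
    + baseline ]; constant across the velocity axes (returned with shape
    (n_theta, n_theta, 1, 1)).  With amplitude I_p and baseline C this is the
    view-cell calibration current; with a small amplitude it serves as the
    pattern-maintenance current (see docs/methods.md).
    """
    th = theta_coords(config)
    s = np.zeros((config.n_theta, config.n_theta))
    for j in range(3):
        proj = (
            (th[:, None] - anchor[0]) * axes.e[j, 0]
            + (th[None, :] - anchor[1]) * axes.e[j, 1]
        ) / axes.l[j]
        s += np.cos(config.k * proj)
    return amplitude * (s / 3.0 + baseline)[:, :, None, None]


def maintenance_current(
    decoding: GridDecoding,
    config: GridConfig,
    axes: ProjectionAxes,
    horizon: float,
) -> np.ndarray:
    """Weak pattern-maintenance current, predictively self-anchored.

    The torus pattern at the shipped parameters is subcritical (its spatial
    mode decays without input support).  This current re-imprints the
    pattern at the phase the network itself predicts ``horizon`` seconds
    ahead — the current decoded phase advanced by the decoded phase velocity
    tan(k*phi)/(k*tau) — so it sustains the amplitude using only information
    already in the network state.  Amplitude I_maint, zero baseline.
    """
    dpx = np.tan(config.k * decoding.phi_x) / (config.k * config.tau) * horizon
    dpy = np.tan(config.k * decoding.phi_y) / (config.k * config.tau) * horizon
    anchor = (decoding.theta_x_hat + dpx, decoding.theta_y_hat + dpy)
    return pattern_current(anchor, config, axes, config.I_maint, 0.0)


def initial_state(config: GridConfig, seed: int = 0) -> GridState:
    """Small random rates, uniform in [0, 0.01]."""
    rng = np.random.default_rng(seed)
    shape = (config.n_theta, config.n_theta, config.n_nu, config.n_nu)
    return GridState(rates=rng.uniform(0.0, 0.01, shape), t=0.0)


def settle(
    config: GridConfig,
    kernel: GridKernel,
    seed: int = 0,
    n_steps: int = 500,
    axes: ProjectionAxes | None = None,
    anchor: tuple[float, float] = (0.0, 0.0),
    release_steps: int = 300,
) -> GridState:
    """Form the k-bump pattern: random init, V = 0, anchored bootstrap current.

    The settled pattern's phase anchors position (0, 0).  The bootstrap
    current (the view-current profile at ``anchor``) breaks the spatial
    symmetry; at the shipped parameters the torus pattern is not
    self-sustaining, so it is created — as in the closed-loop system — by
    the calibration input itself.  A release phase under the weak
    maintenance current follows, so the transient of withdrawing the strong
    bootstrap input has settled before the pattern phase is used to anchor
    anything.
    """
    axes = axes or ProjectionAxes.square_torus()
    state = initial_state(config, seed)
    ext = translational_velocity_input(np.zeros(2), config)
    boot = pattern_current(anchor, config, axes, config.I_p, config.C)
    for _ in range(n_steps):
        state = grid_step(state, ext, boot, config, kernel)
    block = 50  # re-anchor the maintenance current every 50 steps
    done = 0
    while done < release_steps:
        dec = decode_grid_phases(state, axes, config, floor=1e-30)
        maint = maintenance_current(dec, config, axes, 0.0)
        for _ in range(min(block, release_steps - done)):
            state = grid_step(state, ext, maint, config, kernel)
        done += block
    return state


def integrate_velocity_stream(
    velocities: np.ndarray,
    config: GridConfig,
    kernel: GridKernel,
    axes: ProjectionAxes | None = None,
    state: GridState | None = None,
    seed: int = 0,
    frame_dt: float = 0.1,
    maintain: bool = True,
) -> tuple[np.ndarray, GridState, PositionTracker]:
    """Path-integrate a stream of exact velocity vectors [m/s].

    ``velocities`` has shape (n_frames, 2); each row is held for
    ``frame_dt`` seconds and integrated with round(frame_dt/dt) network
    steps.  Returns decoded positions (n_frames, 2) relative to the start,
    the final state, and the tracker.
    """
    axes = axes or ProjectionAxes.square_torus()
    if state is None:
        state = settle(config, kernel, seed=seed, axes=axes)
    dec = decode_grid_phases(state, axes, config)
    tracker = PositionTracker(config)
    tracker.begin(dec)
    origin = np.array(tracker.position)
    substeps = max(1, round(frame_dt / config.dt))
    out = np.empty((len(velocities), 2))
    for i, v in enumerate(np.asarray(velocities, dtype=float)):
        ext = translational_velocity_input(v, config)
        view = maintenance_current(dec, config, axes, frame_dt) if maintain else 0.0
        for _ in range(substeps):
            state = grid_step(state, ext, view, config, kernel)
        dec = decode_grid_phases(state, axes, config, floor=1e-30)
        tracker.update(dec)
        out[i] = np.array(tracker.position) - origin
    return out, state, tracker
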