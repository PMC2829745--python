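"""Deformation-gradient tracking: solve dF/dt = L F along material paths.

The deformation gradient F(t, t0) of the motion map obeys the linear,
non-autonomous matrix ODE dF/dt = L(t) F with F(t0, t0) = I, where L is the
velocity gradient tensor sampled along the material trajectory.  Its
solution is the matricant — the iterated-integral series

    F(t, t0) = I + int L + int L int L + ...

— which admits an ordered multiplicative-integral representation: the limit
of products, newest factor leftmost, of either

    (I + L(t_k*) dt_k)        (linear product)   or
    exp(L(t_k*) dt_k)         (exponential product),

over a partition t0 < t1 < ... < tn = t.  Used without the limit at the
frame interval dt of the cine sequence, the linear product is first-order
accurate and cheap (the default); the exponential product preserves the
identity det exp(A) = exp(tr A) exactly, so a trace-free (incompressible)
velocity field yields det F = 1 to machine precision at any step size.
The composition rule F(t, t0) = F(t, t1) F(t1, t0) holds exactly for both.

Material trajectories are advanced by explicit Euler with one velocity
sample per frame interval (bilinearly interpolated), mirroring the
piecewise-constant-L assumption; L for the k-th interval is sampled at the
tracked position at the interval's right endpoint (t_k* = k dt).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .motion import VelocityGradientField


@dataclasses.dataclass
class TimeGrid:
    """Uniform or non-uniform frame-time grid t0 < t1 < ... < tn."""

    t0: float
    frame_times: np.ndarray  # (n,) times t_1..t_n

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        all_times = np.concatenate([[self.t0], self.frame_times])
        if np.any(np.diff(all_times) <= 0):
            raise ValueError("frame times must be strictly increasing from t0")

    @classmethod
    def uniform(cls, t0: float, dt: float, n_intervals: int) -> "TimeGrid":
        return cls(t0=t0, frame_times=t0 + dt * np.arange(1, n_intervals + 1))

    @property
    def n_intervals(self) -> int:
        return self.frame_times.size

    @property
    def deltas(self) -> np.ndarray:
        """Interval lengths dt_k = t_k - t_{k-1}."""
        return np.diff(np.concatenate([[self.t0], self.frame_times]))

    @property
    def all_times(self) -> np.ndarray:
        return np.concatenate([[self.t0], self.frame_times])


@dataclasses.dataclass
class MaterialTrajectory:
    """Tracked positions of material sample points.

    positions : (n_frames, n_seeds, 2) mm, positions[0] = seeds (reference).
    in_domain : (n_frames, n_seeds) bool — False once tracking left the
        valid region (positions are frozen there, never extrapolated).
    """

    positions: np.ndarray
    in_domain: np.ndarray

    @property
    def seeds(self) -> np.ndarray:
        return self.positions[0]

    @property
    def n_seeds(self) -> int:
        return self.positions.shape[1]


@dataclasses.dataclass
class DeformationField:
    """Per-seed deformation gradients F(t_k, t0), k = 0..n.

    F : (n_frames, n_seeds, 2, 2), F[0] = I exactly.  `valid` is False from
    the first frame at which the trajectory left the valid region onward
    (F frozen at its last valid value there).
    """

    F: np.ndarray
    valid: np.ndarray
    method: str


def step_linear(F_prev: np.ndarray, L_star: np.ndarray, dt: float) -> np.ndarray:
    """One linear-product step: (I + L* dt) F_prev.  Batched over leading axes."""
    F_prev = np.asarray(F_prev, dtype=float)
    L_star = np.asarray(L_star, dtype=float)
    eye = np.eye(2)
    return (eye + L_star * dt) @ F_prev


def expm2(A: np.ndarray) -> np.ndarray:
    """Closed-form 2x2 matrix exponential, batched over leading axes.

    Uses the Cayley-Hamilton form: with A = (tr A / 2) I + B (B trace-free,
    B^2 = mu I, mu = (tr A / 2)^2 - det A),

        exp(A) = e^{tr A / 2} (cosh(sqrt(mu)) I + sinch(sqrt(mu)) B),

    where sinch(x) = sinh(x)/x, evaluated by series near x = 0 (covering the
    degenerate-discriminant / nilpotent cases exactly to machine precision).
    """
    A = np.asarray(A, dtype=float)
    tr = A[..., 0, 0] + A[..., 1, 1]
    det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    half_tr = 0.5 * tr
    mu = half_tr**2 - det
    eye = np.eye(2)
    B = A - half_tr[..., None, None] * eye

    # cosh(sqrt(mu)) and sinh(sqrt(mu))/sqrt(mu) for mu of either sign.
    small = np.abs(mu) < 1e-12
    mu_safe = np.where(small, 1.0, mu)
    sq = np.sqrt(np.abs(mu_safe))
    cosh_term = np.where(mu_safe > 0, np.cosh(sq), np.cos(sq))
    sinch_term = np.where(mu_safe > 0, np.sinh(sq) / sq, np.sin(sq) / sq)
    # series: cosh(sqrt(mu)) = 1 + mu/2 + mu^2/24; sinch = 1 + mu/6 + mu^2/120
    cosh_term = np.where(small, 1.0 + mu / 2.0 + mu**2 / 24.0, cosh_term)
    sinch_term = np.where(small, 1.0 + mu / 6.0 + mu**2 / 120.0, sinch_term)
    out = cosh_term[..., None, None] * eye + sinch_term[..., None, None] * B
    return np.exp(half_tr)[..., None, None] * out


def step_exponential(F_prev: np.ndarray, L_star: np.ndarray, dt: float) -> np.ndarray:
    """One exponential-product step: exp(L* dt) F_prev.  Batched."""
    return expm2(np.asarray(L_star, dtype=float) * dt) @ np.asarray(F_prev, dtype=float)


def compose(F_later: np.ndarray, F_earlier: np.ndarray) -> np.ndarray:
    """Composition rule F(t, t0) = F(t, t1) F(t1, t0)."""
    return np.asarray(F_later) @ np.asarray(F_earlier)


def track_material_points(
    v_fields: list[VelocityGradientField],
    seeds: np.ndarray,
    grid: TimeGrid,
    scheme: str = "euler",
) -> MaterialTrajectory:
    """Advect seed points through the velocity fields.

    Default scheme is explicit Euler — one velocity sample per frame
    interval, x_k = x_{k-1} + v_k(x_{k-1}) dt_k — mirroring the
    piecewise-constant-L assumption of the deformation solver.  `scheme =
    "midpoint"` re-samples the (spatially varying) interval field at the
    half-step position for second-order spatial accuracy.  A trajectory
    that samples an invalid or out-of-grid pixel is frozen and flagged from
    that frame on.
    """
    if scheme not in ("euler", "midpoint"):
        raise ValueError(f"unknown advection scheme {scheme!r}")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if seeds.size == 0:
        raise ValueError("empty seed set")
    n = grid.n_intervals
    if len(v_fields) < n:
        raise ValueError(f"need {n} velocity fields, got {len(v_fields)}")
    deltas = grid.deltas
    n_seeds = seeds.shape[0]
    positions = np.empty((n + 1, n_seeds, 2))
    in_domain = np.ones((n + 1, n_seeds), dtype=bool)
    positions[0] = seeds
    for k in range(1, n + 1):
        v, _, ok = v_fields[k - 1].sample(positions[k - 1])
        if scheme == "midpoint":
            half = positions[k - 1] + np.where(
                ok[:, None] & np.isfinite(v), v, 0.0
            ) * (0.5 * deltas[k - 1])
            v2, _, ok2 = v_fields[k - 1].sample(half)
            v, ok = np.where(ok2[:, None], v2, v), ok & ok2
        alive = in_domain[k - 1] & ok
        step = np.where(alive[:, None], v * deltas[k - 1], 0.0)
        positions[k] = positions[k - 1] + np.where(np.isfinite(step), step, 0.0)
        in_domain[k] = alive
    return MaterialTrajectory(positions=positions, in_domain=in_domain)


def _sample_L(field: VelocityGradientField, pos: np.ndarray):
    _, L, ok = field.sample(pos)
    return L, ok


def integrate_deformation(
    L_seq: list[VelocityGradientField],
    traj: MaterialTrajectory,
    grid: TimeGrid,
    method: str = "linear_product",
    eulerian_sampling: bool = False,
    F0: np.ndarray | None = None,
) -> DeformationField:
    """Ordered-product solution of dF/dt = L F along each trajectory.

    F at frame k is the product of per-interval steps, newest factor
    leftmost.  L for interval k is sampled at the tracked position at the
    interval's right endpoint (t_k* = k dt); with ``eulerian_sampling`` the
    reference (frame-0) position is used instead, for comparison.  Where a
    trajectory has left the valid region, F is frozen at its last valid
    value and flagged.

    `F0` (default identity) is the initial condition F(t0, .): passing the
    deformation accumulated up to t0 continues the ordered product, so
    splitting an interval and composing reproduces the unsplit product
    exactly.
    """
    if method not in ("linear_product", "exp_product"):
        raise ValueError(f"unknown method {method!r}")
    step = step_linear if method == "linear_product" else step_exponential
    n = grid.n_intervals
    deltas = grid.deltas
    n_seeds = traj.n_seeds
    F = np.empty((n + 1, n_seeds, 2, 2))
    valid = np.ones((n + 1, n_seeds), dtype=bool)
    F[0] = np.eye(2) if F0 is None else np.asarray(F0, dtype=float)
    for k in range(1, n + 1):
        pos = traj.positions[0] if eulerian_sampling else traj.positions[k]
        L, ok = _sample_L(L_seq[k - 1], pos)
        alive = valid[k - 1] & ok & traj.in_domain[k]
        L_safe = np.where(alive[:, None, None] & np.isfinite(L), L, 0.0)
        F[k] = step(F[k - 1], L_safe, deltas[k - 1])
        F[k][~alive] = F[k - 1][~alive]  # freeze at last valid value
        valid[k] = alive
    return DeformationField(F=F, valid=valid, method=method)


def _nodal_L_samples(L_seq, traj: MaterialTrajectory, grid: TimeGrid) -> np.ndarray:
    """L at the frame times t_0..t_n along each trajectory, (n+1, n_seeds, 2, 2).

    Interval estimates are averaged onto interior nodes; end nodes take the
    one-sided interval value.  Accepts a list of VelocityGradientField or a
    raw (n+1, ..., 2, 2) array of nodal samples (passed through).
    """
    if isinstance(L_seq, np.ndarray):
        return L_seq
    n = grid.n_intervals
    n_seeds = traj.n_seeds
    interval_L = np.empty((n, n_seeds, 2, 2))
    for k in range(n):
        L, ok = _sample_L(L_seq[k], traj.positions[k])
        interval_L[k] = np.where(ok[:, None, None] & np.isfinite(L), L, 0.0)
    nodal = np.empty((n + 1, n_seeds, 2, 2))
    nodal[0] = interval_L[0]
    nodal[n] = interval_L[n - 1]
    for k in range(1, n):
        nodal[k] = 0.5 * (interval_L[k - 1] + interval_L[k])
    return nodal


def matricant_series(
    L_seq,
    traj: MaterialTrajectory,
    grid: TimeGrid,
    order: int = 3,
) -> DeformationField:
    """Truncated matricant (iterated-integral) expansion, as a cross-check.

    F ~ I + int L + int L int L + ... up to the given order (1..3), with all
    integrals evaluated by the trapezoid rule on the frame grid.  This is an
    independent discretization of the same ODE, useful for validating the
    product solvers; it is not the default solver.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    L = _nodal_L_samples(L_seq, traj, grid)  # (n+1, S, 2, 2)
    times = grid.all_times
    n_nodes = L.shape[0]
    batch = L.shape[1:-2]

    def cumtrap(integrand):
        """Cumulative trapezoid of a (n+1, ..., 2, 2) matrix function of time."""
        out = np.zeros_like(integrand)
        for k in range(1, n_nodes):
            dt = times[k] - times[k - 1]
            out[k] = out[k - 1] + 0.5 * dt * (integrand[k] + integrand[k - 1])
        return out

    eye = np.broadcast_to(np.eye(2), (n_nodes,) + batch + (2, 2)).copy()
    F = eye.copy()
    term = cumtrap(L)  # Phi_1
    F += term
    for _ in range(order - 1):
        term = cumtrap(L @ term)  # Phi_{m+1}(t) = int L(tau) Phi_m(tau) dtau
        F += term
    valid = traj.in_domain.copy() if traj is not None else np.ones((n_nodes,) + batch, dtype=bool)
    return DeformationField(F=F, valid=valid, method="matricant_series")
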