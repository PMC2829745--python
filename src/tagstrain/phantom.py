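"""Synthetic SPAMM-tagged short-axis phantoms with closed-form ground truth.

Each phantom is an analytic motion map ``x(X, t)`` for which the deformation
gradient ``F = dx/dX``, the Eulerian velocity ``v(x, t)`` and its spatial
gradient ``L = dv/dx`` are available in closed form, so every downstream
stage (phase extraction, optic flow, deformation integration, strain) can be
validated against exact oracles without any acquired data.

The physiologically motivated model is ``incompressible_annulus``: an annular
left-ventricular cross-section contracting radially while twisting, via the
area-preserving map ``r(R) = sqrt(R^2 + lambda(t))``, ``theta = Theta +
phi(t)`` with ``lambda <= 0``.  Both ``lambda`` and ``phi`` follow smooth
half-cosine ramps over a simulated systole.  Simpler motions (translation,
rigid rotation, uniform scaling, simple shear) are provided for unit-level
parameter-recovery tests.

Tag rendering paints a single-harmonic cosine pattern on the reference
configuration and passively advects it: frame k holds

    I(x, t_k) = b(t_k) * 1/2 * (1 + m * cos(k_w . X(x, t_k))) + noise,

where ``X(x, t)`` is the inverse motion map, ``m`` the modulation depth and
``b(t) = exp(-fading_rate * t)`` an optional fading envelope.  This is the
image content a harmonic-phase method actually consumes; full k-space MR
simulation is out of scope.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import ImageSequence

MODEL_KINDS = (
    "translation",
    "rigid_rotation",
    "uniform_scaling",
    "simple_shear",
    "incompressible_annulus",
)


class PhantomDomainError(ValueError):
    """The requested motion map is invalid on (part of) the model domain."""


@dataclasses.dataclass
class ImageGrid:
    """Regular 2D pixel grid: shape (ny, nx) and isotropic spacing in mm."""

    shape: tuple[int, int]
    spacing: float = 1.0

    def positions(self) -> np.ndarray:
        """(ny, nx, 2) array of physical (x, y) pixel-center positions in mm."""
        ny, nx = self.shape
        x = np.arange(nx) * self.spacing
        y = np.arange(ny) * self.spacing
        xx, yy = np.meshgrid(x, y)
        return np.stack([xx, yy], axis=-1)


@dataclasses.dataclass
class TagSpec:
    """One sinusoidal tag pattern.

    wave_vector : (2,) rad/mm — direction and spatial frequency of the tags.
    modulation_depth : in [0, 1]; 1 gives full-contrast tags.
    noise_sd : additive zero-mean Gaussian noise, in intensity units
        (the noise-free tag pattern spans [0, 1]).
    fading_rate : 1/s; 0 disables tag fading.
    """

    wave_vector: tuple[float, float]
    modulation_depth: float = 1.0
    noise_sd: float = 0.0
    fading_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if np.allclose(self.wave_vector, 0.0):
            raise ValueError("wave_vector must be nonzero")

    @property
    def tag_spacing(self) -> float:
        """Distance between tag crests in mm (2*pi / |k_w|)."""
        return 2.0 * np.pi / np.linalg.norm(self.wave_vector)


@dataclasses.dataclass
class PhantomModel:
    """Analytic motion model x(X, t) on [t0, t_end].

    parameters (by model_kind):
      translation            velocity: (2,) mm/s
      rigid_rotation         omega: rad/s (counterclockwise about center)
      uniform_scaling        scale: scale factor reached at t_end
                             (s(t) ramps linearly from 1)
      simple_shear           shear_rate: 1/s (gamma(t) = shear_rate*(t-t0))
      incompressible_annulus lam_end: mm^2 (<= 0), phi_end: rad; both follow
                             half-cosine ramps from 0 at t0 to the end value
                             at t_end. r_inner/r_outer (mm) bound the ROI.
    """

    model_kind: str
    parameters: dict
    center: tuple[float, float] = (0.0, 0.0)
    time_span: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        t0, t_end = self.time_span
        if not t_end > t0:
            raise ValueError("time_span must satisfy t_end > t0")
        if self.model_kind == "incompressible_annulus":
            lam_end = self.parameters["lam_end"]
            if lam_end > 0:
                raise PhantomDomainError("lam_end must be <= 0 (contraction)")
            r_inner = self.parameters.get("r_inner", 0.0)
            if r_inner**2 + lam_end <= 0:
                raise PhantomDomainError(
                    "annulus collapses: r_inner^2 + lam_end must stay positive"
                )

    # -- time profiles -----------------------------------------------------

    def _tau(self, t):
        t0, t_end = self.time_span
        return (np.asarray(t, dtype=float) - t0) / (t_end - t0)

    def _ramp(self, t):
        """Half-cosine ramp from 0 at t0 to 1 at t_end, and its time derivative."""
        t0, t_end = self.time_span
        tau = self._tau(t)
        value = 0.5 * (1.0 - np.cos(np.pi * tau))
        rate = 0.5 * np.pi * np.sin(np.pi * tau) / (t_end - t0)
        return value, rate

    def annulus_state(self, t):
        """(lambda, lambda_dot, phi, phi_dot) at time t."""
        value, rate = self._ramp(t)
        lam_end = self.parameters["lam_end"]
        phi_end = self.parameters["phi_end"]
        return lam_end * value, lam_end * rate, phi_end * value, phi_end * rate

    def _scaling_state(self, t):
        t0, t_end = self.time_span
        s_end = self.parameters["scale"]
        tau = self._tau(t)
        s = 1.0 + (s_end - 1.0) * tau
        s_dot = (s_end - 1.0) / (t_end - t0)
        return s, s_dot

    def _check_time(self, t) -> None:
        t0, t_end = self.time_span
        t = np.asarray(t, dtype=float)
        if np.any(t < t0 - 1e-12) or np.any(t > t_end + 1e-12):
            raise ValueError(f"time {t} outside time_span {self.time_span}")


def _rot(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def analytic_position(model: PhantomModel, X, t):
    """Material position x(X, t); X may be (..., 2)."""
    model._check_time(t)
    X = np.asarray(X, dtype=float)
    c = np.asarray(model.center)
    t0 = model.time_span[0]
    dt = t - t0
    kind = model.model_kind
    if kind == "translation":
        v = np.asarray(model.parameters["velocity"])
        return X + v * dt
    if kind == "rigid_rotation":
        R = _rot(model.parameters["omega"] * dt)
        return c + (X - c) @ R.T
    if kind == "uniform_scaling":
        s, _ = model._scaling_state(t)
        return c + s * (X - c)
    if kind == "simple_shear":
        gamma = model.parameters["shear_rate"] * dt
        rel = X - c
        out = rel.copy()
        out[..., 0] = rel[..., 0] + gamma * rel[..., 1]
        return c + out
    # incompressible annulus: r = sqrt(R^2 + lam), theta = Theta + phi
    lam, _, phi, _ = model.annulus_state(t)
    rel = X - c
    R2 = np.sum(rel**2, axis=-1)
    r2 = R2 + lam
    if np.any(r2 <= 0):
        raise PhantomDomainError("annulus radius would become imaginary")
    scale = np.sqrt(r2 / np.where(R2 > 0, R2, 1.0))
    return c + (scale[..., None] * rel) @ _rot(phi).T


def inverse_position(model: PhantomModel, x, t):
    """Reference position X(x, t): analytic inverse of the motion map."""
    model._check_time(t)
    x = np.asarray(x, dtype=float)
    c = np.asarray(model.center)
    t0 = model.time_span[0]
    dt = t - t0
    kind = model.model_kind
    if kind == "translation":
        v = np.asarray(model.parameters["velocity"])
        return x - v * dt
    if kind == "rigid_rotation":
        R = _rot(-model.parameters["omega"] * dt)
        return c + (x - c) @ R.T
    if kind == "uniform_scaling":
        s, _ = model._scaling_state(t)
        if np.any(np.isclose(s, 0.0)):
            raise PhantomDomainError("scaling through zero is not invertible")
        return c + (x - c) / s
    if kind == "simple_shear":
        gamma = model.parameters["shear_rate"] * dt
        rel = x - c
        out = rel.copy()
        out[..., 0] = rel[..., 0] - gamma * rel[..., 1]
        return c + out
    lam, _, phi, _ = model.annulus_state(t)
    rel = (x - c) @ _rot(-phi).T
    r2 = np.sum(rel**2, axis=-1)
    R2 = r2 - lam  # lam <= 0 so R2 >= r2 > 0 away from the center
    scale = np.sqrt(R2 / np.where(r2 > 0, r2, 1.0))
    return c + scale[..., None] * rel


def analytic_deformation(model: PhantomModel, X, t):
    """Ground-truth deformation gradient F(t, t0) = dx/dX at X; (..., 2, 2)."""
    model._check_time(t)
    X = np.asarray(X, dtype=float)
    c = np.asarray(model.center)
    t0 = model.time_span[0]
    dt = t - t0
    kind = model.model_kind
    batch = X.shape[:-1]
    if kind == "translation":
        return np.broadcast_to(np.eye(2), batch + (2, 2)).copy()
    if kind == "rigid_rotation":
        return np.broadcast_to(_rot(model.parameters["omega"] * dt), batch + (2, 2)).copy()
    if kind == "uniform_scaling":
        s, _ = model._scaling_state(t)
        return np.broadcast_to(s * np.eye(2), batch + (2, 2)).copy()
    if kind == "simple_shear":
        gamma = model.parameters["shear_rate"] * dt
        return np.broadcast_to(np.array([[1.0, gamma], [0.0, 1.0]]), batch + (2, 2)).copy()
    # Annulus: F = r'(R) e_r(theta) u(Theta)^T + (r/R) e_t(theta) w(Theta)^T
    # with r' = R/r, so det F = 1 identically.
    lam, _, phi, _ = model.annulus_state(t)
    rel = X - c
    R = np.linalg.norm(rel, axis=-1)
    if np.any(R == 0):
        raise PhantomDomainError("deformation undefined at the annulus center")
    r2 = R**2 + lam
    if np.any(r2 <= 0):
        raise PhantomDomainError("annulus radius would become imaginary")
    r = np.sqrt(r2)
    u = rel / R[..., None]                        # radial unit, reference
    w = np.stack([-u[..., 1], u[..., 0]], axis=-1)  # tangential unit, reference
    Rphi = _rot(phi)
    e_r = u @ Rphi.T
    e_t = w @ Rphi.T
    F = (
        (R / r)[..., None, None] * e_r[..., :, None] * u[..., None, :]
        + (r / R)[..., None, None] * e_t[..., :, None] * w[..., None, :]
    )
    return F


def analytic_velocity_gradient(model: PhantomModel, x, t):
    """Eulerian velocity v(x, t) and gradient L = dv/dx at spatial points x.

    Returns (v, L) with shapes (..., 2) and (..., 2, 2).  Satisfies
    dF/dt = L F at matching material points, and trace(L) = 0 for the
    incompressible annulus.
    """
    model._check_time(t)
    x = np.asarray(x, dtype=float)
    c = np.asarray(model.center)
    batch = x.shape[:-1]
    kind = model.model_kind
    if kind == "translation":
        v = np.broadcast_to(np.asarray(model.parameters["velocity"], dtype=float), batch + (2,)).copy()
        return v, np.zeros(batch + (2, 2))
    if kind == "rigid_rotation":
        omega = model.parameters["omega"]
        rel = x - c
        J = np.array([[0.0, -1.0], [1.0, 0.0]])
        v = omega * rel @ J.T
        return v, np.broadcast_to(omega * J, batch + (2, 2)).copy()
    if kind == "uniform_scaling":
        s, s_dot = model._scaling_state(t)
        rate = s_dot / s
        rel = x - c
        return rate * rel, np.broadcast_to(rate * np.eye(2), batch + (2, 2)).copy()
    if kind == "simple_shear":
        g_dot = model.parameters["shear_rate"]
        rel = x - c
        v = np.zeros_like(rel)
        v[..., 0] = g_dot * rel[..., 1]
        L = np.array([[0.0, g_dot], [0.0, 0.0]])
        return v, np.broadcast_to(L, batch + (2, 2)).copy()
    # Annulus: v = (lam_dot/2) * x_rel / r^2 + phi_dot * J x_rel  (trace-free)
    _, lam_dot, _, phi_dot = model.annulus_state(t)
    rel = x - c
    r2 = np.sum(rel**2, axis=-1)
    if np.any(r2 <= 0):
        raise PhantomDomainError("velocity undefined at the annulus center")
    J = np.array([[0.0, -1.0], [1.0, 0.0]])
    v = 0.5 * lam_dot * rel / r2[..., None] + phi_dot * rel @ J.T
    eye = np.eye(2)
    outer = rel[..., :, None] * rel[..., None, :]
    L = 0.5 * lam_dot * (eye / r2[..., None, None] - 2.0 * outer / (r2**2)[..., None, None])
    L = L + phi_dot * J
    return v, L


def render_tagged_sequence(
    model: PhantomModel,
    tag: TagSpec,
    grid: ImageGrid,
    n_frames: int,
    rng: np.random.Generator | int | None = None,
) -> ImageSequence:
    """Render a tagged cine sequence: tags painted at t0, advected with the tissue."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(rng)
    t0, t_end = model.time_span
    dt = (t_end - t0) / (n_frames - 1)
    pos = grid.positions()
    kx, ky = tag.wave_vector
    frames = np.empty((n_frames,) + grid.shape, dtype=np.float64)
    for k in range(n_frames):
        t_k = t0 + k * dt
        X = inverse_position(model, pos, t_k)
        envelope = np.exp(-tag.fading_rate * (t_k - t0))
        img = envelope * 0.5 * (1.0 + tag.modulation_depth * np.cos(kx * X[..., 0] + ky * X[..., 1]))
        if tag.noise_sd > 0:
            img = img + rng.normal(0.0, tag.noise_sd, size=img.shape)
        frames[k] = img
    return ImageSequence(frames=frames.astype(np.float32), spacing=grid.spacing, dt=dt, t0=t0)


# -- default study phantom -------------------------------------------------

DEFAULT_TAG_SPACING = 7.0  # mm between tag crests


def default_annulus_model(
    grid_size: int = 128,
    spacing: float = 1.0,
    r_inner: float = 25.0,
    r_outer: float = 45.0,
    lam_end: float = -150.0,
    phi_end: float = 0.15,
    systole_duration: float = 0.4,
) -> PhantomModel:
    """Contracting-and-twisting annulus centred on the default grid.

    lam_end in mm^2 and phi_end in rad are the end-systolic values of the
    half-cosine ramps; systole_duration (s) spans the rendered sequence.
    """
    center = ((grid_size - 1) / 2 * spacing, (grid_size - 1) / 2 * spacing)
    return PhantomModel(
        model_kind="incompressible_annulus",
        parameters={
            "lam_end": lam_end,
            "phi_end": phi_end,
            "r_inner": r_inner,
            "r_outer": r_outer,
        },
        center=center,
        time_span=(0.0, systole_duration),
    )


def default_tag_specs(noise_sd: float = 0.0, fading_rate: float = 0.0) -> tuple[TagSpec, TagSpec]:
    """Two orthogonal tag patterns (horizontal-running and vertical-running)."""
    k = 2.0 * np.pi / DEFAULT_TAG_SPACING
    return (
        TagSpec(wave_vector=(k, 0.0), noise_sd=noise_sd, fading_rate=fading_rate),
        TagSpec(wave_vector=(0.0, k), noise_sd=noise_sd, fading_rate=fading_rate),
    )


def analytic_velocity_fields(model: PhantomModel, grid: ImageGrid, n_frames: int):
    """Ground-truth velocity-gradient fields, one per frame interval.

    Each field holds the exact Eulerian (v, L) sampled at pixel centers at
    the interval mid-time, packaged like the optic-flow output so the
    deformation integrator can be driven by exact input (oracle tests,
    Δt-convergence studies).
    """
    from .motion import VelocityGradientField

    t0, t_end = model.time_span
    dt = (t_end - t0) / (n_frames - 1)
    pos = grid.positions()
    fields = []
    for k in range(n_frames - 1):
        t_mid = t0 + (k + 0.5) * dt
        v, L = analytic_velocity_gradient(model, pos, t_mid)
        ok = np.all(np.isfinite(v), axis=-1) & np.all(np.isfinite(L), axis=(-1, -2))
        fields.append(
            VelocityGradientField(
                v=v, L=L,
                selected_scale=np.zeros(grid.shape),
                condition_number=np.ones(grid.shape),
                validity=ok,
                time=t_mid,
                spacing=grid.spacing,
            )
        )
    return fields


def annulus_mask(model: PhantomModel, grid: ImageGrid) -> np.ndarray:
    """Reference-frame ROI mask: pixels with r_inner <= |X - center| <= r_outer."""
    pos = grid.positions()
    R = np.linalg.norm(pos - np.asarray(model.center), axis=-1)
    return (R >= model.parameters["r_inner"]) & (R <= model.parameters["r_outer"])


def make_default_dataset(
    noise_sd: float = 0.0,
    n_frames: int = 21,
    grid_size: int = 128,
    spacing: float = 1.0,
    fading_rate: float = 0.0,
    seed: int | None = 0,
    **model_kwargs,
):
    """Build the default study dataset.

    Returns (model, (seq_a, seq_b), mask, grid): two orthogonally tagged
    sequences of the contracting/twisting annulus, plus the reference ROI.
    """
    model = default_annulus_model(grid_size=grid_size, spacing=spacing, **model_kwargs)
    grid = ImageGrid(shape=(grid_size, grid_size), spacing=spacing)
    tag_a, tag_b = default_tag_specs(noise_sd=noise_sd, fading_rate=fading_rate)
    rng = np.random.default_rng(seed)
    seq_a = render_tagged_sequence(model, tag_a, grid, n_frames, rng=rng)
    seq_b = render_tagged_sequence(model, tag_b, grid, n_frames, rng=rng)
    mask = annulus_mask(model, grid)
    return model, (seq_a, seq_b), mask, grid
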