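"""Dense velocity-gradient estimation by first-order multiscale optic flow.

With two independent harmonic-phase images phi_1, phi_2 (one per tag
direction), the optic-flow constraint equation phi_t + v . grad(phi) = 0
holds for each phase because harmonic phase is a material invariant.  A
first-order local model of the velocity field around a pixel x0,

    v(x) = v0 + L (x - x0),

inserted into the constraint and its two first spatial derivatives gives,
per phase, three linear equations in the six unknowns
(v0_1, v0_2, L11, L12, L21, L22); the two phases together close the 6x6
system with no regularization prior.  Written out, the derivative equation
for direction beta reads

    d_beta phi_t + sum_alpha d_alpha phi * L_{alpha beta}
                 + sum_gamma v_gamma * d_gamma d_beta phi = 0.

All image derivatives are Gaussian-scale-space derivatives at a trial scale;
the scale is selected per pixel (independently, in parallel) as the one
minimizing the 2-norm condition number of the 6x6 matrix, ties broken
toward the smaller scale.  Temporal phase differences are taken between
consecutive complex frames as arg(z_{k+1} conj(z_k)), which is wrap-free
for sub-half-wavelength inter-frame motion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .harp import PhaseImageSequence, _gaussian

COND_LIMIT = 1e6  # pixels whose selected condition number exceeds this are invalidated

# Condition numbers within this relative tolerance are treated as tied, and
# ties resolve to the smaller scale.  Locality is preferred whenever the
# conditioning argument cannot distinguish scales: a marginally lower
# condition number at a coarse scale does not justify the extra bias the
# coarse first-order local flow model incurs where the velocity field is
# spatially nonlinear.
TIE_RTOL = 0.1


@dataclasses.dataclass
class ScaleSweep:
    """Ordered spatial scales (mm) to try, plus the temporal window (frames)."""

    scales: np.ndarray
    temporal_scale: int = 1

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.size < 3:
            raise ValueError("need at least 3 scales")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")


def default_scale_sweep(tag_spacing: float, n_scales: int = 8) -> ScaleSweep:
    """8 log-spaced scales spanning [0.5, 3] tag spacings."""
    return ScaleSweep(scales=np.geomspace(0.5 * tag_spacing, 3.0 * tag_spacing, n_scales))


@dataclasses.dataclass
class VelocityGradientField:
    """Velocity and velocity-gradient tensor for one frame pair.

    v : (ny, nx, 2) mm/s; L : (ny, nx, 2, 2) 1/s (L[a, b] = dv_a/dx_b);
    selected_scale (mm), condition_number and validity per pixel.  `time` is
    the mid-time of the frame pair, where L is reported; L is treated as
    piecewise constant over its frame interval.
    """

    v: np.ndarray
    L: np.ndarray
    selected_scale: np.ndarray
    condition_number: np.ndarray
    validity: np.ndarray
    time: float
    spacing: float

    def sample(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bilinear interpolation of (v, L) at physical positions (..., 2) mm.

        Samples touching invalid or out-of-grid pixels are flagged invalid;
        values are never extrapolated.
        """
        pos = np.asarray(positions, dtype=float)
        batch = pos.shape[:-1]
        coords = np.stack(
            [pos[..., 1].ravel() / self.spacing, pos[..., 0].ravel() / self.spacing]
        )  # (row, col)
        chans = np.concatenate(
            [self.v.reshape(self.v.shape[:2] + (2,)), self.L.reshape(self.L.shape[:2] + (4,))],
            axis=-1,
        )
        filled = np.where(self.validity[..., None], chans, 0.0)
        out = np.empty(coords.shape[1:] + (6,))
        for c in range(6):
            out[:, c] = ndimage.map_coordinates(
                filled[..., c], coords, order=1, mode="constant", cval=0.0
            )
        weight = ndimage.map_coordinates(
            self.validity.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        valid = weight > 1.0 - 1e-9
        v = out[:, :2].reshape(batch + (2,))
        L = out[:, 2:].reshape(batch + (2, 2))
        v[~valid.reshape(batch)] = np.nan
        L[~valid.reshape(batch)] = np.nan
        return v, L, valid.reshape(batch)


def _phase_derivatives(pseq: PhaseImageSequence, frame: int, scale: float):
    """Scale-space phase derivatives at the mid-time of pair (frame, frame+1).

    Returns grad (ny,nx,2), hessian (ny,nx,2,2) [H[g,b] = d_g d_b phi],
    grad_t (ny,nx,2), phi_t (ny,nx), valid (ny,nx).  Units rad/mm, rad/mm^2,
    rad/(mm s), rad/s.
    """
    h = pseq.spacing
    sigma = scale / h
    z0 = pseq.complex_frames[frame]
    z1 = pseq.complex_frames[frame + 1]

    def complex_grad(z):
        """Phase gradient of a slowly varying (demodulated) complex image."""
        zs = _gaussian(z, sigma)
        dzx = _gaussian(z, sigma, order=(0, 1)) / h
        dzy = _gaussian(z, sigma, order=(1, 0)) / h
        mag2 = zs.real**2 + zs.imag**2
        ok = mag2 > (0.05 * np.sqrt(np.median(mag2))) ** 2
        denom = np.where(ok, mag2, 1.0)
        gx = (zs.real * dzx.imag - zs.imag * dzx.real) / denom
        gy = (zs.real * dzy.imag - zs.imag * dzy.real) / denom
        return np.stack([gx, gy], axis=-1), ok

    # Demodulate by the carrier before any smoothing: the residual phase
    # varies slowly, so large-scale Gaussian filtering does not crush the
    # harmonic relative to leaked out-of-band energy.
    carrier = np.asarray(pseq.carrier, dtype=float)
    ny, nx = z0.shape
    xg = np.arange(nx)[None, :] * h
    yg = np.arange(ny)[:, None] * h
    demod = np.exp(-1j * (carrier[0] * xg + carrier[1] * yg))
    g0, ok0 = complex_grad(z0 * demod)
    g1, ok1 = complex_grad(z1 * demod)
    grad = carrier + 0.5 * (g0 + g1)

    # Temporal derivative from the inter-frame complex product (wrap-free).
    w = z1 * np.conj(z0)
    gw, okw = complex_grad(w)
    ws = _gaussian(w, sigma)
    phi_t = np.angle(ws) / pseq.dt
    grad_t = gw / pseq.dt

    # Hessian: Gaussian derivative of the (smooth, unwrapped) gradient maps.
    valid = ok0 & ok1 & okw
    if pseq.validity is not None:
        valid &= pseq.validity[frame] & pseq.validity[frame + 1]
    gfill = np.where(valid[..., None], grad, 0.0)
    hess = np.empty(grad.shape[:2] + (2, 2))
    for b in range(2):  # derivative direction beta
        order = (0, 1) if b == 0 else (1, 0)
        for g in range(2):  # component gamma of grad
            hess[..., g, b] = _gaussian(gfill[..., g], sigma, order=order) / h
    weight = _gaussian(valid.astype(float), sigma)
    valid &= weight > 0.95
    return grad, hess, grad_t, phi_t, valid


def _assemble_pair(
    phases: tuple[PhaseImageSequence, PhaseImageSequence],
    frame: int,
    scale: float,
    flat_idx: np.ndarray,
):
    """Assemble the 6x6 OFCE systems at the given flat pixel indices.

    Returns A (N, 6, 6), b (N, 6), valid (N,).
    """
    n = flat_idx.size
    A = np.zeros((n, 6, 6))
    rhs = np.zeros((n, 6))
    valid = np.ones(n, dtype=bool)
    for q, pseq in enumerate(phases):
        grad, hess, grad_t, phi_t, ok = _phase_derivatives(pseq, frame, scale)
        shp = grad.shape[:2]
        g = grad.reshape(-1, 2)[flat_idx]
        H = hess.reshape(-1, 2, 2)[flat_idx]
        gt = grad_t.reshape(-1, 2)[flat_idx]
        pt = phi_t.reshape(-1)[flat_idx]
        valid &= ok.reshape(-1)[flat_idx]
        r = 3 * q
        # constraint row: grad(phi) . v0 = -phi_t
        A[:, r, 0] = g[:, 0]
        A[:, r, 1] = g[:, 1]
        rhs[:, r] = -pt
        for b_dir in range(2):  # differentiated constraint, direction beta
            row = r + 1 + b_dir
            A[:, row, 0] = H[:, 0, b_dir]
            A[:, row, 1] = H[:, 1, b_dir]
            # L coefficients: unknown order (L11, L12, L21, L22) at columns 2..5;
            # L_{alpha beta} pairs with d_alpha phi.
            A[:, row, 2 + 0 * 2 + b_dir] = g[:, 0]  # alpha = 1
            A[:, row, 2 + 1 * 2 + b_dir] = g[:, 1]  # alpha = 2
            rhs[:, row] = -gt[:, b_dir]
    return A, rhs, valid


def build_ofce_system(
    phases: tuple[PhaseImageSequence, PhaseImageSequence],
    pixel: tuple[int, int],
    frame: int,
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """The 6x6 optic-flow system for one pixel, frame pair and scale.

    Unknown ordering: (v1, v2, L11, L12, L21, L22).  Raises if the phase
    images are invalid within the filter support at that pixel.
    """
    ny, nx = phases[0].shape
    row, col = pixel
    flat = np.array([row * nx + col])
    A, b, valid = _assemble_pair(phases, frame, scale, flat)
    if not valid[0]:
        raise ValueError(f"system unbuildable at pixel {pixel}: invalid phase data")
    return A[0], b[0]


def select_scale(systems: list[tuple[float, np.ndarray, np.ndarray]]):
    """Pick the best-conditioned system from a per-scale family.

    Parameters: list of (scale, A, b), ordered by increasing scale.
    Returns (scale, solution, condition_number) for the system minimizing
    the 2-norm condition number; ties — condition numbers within TIE_RTOL
    relative tolerance of the minimum — go to the smaller scale.
    Raises if every system is singular or non-finite.
    """
    entries = []
    for scale, A, b in systems:
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
            continue
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] <= 0:
            continue
        entries.append((scale, A, b, s[0] / s[-1]))
    if not entries:
        raise ValueError("all systems singular or unbuildable")
    c_min = min(e[3] for e in entries)
    for scale, A, b, cond in entries:  # ordered by increasing scale
        if cond <= c_min * (1.0 + TIE_RTOL):
            return scale, np.linalg.solve(A, b), cond
    raise AssertionError("unreachable")


def estimate_velocity_gradient(
    phases: tuple[PhaseImageSequence, PhaseImageSequence],
    sweep: ScaleSweep,
    mask: np.ndarray,
) -> list[VelocityGradientField]:
    """Estimate (v, L) on the mask for every consecutive frame pair.

    Returns T - 1 fields.  Per pixel, the scale minimizing the 2-norm
    condition number of the OFCE system is selected independently; pixels
    with no solvable system, non-finite solutions or condition number above
    1e6 are invalidated.
    """
    pa, pb = phases
    if pa.n_frames != pb.n_frames:
        raise ValueError("phase sequences must have equal length")
    if pa.n_frames < 2:
        raise ValueError("need at least two frames")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    ny, nx = pa.shape
    flat_idx = np.flatnonzero(mask.ravel())
    n = flat_idx.size
    S = sweep.scales.size
    fields = []
    for frame in range(pa.n_frames - 1):
        A_all = np.empty((S, n, 6, 6))
        b_all = np.empty((S, n, 6))
        conds = np.full((S, n), np.inf)
        for si, scale in enumerate(sweep.scales):
            A, b, ok = _assemble_pair(phases, frame, scale, flat_idx)
            A_all[si], b_all[si] = A, b
            finite = ok & np.all(np.isfinite(A.reshape(n, -1)), axis=1)
            if finite.any():
                sv = np.linalg.svd(A[finite], compute_uv=False)
                with np.errstate(divide="ignore", invalid="ignore"):
                    c = sv[:, 0] / sv[:, -1]
                c[~np.isfinite(c)] = np.inf
                conds[si, finite] = c
        c_min = conds.min(axis=0)
        tied = conds <= c_min[None, :] * (1.0 + TIE_RTOL)
        sel = np.argmax(tied, axis=0)  # first (smallest) scale within the tie band
        cond_sel = conds[sel, np.arange(n)]
        ok = np.isfinite(cond_sel) & (cond_sel <= COND_LIMIT)
        sol = np.full((n, 6), np.nan)
        if ok.any():
            A_sel = A_all[sel[ok], np.arange(n)[ok]]
            b_sel = b_all[sel[ok], np.arange(n)[ok]]
            sol[ok] = np.linalg.solve(A_sel, b_sel[..., None])[..., 0]
        ok &= np.all(np.isfinite(sol), axis=1)

        v = np.full((ny, nx, 2), np.nan)
        L = np.full((ny, nx, 2, 2), np.nan)
        scale_img = np.full((ny, nx), np.nan)
        cond_img = np.full((ny, nx), np.nan)
        validity = np.zeros((ny, nx), dtype=bool)
        rows, cols = np.unravel_index(flat_idx, (ny, nx))
        v[rows, cols] = sol[:, :2]
        L[rows, cols] = sol[:, 2:].reshape(n, 2, 2)
        scale_img[rows, cols] = sweep.scales[sel]
        cond_img[rows, cols] = cond_sel
        validity[rows, cols] = ok
        v[~validity] = np.nan
        L[~validity] = np.nan
        fields.append(
            VelocityGradientField(
                v=v,
                L=L,
                selected_scale=scale_img,
                condition_number=cond_img,
                validity=validity,
                time=pa.t0 + (frame + 0.5) * pa.dt,
                spacing=pa.spacing,
            )
        )
    return fields
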