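"""Lagrangian strain from the deformation gradient, under general metrics.

The Lagrangian strain tensor E = 1/2 (f*^T o f* - id) vanishes identically
for isometries, so it measures genuinely nonrigid deformation.  Its mixed
components under a reference-chart metric g_ij (dual g^ij) and a
deformed-chart metric h_ab are

    E_i^j = 1/2 (g^{lj} F_l^a h_ab F_i^b - delta_i^j).

With a single Cartesian chart for both configurations all metrics are the
identity and this reduces to the familiar E = 1/2 (F^T F - I).  The
carry-along mode instead induces h from g by the deformation itself
(h = F^{-T} g F^{-1}), which nullifies E identically — a built-in
correctness oracle exercised by the tests.

Scalar strains are projections onto local unit directions: circumferential
and radial (polar frame centred at the ROI midpoint) give E_cc, E_rr and the
shear E_cr; the eigensystem of E gives the principal strains E_min <= E_max
(in the eigenframe the shear projection vanishes).  Displayed scalar fields
are regularized by masked Gaussian convolution.

Matrix layout: E[j, i] holds E_i^j (row = upper index); with identity
metrics this matrix is symmetric and acts on vectors as (E w)^j = E[j, i] w^i.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class MetricSpec:
    """Metrics on the reference (g) and deformed (h) charts.

    mode 'identity' uses Euclidean metrics on both charts; 'carry_along'
    induces h from g by the deformation (nullifying E); 'custom' takes both
    as given.  g and h are 2x2 symmetric positive-definite matrices (or
    broadcastable stacks thereof).
    """

    mode: str = "identity"
    g: np.ndarray | None = None
    h: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "custom", "carry_along"):
            raise ValueError(f"unknown metric mode {self.mode!r}")
        if self.mode == "identity":
            self.g = np.eye(2)
            self.h = np.eye(2)
        if self.g is None:
            self.g = np.eye(2)
        self.g = np.asarray(self.g, dtype=float)
        _check_spd(self.g, "g")
        if self.mode == "custom":
            if self.h is None:
                raise ValueError("custom mode requires h")
            self.h = np.asarray(self.h, dtype=float)
            _check_spd(self.h, "h")


def _check_spd(m: np.ndarray, name: str) -> None:
    if m.shape[-2:] != (2, 2):
        raise ValueError(f"{name} must be 2x2")
    if not np.allclose(m, np.swapaxes(m, -1, -2), atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    tr = m[..., 0, 0] + m[..., 1, 1]
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    if np.any(det <= 0) or np.any(tr <= 0):
        raise ValueError(f"{name} must be positive definite")


@dataclasses.dataclass
class DirectionFrame:
    """Radial / circumferential unit vectors per sample point.

    e_r points outward from the center; e_c is e_r rotated by +90 degrees
    (counterclockwise).  Samples at the center are flagged undefined.
    """

    center: np.ndarray
    e_r: np.ndarray
    e_c: np.ndarray
    defined: np.ndarray


SCALAR_NAMES = ("E_cc", "E_rr", "E_cr", "E_min", "E_max")


@dataclasses.dataclass
class StrainField:
    """Mixed-component strain tensors plus derived scalar fields.

    E : (..., 2, 2); scalars : dict name -> (...) arrays for E_cc, E_rr,
    E_cr, E_min, E_max; principal_directions : (..., 2, 2) with
    [..., :, 0] the E_min direction and [..., :, 1] the E_max direction.
    """

    E: np.ndarray
    scalars: dict
    principal_directions: np.ndarray
    valid: np.ndarray


def lagrangian_strain(F: np.ndarray, metrics: MetricSpec | None = None) -> np.ndarray:
    """Mixed-component Lagrangian strain E_i^j = 1/2 (g^{lj} F_l^a h_ab F_i^b - d_i^j).

    F is the deformation gradient (rows = deformed components, columns =
    reference components), batched over leading axes.  In carry_along mode
    h is induced from g by F itself, which returns (numerically) zero.
    """
    F = np.asarray(F, dtype=float)
    if metrics is None:
        metrics = MetricSpec()
    g = metrics.g
    if metrics.mode == "carry_along":
        Finv = np.linalg.inv(F)
        h = np.swapaxes(Finv, -1, -2) @ g @ Finv
    else:
        h = metrics.h
    g_dual = np.linalg.inv(g)
    C = np.swapaxes(F, -1, -2) @ h @ F  # C_ij = F_i^a h_ab F_j^b
    eye = np.eye(2)
    return 0.5 * (g_dual @ C - eye)


def project_strain(E: np.ndarray, u: np.ndarray, w: np.ndarray,
                   g: np.ndarray | None = None) -> np.ndarray:
    """Scalar strain (u, E(w)) = g_jk u^k E_i^j w^i for unit vectors u, w.

    Symmetric in (u, w) when E derives from consistent metrics.  Batched
    over leading axes of E/u/w.
    """
    E = np.asarray(E, dtype=float)
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if g is None:
        g = np.eye(2)
    g = np.asarray(g, dtype=float)
    norm_u = np.einsum("...jk,...k,...j->...", g, u, u)
    norm_w = np.einsum("...jk,...k,...j->...", g, w, w)
    if not (np.allclose(norm_u, 1.0, atol=1e-8) and np.allclose(norm_w, 1.0, atol=1e-8)):
        raise ValueError("u and w must be unit vectors in the metric g")
    Ew = np.einsum("...ji,...i->...j", E, w)
    return np.einsum("...jk,...k,...j->...", g, u, Ew)


def polar_frame(points: np.ndarray, center: np.ndarray) -> DirectionFrame:
    """Radial/circumferential frame of the polar system centred at `center`."""
    points = np.asarray(points, dtype=float)
    center = np.asarray(center, dtype=float)
    rel = points - center
    r = np.linalg.norm(rel, axis=-1)
    defined = r > 0
    safe_r = np.where(defined, r, 1.0)
    e_r = rel / safe_r[..., None]
    e_c = np.stack([-e_r[..., 1], e_r[..., 0]], axis=-1)  # +90 deg rotation
    e_r = np.where(defined[..., None], e_r, np.nan)
    e_c = np.where(defined[..., None], e_c, np.nan)
    return DirectionFrame(center=center, e_r=e_r, e_c=e_c, defined=defined)


def strain_eigensystem(E: np.ndarray, asym_tol: float = 1e-8):
    """Principal strains and directions of a symmetric (identity-metric) E.

    Returns (E_min, E_max, directions) with directions[..., :, 0] the E_min
    eigenvector and [..., :, 1] the E_max eigenvector, each normalized and
    sign-fixed so its first nonzero component is positive.  Raises if E is
    asymmetric beyond `asym_tol` (which indicates a non-identity metric was
    used upstream).
    """
    E = np.asarray(E, dtype=float)
    asym = np.abs(E - np.swapaxes(E, -1, -2)).max()
    if asym > asym_tol:
        raise ValueError(
            f"strain matrix asymmetric by {asym:.2e}: eigensystem requires identity metrics"
        )
    Es = 0.5 * (E + np.swapaxes(E, -1, -2))
    w, v = np.linalg.eigh(Es)  # ascending eigenvalues
    # deterministic eigenvector sign: first component with |.| > tol positive
    first = v[..., 0, :]
    second = v[..., 1, :]
    sign = np.where(np.abs(first) > 1e-12, np.sign(first), np.sign(second))
    sign = np.where(sign == 0, 1.0, sign)
    v = v * sign[..., None, :]
    return w[..., 0], w[..., 1], v


def regularize_scalar_field(field: np.ndarray, sigma: float,
                            valid: np.ndarray | None = None) -> np.ndarray:
    """Masked, normalized Gaussian smoothing of a scalar image (sigma in pixels).

    Invalid pixels carry zero weight; pixels with (numerically) no valid
    support stay NaN.  sigma = 0 returns the input unchanged.
    """
    field = np.asarray(field, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if valid is None:
        valid = np.isfinite(field)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(field)
    if not valid.any():
        raise ValueError("cannot regularize an all-invalid field")
    if sigma == 0:
        out = np.where(valid, field, np.nan)
        return out
    weight = valid.astype(float)
    num = ndimage.gaussian_filter(np.where(valid, field, 0.0), sigma, mode="reflect")
    den = ndimage.gaussian_filter(weight, sigma, mode="reflect")
    out = np.full_like(field, np.nan)
    supported = valid & (den > 1e-12)
    out[supported] = num[supported] / den[supported]
    return out


def strain_scalars(
    E: np.ndarray,
    frame: DirectionFrame,
    valid: np.ndarray | None = None,
) -> StrainField:
    """Project strain tensors onto the polar frame and the eigensystem.

    E_cr uses the convention (e_c, E(e_r)); by symmetry of E under identity
    metrics this equals (e_r, E(e_c)).
    """
    E = np.asarray(E, dtype=float)
    batch = E.shape[:-2]
    if valid is None:
        valid = np.ones(batch, dtype=bool)
    valid = np.asarray(valid, dtype=bool) & frame.defined & np.all(
        np.isfinite(E), axis=(-1, -2)
    )
    eye2 = np.eye(2)
    E_safe = np.where(valid[..., None, None], E, eye2 * 0.0)
    e_r = np.where(frame.defined[..., None], frame.e_r, np.array([1.0, 0.0]))
    e_c = np.where(frame.defined[..., None], frame.e_c, np.array([0.0, 1.0]))
    scalars = {
        "E_cc": project_strain(E_safe, e_c, e_c),
        "E_rr": project_strain(E_safe, e_r, e_r),
        "E_cr": project_strain(E_safe, e_c, e_r),
    }
    emin, emax, dirs = strain_eigensystem(E_safe)
    scalars["E_min"] = emin
    scalars["E_max"] = emax
    for name in scalars:
        scalars[name] = np.where(valid, scalars[name], np.nan)
    dirs = np.where(valid[..., None, None], dirs, np.nan)
    return StrainField(E=np.where(valid[..., None, None], E, np.nan),
                       scalars=scalars, principal_directions=dirs, valid=valid)
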