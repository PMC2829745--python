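"""Model/Results front end tying the pipeline stages together.

`TagStrainModel` is constructed from two orthogonally tagged cine sequences
of the same slice plus a myocardial ROI mask; `.fit()` runs harmonic-phase
extraction, multiscale optic flow, material-point tracking, deformation
integration and strain projection, and returns a `StrainResults` object
carrying the dense fields, ROI statistics over time and a `summary()` table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from . import deformation as dfm
from . import harp, motion, report
from . import strain as strain_mod
from .io import ImageSequence, check_paired_sequences


@dataclasses.dataclass
class TagStrainModel:
    """Myocardial deformation/strain model for a pair of tagged sequences.

    Parameters
    ----------
    seq_a, seq_b : ImageSequence
        Co-registered cine sequences with linearly independent tag
        directions (e.g. vertical and horizontal SPAMM).
    mask : (ny, nx) bool
        Myocardial ROI on the reference (frame-0, end-diastolic) grid.
    center : (2,) mm, optional
        Center of the polar strain frame; defaults to the ROI centroid.
    sweep : ScaleSweep, optional
        Spatial scales for the optic-flow scale selection; defaults to 8
        log-spaced scales in [0.5, 3] tag spacings (from the detected
        carrier).
    method : {'linear_product', 'exp_product'}
        Multiplicative-integral discretization for dF/dt = L F.
    sigma : float
        Gaussian regularization scale for the displayed scalar strain
        fields, in pixels.
    eulerian_sampling : bool
        Sample L at fixed reference pixels instead of tracked material
        positions (comparison mode).
    mask_dilation_px : int
        Dilation of the ROI within which motion is estimated, so that
        material points can be tracked slightly outside the reference ROI.
    """

    seq_a: ImageSequence
    seq_b: ImageSequence
    mask: np.ndarray
    center: np.ndarray | None = None
    sweep: motion.ScaleSweep | None = None
    method: str = "linear_product"
    sigma: float = 1.0
    eulerian_sampling: bool = False
    mask_dilation_px: int = 8

    def __post_init__(self) -> None:
        check_paired_sequences(self.seq_a, self.seq_b)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.seq_a.shape:
            raise ValueError("mask shape does not match the image grid")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @classmethod
    def from_phantom(cls, noise_sd: float = 0.0, n_frames: int = 21, seed: int = 0,
                     **kwargs) -> "TagStrainModel":
        """Build the model on the default contracting/twisting annulus phantom."""
        from .phantom import make_default_dataset

        model_kwargs = {
            k: kwargs.pop(k)
            for k in ("grid_size", "spacing", "r_inner", "r_outer", "lam_end",
                      "phi_end", "systole_duration", "fading_rate")
            if k in kwargs
        }
        phantom_model, (seq_a, seq_b), mask, _ = make_default_dataset(
            noise_sd=noise_sd, n_frames=n_frames, seed=seed, **model_kwargs
        )
        obj = cls(seq_a=seq_a, seq_b=seq_b, mask=mask, **kwargs)
        obj.phantom = phantom_model
        return obj

    def fit(self) -> "StrainResults":
        seq_a, seq_b = self.seq_a, self.seq_b
        carrier_a = harp.detect_carrier(seq_a)
        carrier_b = harp.detect_carrier(seq_b)
        cos_angle = abs(
            carrier_a @ carrier_b / (np.linalg.norm(carrier_a) * np.linalg.norm(carrier_b))
        )
        if cos_angle > 0.9:
            raise ValueError("tag directions are not linearly independent")
        pa = harp.bandpass_harmonic(seq_a, carrier_a)
        pb = harp.bandpass_harmonic(seq_b, carrier_b)

        tag_spacing = 2.0 * np.pi / min(np.linalg.norm(carrier_a), np.linalg.norm(carrier_b))
        sweep = self.sweep or motion.default_scale_sweep(tag_spacing)

        analysis_mask = ndimage.binary_dilation(self.mask, iterations=self.mask_dilation_px)
        guard = harp.border_guard(self.mask.shape, sweep.scales[0] / seq_a.spacing)
        analysis_mask &= guard
        fields = motion.estimate_velocity_gradient((pa, pb), sweep, analysis_mask)

        grid = dfm.TimeGrid.uniform(seq_a.t0, seq_a.dt, seq_a.n_frames - 1)
        rows, cols = np.nonzero(self.mask)
        seeds = np.stack([cols * seq_a.spacing, rows * seq_a.spacing], axis=-1)
        traj = dfm.track_material_points(fields, seeds, grid)
        deform = dfm.integrate_deformation(
            fields, traj, grid, method=self.method,
            eulerian_sampling=self.eulerian_sampling,
        )

        center = self.center
        if center is None:
            center = seeds.mean(axis=0)  # midpoint of the region of interest
        frame = strain_mod.polar_frame(seeds, center)
        T = seq_a.n_frames
        ny, nx = self.mask.shape
        raw = {name: np.full((T, ny, nx), np.nan) for name in strain_mod.SCALAR_NAMES}
        regularized = {name: np.full((T, ny, nx), np.nan) for name in strain_mod.SCALAR_NAMES}
        E_stack = np.full((T, len(seeds), 2, 2), np.nan)
        for k in range(T):
            E_k = strain_mod.lagrangian_strain(deform.F[k])
            sf = strain_mod.strain_scalars(E_k, frame, valid=deform.valid[k])
            E_stack[k] = sf.E
            for name in strain_mod.SCALAR_NAMES:
                img = np.full((ny, nx), np.nan)
                img[rows, cols] = sf.scalars[name]
                raw[name][k] = img
                regularized[name][k] = strain_mod.regularize_scalar_field(
                    img, self.sigma
                )
        summaries = report.summarize(regularized, self.mask)
        raw_summaries = report.summarize(raw, self.mask)
        return StrainResults(
            model=self,
            carriers=(carrier_a, carrier_b),
            phases=(pa, pb),
            sweep=sweep,
            velocity_fields=fields,
            trajectories=traj,
            deformation=deform,
            strain_tensors=E_stack,
            polar=frame,
            center=np.asarray(center),
            scalar_fields=regularized,
            scalar_fields_raw=raw,
            summaries=summaries,
            summaries_raw=raw_summaries,
        )


@dataclasses.dataclass
class StrainResults:
    """Fitted deformation/strain fields with ROI statistics.

    scalar_fields[name] is a (T, ny, nx) stack on the reference grid
    (NaN outside the ROI / invalid samples), Gaussian-regularized at the
    model's sigma; scalar_fields_raw holds the unregularized versions.
    strain_tensors is (T, n_seeds, 2, 2) in seed order (mask row-major).
    """

    model: TagStrainModel
    carriers: tuple
    phases: tuple
    sweep: motion.ScaleSweep
    velocity_fields: list
    trajectories: dfm.MaterialTrajectory
    deformation: dfm.DeformationField
    strain_tensors: np.ndarray
    polar: strain_mod.DirectionFrame
    center: np.ndarray
    scalar_fields: dict
    scalar_fields_raw: dict
    summaries: pd.DataFrame
    summaries_raw: pd.DataFrame

    @property
    def peak_frame(self) -> int:
        """Frame at which the ROI-mean maximal principal strain peaks."""
        return report.peak_frame(self.summaries, "E_max")

    def strain_at(self, frame: int, regularized: bool = True) -> dict:
        src = self.scalar_fields if regularized else self.scalar_fields_raw
        return {name: src[name][frame] for name in strain_mod.SCALAR_NAMES}

    def strain_curves(self, path=None) -> pd.DataFrame:
        return report.strain_curves(self.summaries, path)

    def plot_curves(self, ax=None):
        return report.plot_curves(self.summaries, ax)

    def plot_strain_maps(self, frames=None, path=None):
        """Fig-2-style panel grid: one row per scalar, one column per frame."""
        import matplotlib.pyplot as plt

        if frames is None:
            T = self.model.seq_a.n_frames
            frames = sorted(set([0, T // 4, T // 2, 3 * T // 4, T - 1]))
        names = strain_mod.SCALAR_NAMES
        fig, axes = plt.subplots(len(names), len(frames),
                                 figsize=(2.2 * len(frames), 2.2 * len(names)),
                                 squeeze=False)
        vmax = 0.3
        for i, name in enumerate(names):
            for j, k in enumerate(frames):
                ax = axes[i][j]
                im = ax.imshow(self.scalar_fields[name][k], cmap="RdBu_r",
                               vmin=-vmax, vmax=vmax, origin="upper")
                ax.set_xticks([]), ax.set_yticks([])
                if j == 0:
                    ax.set_ylabel(name)
                if i == 0:
                    ax.set_title(f"frame {k}", fontsize=8)
        fig.colorbar(im, ax=axes[-1][-1], fraction=0.05)
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig

    def summary(self) -> str:
        """Text summary: run configuration and ROI strain at the peak frame."""
        pf = self.peak_frame
        at_peak = self.summaries[self.summaries["frame"] == pf]
        lines = [
            "Tagged-MRI deformation and strain analysis",
            "=" * 56,
            f"frames: {self.model.seq_a.n_frames}   "
            f"grid: {self.model.mask.shape[0]}x{self.model.mask.shape[1]} "
            f"@ {self.model.seq_a.spacing:g} mm   dt: {self.model.seq_a.dt:g} s",
            f"ROI pixels: {int(self.model.mask.sum())}   "
            f"polar center: ({self.center[0]:.1f}, {self.center[1]:.1f}) mm",
            f"carriers (rad/mm): ({self.carriers[0][0]:+.3f}, {self.carriers[0][1]:+.3f}), "
            f"({self.carriers[1][0]:+.3f}, {self.carriers[1][1]:+.3f})",
            f"integration: {self.deformation.method}   "
            f"scales: {self.sweep.scales[0]:.2f}-{self.sweep.scales[-1]:.2f} mm "
            f"({self.sweep.scales.size})   sigma: {self.model.sigma:g} px",
            "-" * 56,
            f"ROI strain at peak-|E_max| frame {pf} (mean +/- spatial std):",
        ]
        for _, row in at_peak.iterrows():
            lines.append(
                f"  {row['scalar']:<6s} {row['mean']:+0.3f} +/- {row['std']:0.3f}"
                f"   (n = {int(row['count'])})"
            )
        lines.append("=" * 56)
        return "\n".join(lines)
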