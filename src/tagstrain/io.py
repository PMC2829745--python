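"""Image-sequence container and standard-format I/O.

Coordinate convention (used by every module in this package): pixel centers,
0-based indices; the physical position of array element ``[row, col]`` is
``(x, y) = (col * spacing, row * spacing)`` in millimetres.  Sequences are
stored as ``(T, ny, nx)`` float arrays; multichannel field stacks as
``(T, ny, nx, C)``.

Supported containers are multi-page TIFF (one page per frame) and NIfTI
(x, y, t), each accompanied by a plain-text JSON sidecar carrying the pixel
spacing (mm), frame interval (s) and reference time t0 (s).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


@dataclasses.dataclass
class ImageSequence:
    """T frames of a scalar image on a regular 2D grid.

    Parameters
    ----------
    frames : ndarray, shape (T, ny, nx)
        Frame stack, float32/float64.
    spacing : float
        Isotropic pixel spacing in mm.
    dt : float
        Frame interval in s.
    t0 : float
        Acquisition time of frame 0 (the reference, end-diastolic, time) in s.
    """

    frames: np.ndarray
    spacing: float
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, ny, nx), got {self.frames.shape}")
        if self.spacing <= 0 or self.dt <= 0:
            raise ValueError("spacing and dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in s."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    def pixel_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinate grids in mm, each shaped (ny, nx)."""
        ny, nx = self.shape
        x = np.arange(nx) * self.spacing
        y = np.arange(ny) * self.spacing
        return np.meshgrid(x, y)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as multi-page TIFF (.tif/.tiff) or NIfTI (.nii/.nii.gz).

    Pixel values are stored as 32-bit float; spacing/dt/t0 go to a JSON
    sidecar next to the image file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(seq.frames, dtype=np.float32)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, data, photometric="minisblack")
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        # NIfTI axis order (x, y, t): transpose from (t, y, x).
        vol = np.transpose(data, (2, 1, 0))
        affine = np.diag([seq.spacing, seq.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol, affine), str(path))
    else:
        raise ValueError(f"unsupported container: {path.name}")
    meta = {"spacing_mm": seq.spacing, "dt_s": seq.dt, "t0_s": seq.t0}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_sequence(path: str | Path) -> ImageSequence:
    """Read a sequence written by :func:`write_sequence`."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 2:
            vol = vol[..., None]
        data = np.transpose(vol, (2, 1, 0))
    else:
        raise ValueError(f"unsupported container: {path.name}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    return ImageSequence(
        frames=np.asarray(data, dtype=np.float32),
        spacing=float(meta["spacing_mm"]),
        dt=float(meta["dt_s"]),
        t0=float(meta.get("t0_s", 0.0)),
    )


def write_field_stack(fields: np.ndarray, seq_like: ImageSequence, path: str | Path,
                      channels: list[str]) -> None:
    """Write a (T, ny, nx, C) multichannel field stack.

    The channel names are recorded in the sidecar so downstream stages (and
    humans) can recover the layout.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = np.asarray(fields, dtype=np.float32)
    if fields.ndim != 4 or fields.shape[-1] != len(channels):
        raise ValueError("fields must be (T, ny, nx, C) matching channel names")
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, fields, photometric="minisblack")
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.transpose(fields, (2, 1, 0, 3))
        affine = np.diag([seq_like.spacing, seq_like.spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(vol, affine), str(path))
    else:
        raise ValueError(f"unsupported container: {path.name}")
    meta = {
        "spacing_mm": seq_like.spacing,
        "dt_s": seq_like.dt,
        "t0_s": seq_like.t0,
        "channels": channels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_field_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multichannel stack; returns (fields (T,ny,nx,C), metadata dict)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        fields = tifffile.imread(path)
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        fields = np.transpose(vol, (2, 1, 0, 3))
    else:
        raise ValueError(f"unsupported container: {path.name}")
    meta = json.loads(_sidecar_path(path).read_text())
    return np.asarray(fields), meta


def read_mask(path: str | Path) -> np.ndarray:
    """Read an ROI mask image (any supported container); nonzero = inside."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim == 3 and arr.shape[-1] == 1:
            arr = arr[..., 0]
        arr = arr.T
    else:
        raise ValueError(f"unsupported container: {path.name}")
    if arr.ndim != 2:
        raise ValueError(f"mask must be a single 2D image, got shape {arr.shape}")
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, mask.astype(np.uint8))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.astype(np.uint8).T, np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported container: {path.name}")


def read_dicom_series(path: str | Path) -> ImageSequence:
    """Stub for clinical tagged-series ingestion.

    Ingesting vendor DICOM tagged cine series (frame sorting, trigger-time
    handling, per-vendor tag metadata) is out of scope; convert the series
    to multi-page TIFF or NIfTI plus a sidecar and use
    :func:`read_sequence`.
    """
    raise NotImplementedError(
        "DICOM ingestion is not implemented; convert the series to TIFF or "
        "NIfTI (see read_sequence) first"
    )


def check_paired_sequences(seq_a: ImageSequence, seq_b: ImageSequence) -> None:
    """Validate that two tag sequences can be analysed jointly."""
    if seq_a.n_frames != seq_b.n_frames:
        raise ValueError(
            f"frame-count mismatch between tag sequences: "
            f"{seq_a.n_frames} vs {seq_b.n_frames}"
        )
    if seq_a.shape != seq_b.shape:
        raise ValueError(f"shape mismatch: {seq_a.shape} vs {seq_b.shape}")
    if not np.isclose(seq_a.spacing, seq_b.spacing) or not np.isclose(seq_a.dt, seq_b.dt):
        raise ValueError("pixel spacing / frame interval mismatch between sequences")
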