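"""ROI statistics and temporal strain curves.

Spatial mean and sample (n - 1) standard deviation of each scalar strain
over the region of interest, per frame; long-format CSV export and an
optional mean +/- std plot per scalar.  The standard deviations capture
spatial variability across the ROI (plus noise and numerics), not
uncertainty of the mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def roi_stats(field: np.ndarray, mask: np.ndarray) -> tuple[float, float, int]:
    """(mean, sample std, count) over valid (finite) masked pixels."""
    field = np.asarray(field, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    values = field[mask & np.isfinite(field)]
    if values.size == 0:
        raise ValueError("empty intersection of mask and valid pixels")
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return mean, std, int(values.size)


def summarize(
    scalar_fields: dict[str, np.ndarray],
    mask: np.ndarray,
) -> pd.DataFrame:
    """ROI summary over time for a dict of (T, ...) scalar stacks.

    Returns a long-format table with columns (frame, scalar, mean, std, count),
    one row per frame per scalar.
    """
    rows = []
    for name, stack in scalar_fields.items():
        for k in range(stack.shape[0]):
            mean, std, count = roi_stats(stack[k], mask)
            rows.append({"frame": k, "scalar": name, "mean": mean, "std": std, "count": count})
    return pd.DataFrame(rows, columns=["frame", "scalar", "mean", "std", "count"])


def peak_frame(summaries: pd.DataFrame, scalar: str = "E_max") -> int:
    """Frame at which the spatial mean of the named scalar attains its maximum.

    Ties resolve to the earliest frame.
    """
    sub = summaries[summaries["scalar"] == scalar].sort_values("frame")
    if sub.empty:
        raise ValueError(f"no rows for scalar {scalar!r}")
    means = sub["mean"].to_numpy()
    frames = sub["frame"].to_numpy()
    return int(frames[int(np.argmax(means))])  # argmax returns first maximum


def strain_curves(summaries: pd.DataFrame, path=None) -> pd.DataFrame:
    """Write (or return) the long-format strain-curve table.

    Values round-trip through CSV at 17 significant digits (bit-exact for
    doubles).
    """
    table = summaries[["frame", "scalar", "mean", "std", "count"]]
    if path is not None:
        table.to_csv(path, index=False, float_format="%.17g")
    return table


def plot_curves(summaries: pd.DataFrame, ax=None):
    """Mean +/- std per scalar over frames (error bars = spatial ROI std)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for name, sub in summaries.groupby("scalar"):
        sub = sub.sort_values("frame")
        ax.errorbar(sub["frame"], sub["mean"], yerr=sub["std"], label=name, capsize=2)
    ax.set_xlabel("frame")
    ax.set_ylabel("strain")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.legend(fontsize=8)
    return ax
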