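"""Standard figures: BL/E scatter with cohort means, division-length histogram."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from sizehom.homeostasis import HomeostasisFit, compute_extension  # noqa: E402

__all__ = ["plot_ble", "plot_length_histogram"]


def plot_ble(records: pd.DataFrame, fit: HomeostasisFit, ax=None):
    """Birth length vs extension: raw points (light grey), cohort means with
    SD bars (dark grey) and the raw-data regression line (red)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = compute_extension(records)
    ax.scatter(
        df["birth_length_um"], df["extension_um"], s=6, c="lightgrey", label="cells"
    )
    coh = fit.cohorts
    ax.errorbar(
        coh["mean_birth_length_um"],
        coh["mean_extension_um"],
        yerr=coh["sd_extension_um"],
        fmt="o",
        color="dimgrey",
        label="cohort means (0.5 µm bins)",
    )
    xs = np.linspace(df["birth_length_um"].min(), df["birth_length_um"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-", label=f"slope {fit.slope:.2f}")
    ax.set_xlabel("birth length (µm)")
    ax.set_ylabel("extension (µm)")
    ax.set_title(f"{fit.strain}: {fit.mode_label}")
    ax.legend(fontsize=8)
    return ax


def plot_length_histogram(records: pd.DataFrame, bin_width: float = 1.0, ax=None):
    """Division-length frequency distribution with fixed-width (1 µm) bins."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    lengths = records["division_length_um"].to_numpy(dtype=float)
    lo = np.floor(lengths.min() / bin_width) * bin_width
    hi = np.ceil(lengths.max() / bin_width) * bin_width
    ax.hist(lengths, bins=np.arange(lo, hi + bin_width, bin_width), edgecolor="k")
    ax.set_xlabel("length at division (µm)")
    ax.set_ylabel("cells")
    return ax
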