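"""Birth-length vs extension (BL/E) size-homeostasis analysis.

For each completed cell cycle the extension is ``E = D - BL`` (division length
minus birth length). Regressing E on BL over a population diagnoses the size
control mode: a slope of -1 means deviations in birth size are fully corrected
within one cycle (sizer), 0 means a fixed increment is added regardless of
birth size (adder), and a positive slope (under exponential growth) means
large-born cells add more than small-born ones (timer). Wild-type fission
yeast sits near -0.7 to -0.8; homeostasis mutants show flattened slopes.

The regression is ordinary least squares on the raw records; 0.5-µm
birth-length cohorts are computed for display only (cohort means of a
noise-free sizer lie exactly on ``E = L_T - BL``). No errors-in-variables
correction is applied: measurement noise on BL enters E with the opposite
sign and biases the OLS slope toward -1, a caveat documented in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HomeostasisFit",
    "compute_extension",
    "cohort_by_birth_length",
    "fit_ble",
    "classify_control_mode",
    "DEFAULT_THRESHOLDS",
]

#: (sizer_max, impaired_max, timer_min) slope thresholds for classification.
DEFAULT_THRESHOLDS = (-0.6, -0.2, 0.2)

COHORT_COLUMNS = [
    "bin_start_um",
    "bin_end_um",
    "n",
    "mean_birth_length_um",
    "mean_extension_um",
    "sd_extension_um",
    "low_count",
]


@dataclass
class HomeostasisFit:
    """Result of the BL/E regression for one strain."""

    strain: str
    n: int
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    cohorts: pd.DataFrame
    mode_label: str
    n_negative_extension: int


def compute_extension(records: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite ``extension_um = division_length_um - birth_length_um``.

    Records with non-positive extension are retained and marked in a boolean
    ``negative_extension`` column (dropping them would bias the regression).
    """
    for col in ("birth_length_um", "division_length_um"):
        if col not in records.columns:
            raise KeyError(f"records table is missing required column {col!r}")
    out = records.copy()
    out["extension_um"] = out["division_length_um"] - out["birth_length_um"]
    out["negative_extension"] = out["extension_um"] <= 0
    return out


def cohort_by_birth_length(
    records: pd.DataFrame, width: float = 0.5, min_count: int = 1
) -> pd.DataFrame:
    """Group records into half-open birth-length bins ``[k*w, (k+1)*w)``
    anchored at 0 and summarise extension per bin.

    Bins with fewer than ``min_count`` records are still reported but marked
    ``low_count`` so display code can grey them out.
    """
    if width <= 0:
        raise ValueError("cohort width must be positive")
    if len(records) == 0:
        raise ValueError("cannot cohort an empty table")
    df = records
    if "extension_um" not in df.columns:
        df = compute_extension(df)
    k = np.floor(df["birth_length_um"].to_numpy() / width).astype(int)
    grouped = df.assign(_bin=k).groupby("_bin")
    rows = []
    for bin_k, sub in grouped:
        ext = sub["extension_um"].to_numpy()
        rows.append(
            (
                bin_k * width,
                (bin_k + 1) * width,
                len(sub),
                sub["birth_length_um"].mean(),
                ext.mean(),
                ext.std(ddof=1) if len(ext) > 1 else np.nan,
                len(sub) < min_count,
            )
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS).sort_values(
        "bin_start_um", ignore_index=True
    )


def fit_ble(
    records: pd.DataFrame,
    strain: str | None = None,
    cohort_width: float = 0.5,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> HomeostasisFit:
    """OLS regression of extension on birth length over raw records.

    Requires at least 10 distinct birth lengths. The cohort table (display
    aid) and a control-mode label derived from the slope are attached.
    """
    df = compute_extension(records)
    bl = df["birth_length_um"].to_numpy(dtype=float)
    ext = df["extension_um"].to_numpy(dtype=float)
    if np.unique(bl).size < 10:
        raise ValueError("fit_ble needs at least 10 distinct birth lengths")
    if np.ptp(bl) == 0:
        raise ValueError("birth lengths have zero variance")
    model = sm.OLS(ext, sm.add_constant(bl)).fit()
    slope = float(model.params[1])
    if strain is None:
        strain = (
            str(df["strain"].iloc[0]) if "strain" in df.columns and len(df) else ""
        )
    fit = HomeostasisFit(
        strain=strain,
        n=len(df),
        slope=slope,
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        r_squared=float(model.rsquared),
        cohorts=cohort_by_birth_length(df, width=cohort_width),
        mode_label=classify_control_mode(slope, thresholds),
        n_negative_extension=int(df["negative_extension"].sum()),
    )
    return fit


def classify_control_mode(
    slope: float | HomeostasisFit,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> str:
    """Map a BL/E slope to a size-control label.

    With default thresholds (-0.6, -0.2, +0.2): slope <= -0.6 is
    ``sizer_like``; (-0.6, -0.2] is ``impaired`` (homeostasis present but
    weakened); (-0.2, +0.2) is ``adder_like``; >= +0.2 is ``timer_like``.
    Thresholds are conventions calibrated to reported wild-type (~ -0.72) and
    mutant (~ -0.46, -0.066) slopes, and are configurable.
    """
    if isinstance(slope, HomeostasisFit):
        slope = slope.slope
    sizer_max, impaired_max, timer_min = thresholds
    if not sizer_max < impaired_max < timer_min:
        raise ValueError("thresholds must be strictly increasing")
    if slope <= sizer_max:
        return "sizer_like"
    if slope <= impaired_max:
        return "impaired"
    if slope < timer_min:
        return "adder_like"
    return "timer_like"
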