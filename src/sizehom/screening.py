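"""Mutant-selection screen on division-length variability.

A candidate strain is selected when all four gates pass against a control
strain:

1. ``n_ok`` -- at least ``min_n`` measured cells (default 50, the sample size
   at which the chi-square CI for the SD is acceptably tight);
2. ``cv_increased`` -- candidate CV of length at division exceeds the
   control's (direction gate);
3. ``cv_significant`` -- the two-sided Feltz-Miller CV-equality test rejects
   at ``alpha`` (default 0.001);
4. ``skew_ok`` -- candidate skewness g1 within [-1, +1]; an asymmetric
   distribution skewed towards large cells indicates checkpoint-arrested
   elongated cells rather than a genuine homeostasis defect.

The test is two-sided and paired with an explicit direction check; a halved
one-sided p-value is deliberately not used. No multiplicity correction is
applied across candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from sizehom.sizestats import (
    SizeSummary,
    cv_equality_test,
    sample_skewness,
    size_summary,
)

__all__ = ["ScreenDecision", "summarize_strains", "screen_select"]


@dataclass
class ScreenDecision:
    """Outcome of the four-gate screen for one candidate strain."""

    strain: str
    n_ok: bool
    cv_increased: bool
    cv_significant: bool
    skew_ok: bool
    selected: bool
    p_value: float
    candidate_cv: float
    control_cv: float
    skewness: float
    n: int


def summarize_strains(
    records: pd.DataFrame,
    length_col: str = "division_length_um",
    strain_col: str = "strain",
) -> pd.DataFrame:
    """Per-strain descriptive summaries of division length.

    Returns one row per strain with the SizeSummary fields. Strains with
    n < 2 are reported with missing statistics (they cannot enter testing).
    """
    if length_col not in records.columns or strain_col not in records.columns:
        raise KeyError(f"records need columns {strain_col!r} and {length_col!r}")
    rows = []
    for strain, sub in records.groupby(strain_col, sort=True):
        x = sub[length_col].to_numpy(dtype=float)
        if x.size < 2:
            rows.append(
                {"strain": strain, "n": int(x.size)}
                | {
                    k: math.nan
                    for k in (
                        "mean",
                        "sd",
                        "cv",
                        "cqv",
                        "skewness",
                        "q1",
                        "median",
                        "q3",
                        "min",
                        "max",
                    )
                }
            )
            continue
        s = size_summary(x, strain=str(strain))
        rows.append(vars(s))
    return pd.DataFrame(rows)


def screen_select(
    candidate: Sequence[float] | pd.DataFrame,
    control: Sequence[float] | pd.DataFrame,
    alpha: float = 0.001,
    skew_range: tuple[float, float] = (-1.0, 1.0),
    min_n: int = 50,
    strain: str = "candidate",
    length_col: str = "division_length_um",
) -> ScreenDecision:
    """Apply the four selection gates to a candidate vs a control sample.

    ``candidate`` and ``control`` may be plain length vectors or record
    tables carrying ``length_col``. An undersized candidate yields
    ``n_ok=False`` and ``selected=False`` rather than an exception.
    """
    cand = _lengths(candidate, length_col)
    ctrl = _lengths(control, length_col)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")

    result = cv_equality_test([cand, ctrl], labels=(strain, "control"))
    cand_cv, ctrl_cv = result.cvs
    g1 = sample_skewness(cand) if cand.std(ddof=0) > 0 else 0.0

    n_ok = cand.size >= min_n
    cv_increased = cand_cv > ctrl_cv
    cv_significant = result.p_value < alpha
    skew_ok = skew_range[0] <= g1 <= skew_range[1]
    return ScreenDecision(
        strain=strain,
        n_ok=n_ok,
        cv_increased=cv_increased,
        cv_significant=cv_significant,
        skew_ok=skew_ok,
        selected=n_ok and cv_increased and cv_significant and skew_ok,
        p_value=result.p_value,
        candidate_cv=100.0 * cand_cv,
        control_cv=100.0 * ctrl_cv,
        skewness=g1,
        n=int(cand.size),
    )


def _lengths(data, length_col: str) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        if length_col not in data.columns:
            raise KeyError(f"table is missing column {length_col!r}")
        data = data[length_col]
    x = np.asarray(data, dtype=float)
    if x.size < 2:
        raise ValueError("screen requires at least 2 observations per sample")
    return x
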