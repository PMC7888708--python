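"""Quantification of multinucleate cells and per-nucleus intensities.

When cytokinesis is blocked, nuclei sharing one cytoplasm normally divide in
lock-step, so nuclei counts per cell follow the 2/4/8 doubling series. Cells
with 3, 5, 6 or 7 nuclei have undergone asynchronous nuclear divisions; their
fraction -- computed among cells with two or more nuclei, since a 1-nucleus
cell has not divided and is uninformative -- quantifies the loss of synchrony.

Independently, the per-cell coefficient of variation of per-nucleus
fluorescence intensities measures how evenly a nuclear factor accumulates
across nuclei of the same cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sizehom.sizestats import coefficient_of_variation

__all__ = [
    "NucleiCountSummary",
    "IntensityCVSummary",
    "nuclei_count_distribution",
    "asynchrony_fraction",
    "per_cell_intensity_cv",
    "nuclei_count_pmf",
    "ASYNCHRONOUS_COUNTS",
]

#: Nuclei counts outside the synchronous doubling series (up to 8).
ASYNCHRONOUS_COUNTS = frozenset({3, 5, 6, 7})


@dataclass
class NucleiCountSummary:
    """Distribution of nuclei counts over a cell population.

    ``percentages`` maps each observed count to its percentage of all cells
    (summing to 100). ``asynchrony_pct`` is the percentage of cells with a
    count in the asynchronous set among cells with >= 2 nuclei; ``None`` when
    no cell has >= 2 nuclei (undefined, not zero).
    """

    percentages: dict[int, float]
    n_cells: int
    asynchrony_pct: float | None

    def binned_percentages(self, cap: int = 8) -> dict[str, float]:
        """Display binning: counts above ``cap`` pooled into ``"8+"``
        (exact counts are kept internally)."""
        out: dict[str, float] = {}
        overflow = 0.0
        for count, pct in sorted(self.percentages.items()):
            if count > cap:
                overflow += pct
            else:
                out[str(count)] = pct
        if overflow:
            out[f"{cap}+"] = overflow
        return out


@dataclass
class IntensityCVSummary:
    """Per-cell CVs of per-nucleus intensities plus their group mean."""

    per_cell: pd.DataFrame  # columns: cell_id, n_nuclei, mean_au, cv_pct
    mean_cv_pct: float


def _counts_array(counts) -> np.ndarray:
    if isinstance(counts, pd.DataFrame):
        if "nuclei_count" not in counts.columns:
            raise KeyError("table is missing column 'nuclei_count'")
        counts = counts["nuclei_count"]
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("no nuclei counts supplied")
    if not np.issubdtype(c.dtype, np.number) or np.any(c < 1) or np.any(c != np.floor(c)):
        raise ValueError("nuclei counts must be integers >= 1")
    return c.astype(int)


def nuclei_count_distribution(counts) -> NucleiCountSummary:
    """Percentage of the population at each nuclei count.

    ``counts`` may be a vector or a long-format table with a ``nuclei_count``
    column; multiple timepoints supplied together are pooled (cells are
    totalled across timepoints).
    """
    c = _counts_array(counts)
    values, freq = np.unique(c, return_counts=True)
    pct = {int(v): float(100.0 * f / c.size) for v, f in zip(values, freq)}
    return NucleiCountSummary(
        percentages=pct,
        n_cells=int(c.size),
        asynchrony_pct=asynchrony_fraction(c),
    )


def asynchrony_fraction(
    counts, asynchronous_set: frozenset[int] = ASYNCHRONOUS_COUNTS
) -> float | None:
    """Percentage of cells with an off-series nuclei count (3, 5, 6, 7)
    among cells with two or more nuclei; ``None`` if that denominator is
    empty."""
    c = _counts_array(counts)
    divided = c[c >= 2]
    if divided.size == 0:
        return None
    asyn = np.isin(divided, list(asynchronous_set)).sum()
    return 100.0 * asyn / divided.size


def nuclei_count_pmf(division_prob: float, n_cycles: int) -> dict[int, float]:
    """Exact nuclei-count distribution of the independent-division process.

    Starting from one nucleus, each cycle every nucleus divides independently
    with probability ``q``; ``k`` divisions among ``c`` nuclei give ``c + k``
    nuclei with binomial probability. The distribution after ``n_cycles`` is
    propagated exactly (reference for the stochastic simulator).
    """
    if not 0.0 <= division_prob <= 1.0:
        raise ValueError("division_prob must be in [0, 1]")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    q = division_prob
    pmf = {1: 1.0}
    for _ in range(n_cycles):
        nxt: dict[int, float] = {}
        for c, p in pmf.items():
            for k in range(c + 1):
                pk = math.comb(c, k) * q**k * (1 - q) ** (c - k)
                nxt[c + k] = nxt.get(c + k, 0.0) + p * pk
        pmf = nxt
    return dict(sorted(pmf.items()))


def per_cell_intensity_cv(
    intensities, floor: float = 1e-6
) -> IntensityCVSummary:
    """Per-cell CV of per-nucleus intensities.

    ``intensities`` is a long-format table (``cell_id, intensity_au``, as
    written by the simulator) or a mapping/sequence of per-cell intensity
    vectors. Each cell needs >= 2 nuclei; the CV uses the sample SD (n-1),
    noted because nuclei counts are tiny (typically 4). Non-positive
    intensities are raised to ``floor`` and the cell is marked flagged.
    """
    sets = _intensity_sets(intensities)
    rows = []
    for cell_id, vals in sets:
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"cell {cell_id!r} has fewer than 2 nuclei")
        flagged = bool(np.any(vals <= 0))
        vals = np.maximum(vals, floor)
        rows.append(
            (
                cell_id,
                int(vals.size),
                float(vals.mean()),
                coefficient_of_variation(vals),
                flagged,
            )
        )
    per_cell = pd.DataFrame(
        rows, columns=["cell_id", "n_nuclei", "mean_au", "cv_pct", "flagged"]
    )
    return IntensityCVSummary(
        per_cell=per_cell, mean_cv_pct=float(per_cell["cv_pct"].mean())
    )


def _intensity_sets(intensities):
    if isinstance(intensities, pd.DataFrame):
        for col in ("cell_id", "intensity_au"):
            if col not in intensities.columns:
                raise KeyError(f"intensity table is missing column {col!r}")
        return [
            (cid, sub["intensity_au"].to_numpy())
            for cid, sub in intensities.groupby("cell_id", sort=True)
        ]
    if isinstance(intensities, dict):
        return sorted(intensities.items())
    return [(i, v) for i, v in enumerate(intensities)]
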