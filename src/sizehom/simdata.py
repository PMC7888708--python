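"""Stochastic lineage simulator for rod cells under sizer/adder/timer control.

The simulator emulates the steady-state populations measured in single-cell
time-lapse experiments: cells grow continuously from their birth length
(linearly, ``L(t) = BL + v t``, the default for fission yeast, or
exponentially, ``L(t) = BL e^{rt}``) and commit to division when a noisy
trigger fires:

* **sizer** -- division at length ``L_T + eps``: deviations in birth size are
  corrected within one cycle (BL/E slope -1);
* **adder** -- division at length ``BL + Delta + eps``: a fixed increment is
  added regardless of birth size (BL/E slope 0);
* **timer** -- division at age ``T_dur + eps``: under exponential growth large
  cells add more than small ones (BL/E slope +1 when ``rT = ln 2``).

``eps ~ N(0, sigma_T)`` is resampled once per cell. Division is near
symmetric: each daughter receives a fraction ``f ~ N(0.5, sigma_f)`` clipped
to [0.3, 0.7] of the mother's division length.

Optional frame sampling mimics time-lapse acquisition at ``frame_interval``
minutes: the recorded birth length is the true length at the first frame at or
after the actual birth, the recorded division length is the true length at the
last frame at or before the actual division, each perturbed by independent
``N(0, sigma_m)`` measurement noise, and the recorded cycle time is the frame
time difference. With ``frame_interval = 0`` the true event values are
recorded.

Two further generators support the multinucleate experiments: nuclei-doubling
with tunable synchrony (cytokinesis-blocked cells in which nuclei normally
divide in lock-step, giving 2/4/8 nuclei per cell) and per-nucleus fluorescence
intensity sets with separate between-cell and within-cell noise.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "MultinucSimParams",
    "IntensitySimParams",
    "simulate_lineages",
    "simulate_multinucleate",
    "simulate_nuclear_intensities",
    "sizer_preset",
    "adder_preset",
    "timer_preset",
    "CELL_RECORD_COLUMNS",
]

#: Column order of the cell-record table (units in the names).
CELL_RECORD_COLUMNS = [
    "cell_id",
    "lineage_id",
    "strain",
    "generation",
    "birth_time_min",
    "birth_length_um",
    "division_length_um",
    "extension_um",
    "cycle_time_min",
    "flagged",
]

_CONTROL_MODELS = ("sizer", "adder", "timer")
_GROWTH_MODELS = ("linear", "exponential")

#: Daughter-fraction clipping bounds (prevents degenerate daughters).
_FRACTION_LO, _FRACTION_HI = 0.3, 0.7

#: Grace interval (min) for trigger-already-satisfied cells when frame
#: sampling is disabled; keeps recorded extension positive.
_GRACE_MIN = 1.0


@dataclass
class SimParams:
    """Parameters of one lineage-simulation run.

    Attributes
    ----------
    control_model : {"sizer", "adder", "timer"}
        Division-trigger rule.
    growth_model : {"linear", "exponential"}
        Single-cell growth law. Linear is the default (rod cells growing by
        tip extension); exponential is offered mainly to expose the timer's
        positive BL/E slope.
    growth_rate : float
        Linear extension rate v in µm/min, or exponential rate r in 1/min.
    target_length : float
        Sizer target L_T in µm.
    increment : float
        Adder increment Delta in µm.
    duration : float
        Timer duration T_dur in min.
    trigger_noise_sd : float
        SD of the division-trigger noise: µm for sizer/adder, min for timer.
    asym_sd : float
        SD of the daughter fraction around 0.5 (dimensionless); samples are
        clipped to [0.3, 0.7].
    meas_noise_sd : float
        SD of additive measurement noise on recorded lengths, µm.
    frame_interval : float
        Imaging interval in min; 0 disables frame sampling.
    n_founders : int
        Number of independent founder cells (lineages).
    founder_mean, founder_sd : float
        Founder birth lengths are drawn from N(founder_mean, founder_sd), µm.
    max_generations : int
        Only cells of generation <= max_generations are emitted (founders are
        generation 1), matching the first-three-generations measurement rule.
    total_time : float
        Only cells dividing before this time (min) are emitted; default 720
        (a 12-h movie).
    strain : str
        Label stamped on every record.
    seed : int
        Seed of the single generator driving all stochastic draws.
    """

    control_model: str = "sizer"
    growth_model: str = "linear"
    growth_rate: float = 0.0467
    target_length: float = 14.0
    increment: float = 7.0
    duration: float = 150.0
    trigger_noise_sd: float = 1.12
    asym_sd: float = 0.02
    meas_noise_sd: float = 0.0
    frame_interval: float = 0.0
    n_founders: int = 50
    founder_mean: float = 7.0
    founder_sd: float = 0.5
    max_generations: int = 3
    total_time: float = 720.0
    strain: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if self.control_model not in _CONTROL_MODELS:
            raise ValueError(f"control_model must be one of {_CONTROL_MODELS}")
        if self.growth_model not in _GROWTH_MODELS:
            raise ValueError(f"growth_model must be one of {_GROWTH_MODELS}")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        trigger = {
            "sizer": self.target_length,
            "adder": self.increment,
            "timer": self.duration,
        }[self.control_model]
        if trigger <= 0:
            raise ValueError(
                f"trigger parameter for {self.control_model!r} must be positive"
            )
        for name in ("trigger_noise_sd", "asym_sd", "meas_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval < 0:
            raise ValueError("frame_interval must be >= 0")
        if self.n_founders < 1 or self.max_generations < 1:
            raise ValueError("n_founders and max_generations must be >= 1")
        if self.founder_mean <= 0 or self.founder_sd < 0:
            raise ValueError("founder_mean must be > 0 and founder_sd >= 0")
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")


def sizer_preset(**overrides) -> SimParams:
    """Wild-type-like sizer: L_T = 14 µm, sigma_T = 1.12 µm (division CV 8%),
    linear growth at 0.0467 µm/min (~150 min cycle at steady state)."""
    p = SimParams(
        control_model="sizer",
        target_length=14.0,
        trigger_noise_sd=1.12,
        growth_rate=0.0467,
        strain="sizer_wt",
    )
    return _apply_overrides(p, overrides)


def adder_preset(**overrides) -> SimParams:
    """Impaired-homeostasis adder: Delta = 7 µm, trigger SD calibrated so the
    stationary division-length CV is about 16% (mean 2*Delta = 14 µm)."""
    p = SimParams(
        control_model="adder",
        increment=7.0,
        trigger_noise_sd=1.94,
        growth_rate=0.0467,
        strain="adder_mut",
    )
    return _apply_overrides(p, overrides)


def timer_preset(**overrides) -> SimParams:
    """Timer under exponential growth with r*T = ln 2 (cells double in one
    cycle), exposing the positive BL/E slope."""
    t_dur = 150.0
    p = SimParams(
        control_model="timer",
        growth_model="exponential",
        duration=t_dur,
        growth_rate=math.log(2.0) / t_dur,
        trigger_noise_sd=5.0,
        strain="timer_sim",
    )
    return _apply_overrides(p, overrides)


def _apply_overrides(params: SimParams, overrides: dict) -> SimParams:
    valid = {f.name for f in fields(SimParams)}
    for key, val in overrides.items():
        if key not in valid:
            raise TypeError(f"unknown SimParams field {key!r}")
        setattr(params, key, val)
    return params


def _length_at(bl: float, t: float, growth_model: str, rate: float) -> float:
    if growth_model == "linear":
        return bl + rate * t
    return bl * math.exp(rate * t)


def _division_event(
    bl: float, params: SimParams, eps: float
) -> tuple[float, float, bool]:
    """True division length, true cycle time, and a flag for cells whose
    trigger is already satisfied at birth (those divide after one frame
    interval, or a short grace interval if frame sampling is off)."""
    gm, rate = params.growth_model, params.growth_rate
    if params.control_model == "timer":
        t = params.duration + eps
        if t <= 0:
            t = params.frame_interval if params.frame_interval > 0 else _GRACE_MIN
            return _length_at(bl, t, gm, rate), t, True
        return _length_at(bl, t, gm, rate), t, False
    target = (
        params.target_length + eps
        if params.control_model == "sizer"
        else bl + params.increment + eps
    )
    if target <= bl:
        t = params.frame_interval if params.frame_interval > 0 else _GRACE_MIN
        return _length_at(bl, t, gm, rate), t, True
    if gm == "linear":
        t = (target - bl) / rate
    else:
        t = math.log(target / bl) / rate
    return target, t, False


def simulate_lineages(params: SimParams) -> pd.DataFrame:
    """Simulate lineages of dividing cells and return one row per completed
    cell cycle.

    Founder birth lengths are drawn from ``N(founder_mean, founder_sd)``
    (truncated at 0.1 µm). Lineages are expanded breadth-first; all random
    draws come from one ``numpy`` generator seeded with ``params.seed``, so
    identical parameters give bit-identical output.

    Returns
    -------
    pandas.DataFrame
        Columns ``cell_id, lineage_id, strain, generation, birth_time_min,
        birth_length_um, division_length_um, extension_um, cycle_time_min,
        flagged``. ``extension_um`` is exactly ``division - birth``.
        ``flagged`` marks cells whose division trigger was already satisfied
        at birth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval

    queue: deque[tuple[int, int, float, float]] = deque()
    for lineage in range(params.n_founders):
        bl = max(0.1, rng.normal(params.founder_mean, params.founder_sd))
        queue.append((lineage, 1, 0.0, bl))

    rows = []
    cell_idx = 0
    while queue:
        lineage, gen, birth_time, bl = queue.popleft()
        eps = rng.normal(0.0, params.trigger_noise_sd) if params.trigger_noise_sd else 0.0
        d_true, t_true, flagged = _division_event(bl, params, eps)
        division_time = birth_time + t_true

        if dt > 0:
            birth_frame = math.ceil(birth_time / dt) * dt
            div_frame = math.floor(division_time / dt) * dt
            if div_frame <= birth_frame:
                # cycle shorter than one frame: record one-frame cycle
                div_frame = birth_frame + dt
                flagged = True
            rec_bl = _length_at(
                bl, birth_frame - birth_time, params.growth_model, params.growth_rate
            )
            rec_d = _length_at(
                bl,
                min(div_frame, division_time) - birth_time,
                params.growth_model,
                params.growth_rate,
            )
            cycle_time = div_frame - birth_frame
        else:
            rec_bl, rec_d, cycle_time = bl, d_true, t_true

        if params.meas_noise_sd:
            rec_bl += rng.normal(0.0, params.meas_noise_sd)
            rec_d += rng.normal(0.0, params.meas_noise_sd)

        if gen <= params.max_generations and division_time < params.total_time:
            rows.append(
                (
                    f"c{cell_idx:06d}",
                    f"L{lineage:04d}",
                    params.strain,
                    gen,
                    birth_time,
                    rec_bl,
                    rec_d,
                    rec_d - rec_bl,
                    cycle_time,
                    flagged,
                )
            )
            cell_idx += 1

        if gen + 1 <= params.max_generations and division_time < params.total_time:
            f = rng.normal(0.5, params.asym_sd) if params.asym_sd else 0.5
            f = min(max(f, _FRACTION_LO), _FRACTION_HI)
            queue.append((lineage, gen + 1, division_time, f * d_true))
            queue.append((lineage, gen + 1, division_time, (1.0 - f) * d_true))

    return pd.DataFrame(rows, columns=CELL_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# multinucleate cells


@dataclass
class MultinucSimParams:
    """Nuclei-doubling simulation for cytokinesis-blocked cells.

    In ``synchronous`` mode every nucleus divides each cycle (counts follow
    1, 2, 4, 8, ...). In ``independent`` mode each nucleus divides with
    probability ``division_prob`` per cycle, producing the off-series counts
    (3, 5, 6, 7) diagnostic of asynchronous nuclear division.
    """

    mode: str = "synchronous"
    division_prob: float = 1.0
    n_cycles: int = 3
    n_cells: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synchronous", "independent"):
            raise ValueError("mode must be 'synchronous' or 'independent'")
        if not 0.0 <= self.division_prob <= 1.0:
            raise ValueError("division_prob must be in [0, 1]")
        if self.n_cycles < 1 or self.n_cells < 1:
            raise ValueError("n_cycles and n_cells must be >= 1")


def simulate_multinucleate(params: MultinucSimParams) -> pd.DataFrame:
    """Simulate per-cell nuclei counts over successive division cycles.

    Every cell starts with one nucleus. Returns a long-format table with
    columns ``cell_id, cycle, nuclei_count`` (cycle 1..n_cycles), one row per
    cell per cycle.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    counts = np.ones(params.n_cells, dtype=np.int64)
    frames = []
    for cycle in range(1, params.n_cycles + 1):
        if params.mode == "synchronous":
            counts = counts * 2
        else:
            counts = counts + rng.binomial(counts, params.division_prob)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"m{i:06d}" for i in range(params.n_cells)],
                    "cycle": cycle,
                    "nuclei_count": counts.copy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# per-nucleus intensities


@dataclass
class IntensitySimParams:
    """Per-nucleus fluorescence intensities with a two-level noise model:
    cell mean ~ N(mean_intensity, between_cell_sd), nucleus intensity ~
    N(cell mean, within_cell_sd). Intensities are truncated at 0.1% of
    ``mean_intensity`` to stay positive."""

    n_cells: int = 5
    nuclei_per_cell: int = 4
    mean_intensity: float = 100.0
    between_cell_sd: float = 10.0
    within_cell_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.nuclei_per_cell < 2:
            raise ValueError("nuclei_per_cell must be >= 2")
        if self.mean_intensity <= 0:
            raise ValueError("mean_intensity must be positive")
        if self.between_cell_sd < 0 or self.within_cell_sd < 0:
            raise ValueError("intensity SDs must be >= 0")


def simulate_nuclear_intensities(params: IntensitySimParams) -> pd.DataFrame:
    """Simulate per-nucleus intensity sets; long format ``cell_id,
    nucleus_index, intensity_au``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    floor = 1e-3 * params.mean_intensity
    cell_means = rng.normal(
        params.mean_intensity, params.between_cell_sd, size=params.n_cells
    )
    intensities = rng.normal(
        cell_means[:, None],
        params.within_cell_sd,
        size=(params.n_cells, params.nuclei_per_cell),
    )
    intensities = np.maximum(intensities, floor)
    return pd.DataFrame(
        {
            "cell_id": np.repeat(
                [f"n{i:06d}" for i in range(params.n_cells)], params.nuclei_per_cell
            ),
            "nucleus_index": np.tile(
                np.arange(params.nuclei_per_cell), params.n_cells
            ),
            "intensity_au": intensities.ravel(),
        }
    )
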