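"""Record I/O, run configuration and the end-to-end pipeline.

Cell records travel as CSV (comma) or TSV (tab, chosen by file extension)
with the header written by the simulator::

    cell_id, lineage_id, strain, generation, birth_time_min,
    birth_length_um, division_length_um, extension_um, cycle_time_min

Lengths are in µm, times in min, intensities in arbitrary units, CV/CQV in
percent. A run configuration is a YAML file mirroring the parameter dataclass
field names exactly; it round-trips byte-identically. Every pipeline run
writes a manifest (seed, package version, parameter echo, flagged-record
counts) so the outputs are reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from sizehom.homeostasis import DEFAULT_THRESHOLDS, fit_ble
from sizehom.multinuclear import nuclei_count_distribution, per_cell_intensity_cv
from sizehom.screening import screen_select, summarize_strains
from sizehom.simdata import (
    CELL_RECORD_COLUMNS,
    IntensitySimParams,
    MultinucSimParams,
    SimParams,
    simulate_lineages,
    simulate_multinucleate,
    simulate_nuclear_intensities,
)

logger = logging.getLogger("sizehom")

__all__ = [
    "read_cell_records",
    "write_cell_records",
    "RunConfig",
    "run_pipeline",
]

REQUIRED_COLUMNS = [
    "cell_id",
    "lineage_id",
    "strain",
    "generation",
    "birth_time_min",
    "birth_length_um",
    "division_length_um",
    "cycle_time_min",
]

NUMERIC_COLUMNS = [
    "generation",
    "birth_time_min",
    "birth_length_um",
    "division_length_um",
    "cycle_time_min",
]

#: plausible length range (µm) for unit sanity warnings
_LENGTH_WARN_RANGE = (1.0, 50.0)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cell_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a cell-record CSV/TSV.

    Raises ``ValueError`` naming any missing required column, and a row-level
    error (with 1-based data line number) for non-numeric entries. Lengths
    outside 1-50 µm trigger a unit-sanity warning in the log, not an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in NUMERIC_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path.name}: non-numeric value in column {col!r} at line {row}"
            )
        df[col] = converted
    if "extension_um" not in df.columns:
        df["extension_um"] = df["division_length_um"] - df["birth_length_um"]
    lengths = pd.concat([df["birth_length_um"], df["division_length_um"]])
    lo, hi = _LENGTH_WARN_RANGE
    n_odd = int(((lengths < lo) | (lengths > hi)).sum())
    if n_odd:
        logger.warning(
            "%s: %d length values outside %s-%s um; check units",
            path.name,
            n_odd,
            lo,
            hi,
        )
    return df


def write_cell_records(records: pd.DataFrame, path: str | Path) -> Path:
    """Write records as CSV or TSV (by extension) in canonical column order."""
    path = Path(path)
    cols = [c for c in CELL_RECORD_COLUMNS if c in records.columns] + [
        c for c in records.columns if c not in CELL_RECORD_COLUMNS
    ]
    records.loc[:, cols].to_csv(path, sep=_sep_for(path), index=False)
    return path


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``strains`` maps a strain label to a ``SimParams`` block (field names
    identical to the dataclass); ``control_strain`` names the screen
    reference. The multinucleate and intensity blocks are optional stages.
    Defaults mirror the values documented in the modules that consume them.
    """

    outdir: str = "sizehom_run"
    seed: int = 0
    control_strain: str = "control"
    alpha: float = 0.001
    skew_lo: float = -1.0
    skew_hi: float = 1.0
    min_n: int = 50
    cohort_width: float = 0.5
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    strains: dict = field(default_factory=dict)
    multinuc: dict | None = None
    intensity: dict | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["thresholds"] = list(self.thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path


def _sim_params(name: str, block: dict, seed: int) -> SimParams:
    block = dict(block)
    block.setdefault("strain", name)
    block.setdefault("seed", seed)
    return SimParams(**block)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> summarize -> screen -> homeostasis (-> multinucleate).

    Writes per-strain record CSVs, a summary table, screen decisions, BL/E
    fit reports with cohort tables, optional multinucleate / intensity
    summaries, and a JSON manifest. Returns the manifest dictionary. All
    randomness derives from ``config.seed`` (strain order adds a fixed
    offset), so a given (config, seed) is fully deterministic.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    if not config.strains:
        raise ValueError("config.strains is empty; nothing to simulate")
    if config.control_strain not in config.strains:
        raise ValueError(
            f"control_strain {config.control_strain!r} not among strains "
            f"{sorted(config.strains)}"
        )

    manifest: dict = {
        "seed": config.seed,
        "version": _package_version(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    tables = {}
    for offset, (name, block) in enumerate(sorted(config.strains.items())):
        try:
            params = _sim_params(name, block, config.seed + offset)
            tables[name] = simulate_lineages(params)
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise RuntimeError(f"simulate stage failed for strain {name!r}: {exc}") from exc
        write_cell_records(tables[name], outdir / f"records_{name}.csv")
        n_flag = int(tables[name]["flagged"].sum())
        if n_flag:
            logger.info("strain %s: %d flagged records", name, n_flag)
    all_records = pd.concat(tables.values(), ignore_index=True)
    manifest["stages"]["simulate"] = {
        name: {"n": len(t), "flagged": int(t["flagged"].sum())}
        for name, t in tables.items()
    }

    # --- summarize ----------------------------------------------------
    summary = summarize_strains(all_records)
    summary.to_csv(outdir / "strain_summaries.csv", index=False)
    manifest["stages"]["summarize"] = {"n_strains": len(summary)}

    # --- screen -------------------------------------------------------
    control = tables[config.control_strain]["division_length_um"]
    decisions = []
    for name, t in sorted(tables.items()):
        if name == config.control_strain:
            continue
        try:
            d = screen_select(
                t["division_length_um"],
                control,
                alpha=config.alpha,
                skew_range=(config.skew_lo, config.skew_hi),
                min_n=config.min_n,
                strain=name,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"screen stage failed for strain {name!r}: {exc}") from exc
        decisions.append(vars(d))
    if decisions:
        pd.DataFrame(decisions).to_csv(outdir / "screen_decisions.csv", index=False)
    manifest["stages"]["screen"] = {
        d["strain"]: bool(d["selected"]) for d in decisions
    }

    # --- homeostasis --------------------------------------------------
    fits = {}
    for name, t in sorted(tables.items()):
        try:
            fit = fit_ble(
                t,
                strain=name,
                cohort_width=config.cohort_width,
                thresholds=tuple(config.thresholds),
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"homeostasis stage failed for strain {name!r}: {exc}"
            ) from exc
        fits[name] = fit
        fit.cohorts.to_csv(outdir / f"cohorts_{name}.csv", index=False)
    pd.DataFrame(
        [
            {
                "strain": f.strain,
                "n": f.n,
                "slope": f.slope,
                "intercept_um": f.intercept,
                "slope_se": f.slope_se,
                "r_squared": f.r_squared,
                "mode_label": f.mode_label,
                "n_negative_extension": f.n_negative_extension,
            }
            for f in fits.values()
        ]
    ).to_csv(outdir / "ble_fits.csv", index=False)
    manifest["stages"]["homeostasis"] = {
        name: {"slope": f.slope, "mode_label": f.mode_label} for name, f in fits.items()
    }

    # --- multinucleate (optional) ------------------------------------
    if config.multinuc:
        mparams = MultinucSimParams(**{"seed": config.seed, **config.multinuc})
        counts = simulate_multinucleate(mparams)
        counts.to_csv(outdir / "nuclei_counts.csv", index=False)
        final = counts[counts["cycle"] == counts["cycle"].max()]
        dist = nuclei_count_distribution(final)
        manifest["stages"]["multinuc"] = {
            "n_cells": dist.n_cells,
            "asynchrony_pct": dist.asynchrony_pct,
        }
    if config.intensity:
        iparams = IntensitySimParams(**{"seed": config.seed, **config.intensity})
        intens = simulate_nuclear_intensities(iparams)
        intens.to_csv(outdir / "nuclear_intensities.csv", index=False)
        cv = per_cell_intensity_cv(intens)
        cv.per_cell.to_csv(outdir / "intensity_cv.csv", index=False)
        manifest["stages"]["intensity"] = {"mean_cv_pct": cv.mean_cv_pct}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _package_version() -> str:
    from sizehom import __version__

    return __version__
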