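"""Table schemas, readers/writers and pipeline configuration.

All tables are comma-delimited UTF-8 with one header row; column names are
snake_case with unit suffixes (``x_um``, ``angle_deg``).  Readers validate
schemas and report offending row numbers; every writer output is
re-readable by the matching reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .classify import AngleThresholds, ResolutionModel
from .core import ValidationError
from .simulate import CohortProfile, CohortTables, get_profile

logger = logging.getLogger("kinarch")

__all__ = [
    "PipelineConfig",
    "read_spot_table",
    "read_fiber_table",
    "read_chromatin_table",
    "read_oocyte_table",
    "read_timelapse_table",
    "write_cohort_tables",
    "read_cohort_tables",
    "load_config",
    "save_config",
]

_SCHEMAS: Dict[str, dict] = {
    "spots": {
        "required": [
            "oocyte_id", "spot_id", "unit_id", "homolog_id",
            "x_um", "y_um", "z_um", "radius_um", "merged",
        ],
        "numeric": ["x_um", "y_um", "z_um", "radius_um"],
        "unique": "spot_id",
    },
    "fibers": {
        "required": [
            "oocyte_id", "fiber_id", "kinetochore_spot_id", "pole_index",
            "x_um", "y_um", "z_um", "contact_geometry",
        ],
        "numeric": ["x_um", "y_um", "z_um"],
        "unique": "fiber_id",
    },
    "chromatin": {
        "required": ["oocyte_id", "unit_id", "homolog_id", "x_um", "y_um",
                     "z_um", "extent_um"],
        "numeric": ["x_um", "y_um", "z_um", "extent_um"],
        "unique": None,
    },
    "oocytes": {
        "required": [
            "oocyte_id", "donor_age_years", "stage", "cold_treated",
            "pole0_x_um", "pole0_y_um", "pole0_z_um",
            "pole1_x_um", "pole1_y_um", "pole1_z_um",
        ],
        "numeric": ["donor_age_years", "pole0_x_um", "pole0_y_um", "pole0_z_um",
                    "pole1_x_um", "pole1_y_um", "pole1_z_um"],
        "unique": "oocyte_id",
    },
    "timelapse": {
        "required": ["oocyte_id", "t_nebd_h", "t_congression_h",
                     "t_anaphase_onset_h", "n_misaligned", "severity",
                     "lagging", "progressed"],
        "numeric": ["t_nebd_h", "t_congression_h"],
        "unique": "oocyte_id",
    },
}


def _read_table(path, kind: str) -> pd.DataFrame:
    schema = _SCHEMAS[kind]
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{kind} table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path.name}: missing required column(s) {missing}"
        )
    for col in schema["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValidationError(
                f"{path.name}: non-numeric value in column {col!r} at row "
                f"{int(bad[0]) + 2}"
            )
        if df[col].isna().any() and col in ("x_um", "y_um", "z_um"):
            row = int(df.index[df[col].isna()][0]) + 2
            raise ValidationError(
                f"{path.name}: missing coordinate in {col!r} at row {row}"
            )
        df[col] = coerced
    key = schema["unique"]
    if key is not None and df[key].duplicated().any():
        first = df[df[key].duplicated()].iloc[0]
        raise ValidationError(
            f"{path.name}: duplicate {key} {first[key]!r}"
        )
    for col in ("merged", "resolved_confident", "cold_treated", "lagging",
                "progressed"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def read_spot_table(path) -> pd.DataFrame:
    """Read and validate a kinetochore spot table (µm world coordinates)."""
    df = _read_table(path, "spots")
    if not np.isfinite(df[["x_um", "y_um", "z_um"]].to_numpy()).all():
        raise ValidationError(f"{Path(path).name}: non-finite coordinates")
    return df


def read_fiber_table(path) -> pd.DataFrame:
    df = _read_table(path, "fibers")
    if "trunk_group" not in df.columns:
        df["trunk_group"] = ""
    df["trunk_group"] = df["trunk_group"].fillna("")
    return df


def read_chromatin_table(path) -> pd.DataFrame:
    return _read_table(path, "chromatin")


def read_oocyte_table(path) -> pd.DataFrame:
    return _read_table(path, "oocytes")


def read_timelapse_table(path) -> pd.DataFrame:
    df = _read_table(path, "timelapse")
    df["t_anaphase_onset_h"] = pd.to_numeric(df["t_anaphase_onset_h"], errors="coerce")
    return df


_TABLE_FILES = {
    "oocytes": "oocytes.csv",
    "spots": "spots.csv",
    "fibers": "fibers.csv",
    "chromatin": "chromatin.csv",
    "truth_pairs": "truth_pairs.csv",
    "truth_units": "truth_units.csv",
}


def write_cohort_tables(tables: CohortTables, out_dir) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in _TABLE_FILES.items():
        df = getattr(tables, name)
        p = out_dir / fname
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p
    return paths


def read_cohort_tables(in_dir) -> CohortTables:
    in_dir = Path(in_dir)
    kw = {
        "oocytes": read_oocyte_table(in_dir / "oocytes.csv"),
        "spots": read_spot_table(in_dir / "spots.csv"),
        "chromatin": read_chromatin_table(in_dir / "chromatin.csv"),
    }
    fp = in_dir / "fibers.csv"
    kw["fibers"] = read_fiber_table(fp) if fp.exists() and fp.stat().st_size > 1 else pd.DataFrame(
        columns=_SCHEMAS["fibers"]["required"] + ["trunk_group"]
    )
    for name in ("truth_pairs", "truth_units"):
        p = in_dir / f"{name}.csv"
        kw[name] = pd.read_csv(p) if p.exists() else pd.DataFrame()
    return CohortTables(**kw)


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    profile: str = "young_baseline"
    profile_overrides: dict = field(default_factory=dict)
    thresholds: AngleThresholds = field(default_factory=AngleThresholds)
    resolution: ResolutionModel = field(default_factory=ResolutionModel)
    at_pole_fraction: float = 0.1
    out_dir: str = "kinarch_out"
    seed: int = 0
    log_level: str = "INFO"

    def build_profile(self) -> CohortProfile:
        overrides = dict(self.profile_overrides)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("resolution", self.resolution)
        return get_profile(self.profile, **overrides)

    def to_dict(self) -> dict:
        return {
            "profile": self.profile,
            "profile_overrides": dict(self.profile_overrides),
            "thresholds": dataclasses.asdict(self.thresholds),
            "resolution": dataclasses.asdict(self.resolution),
            "at_pole_fraction": self.at_pole_fraction,
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = AngleThresholds(**d["thresholds"])
        if isinstance(d.get("resolution"), dict):
            d["resolution"] = ResolutionModel(**d["resolution"])
        return PipelineConfig(**d)


def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(fh)
        else:
            data = json.load(fh)
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        else:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> detect/resolve -> pair -> classify -> stats.

    Writes all cohort tables, per-unit results, summary tables and a text
    report under ``config.out_dir``; returns them in memory too.
    Deterministic for a fixed config.
    """
    from .pipeline import classify_cohort, render_report, summarize_cohort
    from .simulate import simulate_cohort, simulate_timelapse_cohort

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    profile = config.build_profile()
    out_dir = Path(config.out_dir)

    logger.info("simulate: profile %s, %d oocytes, seed %d",
                profile.name, profile.n_oocytes, profile.seed)
    tables = simulate_cohort(profile)
    write_cohort_tables(tables, out_dir)
    logger.info("simulate: %d spots, %d fibers in, %d chromatin bodies",
                len(tables.spots), len(tables.fibers), len(tables.chromatin))

    pair_results, unit_results = classify_cohort(
        tables.oocytes, tables.spots, tables.fibers, tables.chromatin,
        thresholds=config.thresholds, resolution=config.resolution,
        at_pole_fraction=config.at_pole_fraction,
    )
    pair_results.to_csv(out_dir / "pair_results.csv", index=False, float_format="%.6f")
    unit_results.to_csv(out_dir / "unit_results.csv", index=False, float_format="%.6f")
    logger.info("classify: %d pair rows out (%d excluded), %d unit rows out",
                len(pair_results), int(pair_results["excluded"].sum()),
                len(unit_results))

    timelapse = simulate_timelapse_cohort(profile)
    timelapse.to_csv(out_dir / "timelapse.csv", index=False, float_format="%.4f")

    summary = summarize_cohort(pair_results, unit_results, tables.oocytes)
    for name, df in summary.items():
        df.to_csv(out_dir / f"summary_{name}.csv", index=False, float_format="%.6f")
    report = render_report(summary)
    (out_dir / "report.txt").write_text(report, encoding="utf-8")
    save_config(config, out_dir / "config.yaml")
    return {
        "tables": tables,
        "pair_results": pair_results,
        "unit_results": unit_results,
        "timelapse": timelapse,
        "summary": summary,
        "report": report,
    }
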