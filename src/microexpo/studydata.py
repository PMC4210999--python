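"""Packaged Milan study fixtures, file I/O and run configuration.

The study inputs are small printed tables, so CSV is the canonical
interchange format:

* concentration table — ``me_id,category,season,mean_pt_cm3,sd_pt_cm3,
  sampling_hours``, one row per (microenvironment, season);
* time profiles — ``profile_id,me_id,mean_fraction,sd_fraction``, one row
  per (subpopulation profile, microenvironment);
* summaries — one row per ME/cumulative group per scenario, either CSV or a
  JSON map keyed by ``profile|season|row``.

``load_study_bundle`` returns the packaged Milan fixtures: eleven MEs with
summer and winter concentration moments, the male and female time-activity
profiles, a ``mean_subject`` profile transcribed from the population-level
time-use column (shipped with zero spreads and a caveat — that column is
internally inconsistent with the per-gender diaries and the reproduction
targets avoid it), and cumulative-level reference records for the age,
employment and education subpopulations (their per-ME breakdown was never
published, so they cannot be simulated, only compared against).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .engine import MicroenvironmentTable, TimeProfile

__all__ = [
    "StudyBundle",
    "RunConfig",
    "load_concentration_table",
    "load_time_profile",
    "load_time_profiles",
    "load_gender_reference",
    "load_cumulative_reference",
    "load_study_bundle",
    "write_summary",
    "read_summary",
]

_DATA = resources.files("microexpo") / "data"


def _builtin(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as p:
        return pd.read_csv(p)


@dataclass(frozen=True)
class StudyBundle:
    """All packaged study inputs plus the ME category grouping."""

    conc_table: MicroenvironmentTable
    profiles: dict[str, TimeProfile]
    grouping: dict[str, str]
    gender_reference: pd.DataFrame
    cumulative_reference: pd.DataFrame


@dataclass
class RunConfig:
    """Flat run configuration, loadable from a key-value YAML file."""

    profiles: list[str] = field(default_factory=lambda: ["male", "female"])
    seasons: list[str] = field(default_factory=lambda: ["summer", "winter"])
    n_iterations: int = 2000
    seed: int = 0
    renormalize_time: bool = False
    infeasible_policy: str = "error"
    out: str | None = None
    format: str = "csv"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_concentration_table(path: str | Path | None = None) -> MicroenvironmentTable:
    """Load and validate a concentration table (builtin fixture by default)."""
    df = _builtin("concentrations.csv") if path is None else pd.read_csv(path)
    return MicroenvironmentTable(df)


def load_time_profiles(path: str | Path | None = None) -> dict[str, TimeProfile]:
    """Load every profile in a time-profile CSV, keyed by profile_id."""
    df = _builtin("time_profiles.csv") if path is None else pd.read_csv(path)
    required = {"profile_id", "me_id", "mean_fraction", "sd_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = {}
    for pid, sub in df.groupby("profile_id", sort=False):
        out[pid] = TimeProfile(
            profile_id=pid,
            data=sub[["me_id", "mean_fraction", "sd_fraction"]].reset_index(drop=True),
        )
    return out


def load_time_profile(
    profile_id: str, path: str | Path | None = None
) -> TimeProfile:
    profiles = load_time_profiles(path)
    if profile_id not in profiles:
        raise KeyError(
            f"profile {profile_id!r} not found; available: {sorted(profiles)}"
        )
    return profiles[profile_id]


def load_gender_reference() -> pd.DataFrame:
    """Printed per-ME and cumulative mean exposures for the gender profiles."""
    return _builtin("gender_reference.csv")


def load_cumulative_reference() -> pd.DataFrame:
    """Printed cumulative exposures for age/employment/education subgroups."""
    return _builtin("cumulative_reference.csv")


def load_study_bundle() -> StudyBundle:
    conc = load_concentration_table()
    return StudyBundle(
        conc_table=conc,
        profiles=load_time_profiles(),
        grouping=conc.grouping,
        gender_reference=load_gender_reference(),
        cumulative_reference=load_cumulative_reference(),
    )


def _tidy(tables: Mapping[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for (profile_id, season), table in tables.items():
        t = table.copy()
        t.insert(0, "row", t.index)
        t.insert(0, "season", season)
        t.insert(0, "profile_id", profile_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def write_summary(
    tables: Mapping[tuple[str, str], pd.DataFrame],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write scenario summaries, round-trippable at full double precision.

    ``tables`` maps (profile_id, season) to a summary DataFrame as produced
    by :func:`microexpo.engine.summarize`.  CSV output is tidy (one row per
    ME/group per scenario); JSON is a map keyed ``profile|season|row``.
    """
    if not tables:
        raise ValueError("no summaries to write")
    path = Path(path)
    tidy = _tidy(tables)
    if format == "csv":
        tidy.to_csv(path, index=False, float_format="%.17g")
    elif format == "json":
        payload = {
            f"{r.profile_id}|{r.season}|{r.row}": {
                k: getattr(r, k)
                for k in ("mean", "mean_pct", "sd", "min", "p5", "median", "p95", "max")
            }
            for r in tidy.itertuples()
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read back a summary written by :func:`write_summary` (CSV or JSON)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        rows = []
        for key, stats in payload.items():
            profile_id, season, row = key.split("|", 2)
            rows.append({"profile_id": profile_id, "season": season, "row": row, **stats})
        return pd.DataFrame(rows)
    return pd.read_csv(path)
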