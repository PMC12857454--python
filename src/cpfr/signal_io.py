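"""On-disk artifacts: tidy beat-series CSV, result tables, run configuration.

The canonical interchange format is a tidy long CSV with one row per
beat observation (columns ``participant, signal, time_s, value``, plus an
optional ``frequency_hz``).  Times are seconds from recording start; values
are mmHg (MAP) or cm/s (MCAv).  Result tables are tidy CSVs with a stable
column order so that re-running a pipeline reproduces byte-identical bodies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .beat_processing import BeatSeries
from .transition_metrics import TransitionMetrics, WindowSummary

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Input file does not match the expected tidy layout."""


class ConfigError(ValueError):
    """Run configuration fails validation."""


@dataclass(frozen=True)
class Recording:
    """Beat series for one participant at one RSS frequency."""

    participant_id: str
    frequency_hz: float
    map_series: BeatSeries
    mcav_series: BeatSeries
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        cycle = 1.0 / self.frequency_hz
        lo = max(self.map_series.times_s[0], self.mcav_series.times_s[0])
        hi = min(self.map_series.times_s[-1], self.mcav_series.times_s[-1])
        if hi - lo < cycle:
            raise ValueError(
                f"MAP and MCAv series of {self.participant_id} overlap for "
                f"{hi - lo:.1f} s, less than one oscillation cycle ({cycle:.0f} s)"
            )


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class ProtocolConfig:
    frequency_hz: float = 0.05
    expected_total_duration_s: float = 300.0
    window_lengths_s: tuple[float, ...] = (60.0, 120.0, 180.0, 240.0, 300.0)


@dataclass
class FilterConfig:
    sd_multiplier: float = 3.0
    initial_fraction_of_median: float = 0.5
    min_amplitude: float = 5.0


@dataclass
class ReliabilityConfig:
    reference_window_s: float = 300.0
    ci_level: float = 0.95


@dataclass
class AnovaConfig:
    gg_correction: bool = True
    dunnett_mc_draws: int = 50_000
    seed: int = 0


@dataclass
class RunConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    reliability: ReliabilityConfig = field(default_factory=ReliabilityConfig)
    anova: AnovaConfig = field(default_factory=AnovaConfig)
    synth: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        half_cycle = 0.5 / self.protocol.frequency_hz
        windows = tuple(sorted(self.protocol.window_lengths_s))
        for w in windows:
            n_half = w / half_cycle
            if abs(n_half - round(n_half)) > 1e-9:
                raise ConfigError(
                    f"window {w} s does not divide into whole half-cycles "
                    f"of {half_cycle} s at {self.protocol.frequency_hz} Hz"
                )
        self.protocol.window_lengths_s = windows
        if self.reliability.reference_window_s not in windows:
            raise ConfigError(
                f"reference window {self.reliability.reference_window_s} s "
                f"is not one of the analysis windows {windows}"
            )
        return self


def _fill_section(cls, data: Mapping, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        log.warning("unknown config keys under %s ignored: %s", path, sorted(unknown))
    kwargs = {k: v for k, v in data.items() if k in known}
    if "window_lengths_s" in kwargs:
        kwargs["window_lengths_s"] = tuple(float(w) for w in kwargs["window_lengths_s"])
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML (or JSON) run configuration, filling defaults.

    An empty or absent document yields the full default configuration
    (3 SD outlier filter, 95% CIs, 300 s reference window).  Unknown keys
    warn rather than fail; invalid window lists raise :class:`ConfigError`.
    """
    data: Mapping = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config root of {path} must be a mapping")
    cfg = RunConfig(
        protocol=_fill_section(ProtocolConfig, data.get("protocol", {}), "protocol"),
        filtering=_fill_section(FilterConfig, data.get("filtering", {}), "filtering"),
        reliability=_fill_section(
            ReliabilityConfig, data.get("reliability", {}), "reliability"),
        anova=_fill_section(AnovaConfig, data.get("anova", {}), "anova"),
        synth=dict(data.get("synth", {})),
    ).validate()
    log.info("resolved config: %s", cfg)
    return cfg


# ---------------------------------------------------------------------------
# beat-series CSV

_REQUIRED_COLUMNS = ("participant", "signal", "time_s", "value")


def read_beat_series(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    frequency_hz: float | None = None,
) -> list[Recording]:
    """Read the tidy beat-series CSV into one Recording per participant/frequency.

    ``column_map`` renames input columns onto the canonical names.  Rows with
    non-numeric values are dropped (count logged).  A missing required
    column, a participant lacking one of the two signals, or non-increasing
    times raise :class:`FormatError`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"beat-series file {path} is missing column '{col}'")
    if "frequency_hz" not in df.columns:
        if frequency_hz is None:
            raise FormatError(
                f"{path} has no 'frequency_hz' column and no frequency was supplied"
            )
        df["frequency_hz"] = frequency_hz

    n0 = len(df)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["time_s"] = pd.to_numeric(df["time_s"], errors="coerce")
    df = df.dropna(subset=["time_s", "value"])
    if len(df) < n0:
        log.warning("dropped %d rows with non-numeric time/value", n0 - len(df))

    recordings = []
    for (pid, freq), group in df.groupby(["participant", "frequency_hz"], sort=True):
        series = {}
        for signal, sub in group.groupby("signal"):
            t = sub["time_s"].to_numpy(dtype=float)
            v = sub["value"].to_numpy(dtype=float)
            if not np.all(np.diff(t) > 0):
                raise FormatError(
                    f"times not strictly increasing for participant {pid}, "
                    f"signal {signal}"
                )
            series[signal] = BeatSeries(t, v)
        missing = {"MAP", "MCAv"} - set(series)
        if missing:
            raise FormatError(
                f"participant {pid} at {freq} Hz is missing signal(s) "
                f"{sorted(missing)}"
            )
        recordings.append(Recording(
            participant_id=str(pid), frequency_hz=float(freq),
            map_series=series["MAP"], mcav_series=series["MCAv"],
        ))
    return recordings


def recordings_to_frame(recordings: Sequence[Recording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        for signal, series in (("MAP", rec.map_series), ("MCAv", rec.mcav_series)):
            rows.append(pd.DataFrame({
                "participant": rec.participant_id,
                "frequency_hz": rec.frequency_hz,
                "signal": signal,
                "time_s": series.times_s,
                "value": series.values,
            }))
    cols = ["participant", "frequency_hz", "signal", "time_s", "value"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# result tables

TRANSITION_COLUMNS = [
    "participant", "frequency_hz", "index", "direction",
    "map_from_time_s", "map_from_value", "map_to_time_s", "map_to_value",
    "mcav_from_time_s", "mcav_from_value", "mcav_to_time_s", "mcav_to_value",
    "delta_map", "delta_mcav", "dt_map", "dt_mcav", "rate_map", "rate_mcav",
    "rel_change_map", "rel_change_mcav", "ratio_abs", "ratio_rel",
    "included", "exclusion_reason",
]


def transitions_to_frame(
    transitions: Sequence[TransitionMetrics],
    *,
    participant_id: str,
    frequency_hz: float,
) -> pd.DataFrame:
    rows = []
    for tr in transitions:
        rows.append({
            "participant": participant_id,
            "frequency_hz": frequency_hz,
            "index": tr.index,
            "direction": tr.direction,
            "map_from_time_s": tr.map_from.time_s,
            "map_from_value": tr.map_from.value,
            "map_to_time_s": tr.map_to.time_s,
            "map_to_value": tr.map_to.value,
            "mcav_from_time_s": tr.mcav_from.time_s if tr.mcav_from else np.nan,
            "mcav_from_value": tr.mcav_from.value if tr.mcav_from else np.nan,
            "mcav_to_time_s": tr.mcav_to.time_s if tr.mcav_to else np.nan,
            "mcav_to_value": tr.mcav_to.value if tr.mcav_to else np.nan,
            "delta_map": tr.delta_map, "delta_mcav": tr.delta_mcav,
            "dt_map": tr.dt_map, "dt_mcav": tr.dt_mcav,
            "rate_map": tr.rate_map, "rate_mcav": tr.rate_mcav,
            "rel_change_map": tr.rel_change_map,
            "rel_change_mcav": tr.rel_change_mcav,
            "ratio_abs": tr.ratio_abs, "ratio_rel": tr.ratio_rel,
            "included": tr.included, "exclusion_reason": tr.exclusion_reason,
        })
    return pd.DataFrame(rows, columns=TRANSITION_COLUMNS)


SUMMARY_COLUMNS = [
    "participant", "frequency_hz", "direction", "window_s", "n_included",
    "mean_ratio_abs", "mean_ratio_rel", "mean_delta_map", "mean_delta_mcav",
    "mean_dt_map", "mean_dt_mcav", "mean_rate_map", "mean_rate_mcav",
]


def summaries_to_frame(summaries: Sequence[WindowSummary]) -> pd.DataFrame:
    rows = [{
        "participant": s.participant_id,
        "frequency_hz": s.frequency_hz,
        "direction": s.direction,
        "window_s": s.window_s,
        "n_included": s.n_included,
        "mean_ratio_abs": s.mean_ratio_abs,
        "mean_ratio_rel": s.mean_ratio_rel,
        "mean_delta_map": s.mean_delta_map,
        "mean_delta_mcav": s.mean_delta_mcav,
        "mean_dt_map": s.mean_dt_map,
        "mean_dt_mcav": s.mean_dt_mcav,
        "mean_rate_map": s.mean_rate_map,
        "mean_rate_mcav": s.mean_rate_mcav,
    } for s in summaries]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict:
    """Write result tables as tidy CSVs plus a row-count manifest.

    ``results`` maps a table kind (``transitions``, ``window_summaries``,
    ``reliability``, ``anova``, ...) to a DataFrame.  Column order is
    preserved as given; an empty frame still produces a header-only file.
    Returns the manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for kind in sorted(results):
        frame = results[kind]
        path = out / f"{kind}.csv"
        frame.to_csv(path, index=False)
        manifest["files"].append({"file": path.name, "rows": int(len(frame))})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
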