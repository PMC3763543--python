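"""Plain-text trace formats, dataset containers and run configuration.

One molecule per file, one camera frame per row, tab-delimited with
``# key=value`` metadata header lines: columns ``time_s, donor, acceptor``
for FRET traces and ``time_s, intensity`` for PIFE traces (units embedded
in the names: seconds and counts/frame). A dataset is a directory with a
``manifest.yaml``, a ``traces/`` folder and -- for synthetic data -- a
parallel ``truth/`` folder of (state, entry_s, exit_s) ground-truth
segments. Values are written with full repr precision so write -> read
round-trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .kinetics import KineticScheme, Segment, StatePath, preset_catalog
from .synthetic_data import Dataset, FrameTrace

__all__ = [
    "TraceFormatError",
    "ConfigError",
    "RunConfig",
    "write_trace",
    "read_trace",
    "write_state_path",
    "read_state_path",
    "write_dataset",
    "read_dataset",
    "read_traces",
    "load_config",
]


class TraceFormatError(ValueError):
    """Raised on malformed trace files; the message names the line."""


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


_FRET_COLUMNS = ("time_s", "donor", "acceptor")
_PIFE_COLUMNS = ("time_s", "intensity")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trace(path, trace: FrameTrace) -> None:
    path = Path(path)
    lines = [f"# channel={trace.channel_kind}", f"# frame_time={_fmt(trace.frame_time)}"]
    if trace.baseline is not None:
        lines.append(f"# baseline={_fmt(trace.baseline)}")
    for key, val in sorted(trace.meta.items()):
        lines.append(f"# {key}={val}")
    times = trace.times
    if trace.channel_kind == "fret":
        lines.append("\t".join(_FRET_COLUMNS))
        for t, d, a in zip(times, trace.donor, trace.acceptor):
            lines.append(f"{_fmt(t)}\t{_fmt(d)}\t{_fmt(a)}")
    else:
        lines.append("\t".join(_PIFE_COLUMNS))
        for t, v in zip(times, trace.intensity):
            lines.append(f"{_fmt(t)}\t{_fmt(v)}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value in ("inf", "-inf"):
        return float(value)
    return value


def read_trace(path) -> FrameTrace:
    path = Path(path)
    meta: dict = {}
    header: tuple[str, ...] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = _parse_meta(value.strip())
            continue
        fields = line.split("\t")
        if header is None:
            header = tuple(fields)
            if header not in (_FRET_COLUMNS, _PIFE_COLUMNS):
                raise TraceFormatError(
                    f"{path}:{lineno}: unrecognized column header {header!r}; "
                    f"expected {_FRET_COLUMNS} or {_PIFE_COLUMNS}"
                )
            continue
        if len(fields) != len(header):
            raise TraceFormatError(
                f"{path}:{lineno}: expected {len(header)} columns "
                f"({', '.join(header)}), found {len(fields)}"
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if header is None or not rows:
        raise TraceFormatError(f"{path}: no data rows found")
    data = np.asarray(rows)
    frame_time = float(meta.pop("frame_time", 0.05))
    channel = meta.pop("channel", "fret" if header == _FRET_COLUMNS else "pife")
    baseline = meta.pop("baseline", None)
    if header == _FRET_COLUMNS:
        return FrameTrace(
            frame_time=frame_time,
            channel_kind=channel,
            donor=data[:, 1],
            acceptor=data[:, 2],
            meta=meta,
        )
    return FrameTrace(
        frame_time=frame_time,
        channel_kind=channel,
        intensity=data[:, 1],
        baseline=baseline,
        meta=meta,
    )


def write_state_path(path, state_path: StatePath) -> None:
    lines = [f"# total_duration={_fmt(state_path.total_duration)}", "state\tentry_s\texit_s"]
    for seg in state_path.segments:
        lines.append(f"{seg.state}\t{_fmt(seg.start)}\t{_fmt(seg.end)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_state_path(path) -> StatePath:
    path = Path(path)
    duration = None
    segs: list[Segment] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("total_duration="):
                duration = float(body.partition("=")[2])
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(fields) != ("state", "entry_s", "exit_s"):
                raise TraceFormatError(f"{path}:{lineno}: bad ground-truth header")
            header_seen = True
            continue
        if len(fields) != 3:
            raise TraceFormatError(f"{path}:{lineno}: expected 3 columns")
        segs.append(Segment(fields[0], float(fields[1]), float(fields[2])))
    if duration is None or not segs:
        raise TraceFormatError(f"{path}: incomplete ground-truth file")
    return StatePath(tuple(segs), duration)


def write_dataset(dirpath, dataset: Dataset) -> None:
    dirpath = Path(dirpath)
    (dirpath / "traces").mkdir(parents=True, exist_ok=True)
    (dirpath / "truth").mkdir(parents=True, exist_ok=True)
    (dirpath / "manifest.yaml").write_text(
        yaml.safe_dump(dataset.manifest, sort_keys=False)
    )
    width = max(5, len(str(dataset.n_traces)))
    for k, (trace, path) in enumerate(zip(dataset.traces, dataset.paths)):
        stem = f"trace_{k:0{width}d}.tsv"
        write_trace(dirpath / "traces" / stem, trace)
        write_state_path(dirpath / "truth" / stem, path)


def read_dataset(dirpath) -> Dataset:
    dirpath = Path(dirpath)
    manifest_file = dirpath / "manifest.yaml"
    if not manifest_file.exists():
        raise TraceFormatError(f"{dirpath}: no manifest.yaml (not a dataset directory)")
    manifest = yaml.safe_load(manifest_file.read_text())
    scheme = KineticScheme.from_dict(manifest["scheme"])
    trace_files = sorted((dirpath / "traces").glob("*.tsv"))
    traces = [read_trace(f) for f in trace_files]
    paths = []
    for f in trace_files:
        truth = dirpath / "truth" / f.name
        if truth.exists():
            paths.append(read_state_path(truth))
    return Dataset(traces=traces, paths=paths, scheme=scheme, manifest=manifest)


def read_traces(path):
    """Read a single trace file or a dataset directory into trace list(s)."""
    path = Path(path)
    if path.is_dir():
        return read_dataset(path)
    return read_trace(path)


@dataclass
class RunConfig:
    """Validated parameters for an end-to-end pipeline run."""

    preset: str = "aaf_n1"
    n_traces: int = 100
    duration: float = 60.0
    frame_time: float = 0.05
    channel: str = "fret"
    window: int = 5
    seed: int = 0
    n_states: int = 3
    total_intensity: float = 1000.0
    noise_sd: float = 30.0
    threshold: float = 1.45
    min_frames: int = 2
    grid_step: float = 0.05
    out_dir: str = "polbind_out"

    def validate(self) -> None:
        problems = []
        if self.preset not in preset_catalog():
            problems.append(
                f"unknown preset {self.preset!r}; choose from "
                f"{sorted(preset_catalog())}"
            )
        if self.n_traces < 1:
            problems.append("n_traces must be >= 1")
        if self.duration <= 0:
            problems.append("duration must be positive seconds")
        if self.frame_time <= 0:
            problems.append("frame_time must be positive seconds")
        if self.channel not in ("fret", "pife"):
            problems.append("channel must be 'fret' or 'pife'")
        if self.window < 1 or self.window % 2 == 0:
            problems.append("window must be a positive odd integer")
        if self.n_states < 2:
            problems.append("n_states must be >= 2")
        if self.total_intensity <= 0:
            problems.append("total_intensity must be positive")
        if self.noise_sd < 0:
            problems.append("noise_sd must be nonnegative")
        if self.min_frames < 1:
            problems.append("min_frames must be >= 1")
        if not 0 < self.grid_step <= 0.5:
            problems.append("grid_step must lie in (0, 0.5]")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
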