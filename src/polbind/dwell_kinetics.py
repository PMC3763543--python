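"""Dwell-time extraction and dissociation-rate / free-energy estimation.

Binding events are located by thresholding a normalized PIFE or FRET trace;
their durations are exponential under a Markov scheme, so the dissociation
rate constant is estimated by censored-exponential maximum likelihood:
k = (uncensored events) / (total observed bound time). First and last
events of every trace are censored -- their entry or exit falls outside
the observation window -- as are photobleach-terminated events; ignoring
that censoring (e.g. a naive mean of the durations) biases k upward.
Rate ratios convert to binding free-energy differences via ddG = RT ln(k1/k2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import RateEstimate
from .synthetic_data import FrameTrace
from .trace_metrics import apparent_fret, normalize_pife

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "Interval",
    "DwellSet",
    "EnergyDifference",
    "FoldChange",
    "segment_binding_events",
    "extract_dwells",
    "fit_exponential_mle",
    "fold_change",
    "delta_g",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987e-3
#: Room temperature (~22 degrees C), the measurement condition.
DEFAULT_TEMPERATURE_K = 295.15


@dataclass(frozen=True)
class Interval:
    """A maximal bound or unbound stretch, in frames [start, end)."""

    kind: str  # "bound" | "unbound"
    start_frame: int
    end_frame: int
    censored_start: bool
    censored_end: bool

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class DwellSet:
    """Dwell durations for one state with censoring flags and exits."""

    durations: np.ndarray
    censored: np.ndarray
    state_label: str
    exit_destination: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored flags must align")
        if np.any(self.durations <= 0):
            raise ValueError("dwell durations must be positive")
        if self.exit_destination is not None:
            self.exit_destination = np.asarray(self.exit_destination, dtype=object)
            if self.exit_destination.shape != self.durations.shape:
                raise ValueError("exit destinations must align with durations")

    @property
    def n_dwells(self) -> int:
        return int(self.durations.size)

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())

    @classmethod
    def concatenate(cls, parts: Sequence["DwellSet"]) -> "DwellSet":
        parts = [p for p in parts if p.n_dwells]
        if not parts:
            return cls(np.empty(0), np.empty(0, bool), state_label="bound")
        labels = {p.state_label for p in parts}
        if len(labels) > 1:
            raise ValueError(f"cannot pool dwells across states {labels}")
        dest = None
        if all(p.exit_destination is not None for p in parts):
            dest = np.concatenate([p.exit_destination for p in parts])
        return cls(
            np.concatenate([p.durations for p in parts]),
            np.concatenate([p.censored for p in parts]),
            state_label=parts[0].state_label,
            exit_destination=dest,
        )


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two rate constants with first-order error propagation."""

    value: float
    stderr: float


@dataclass(frozen=True)
class EnergyDifference:
    """A binding free-energy difference, kcal/mol at a stated temperature."""

    value: float
    stderr: float
    temperature: float

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")


def _threshold_values(trace, observable: str | None) -> np.ndarray:
    if isinstance(trace, FrameTrace):
        if trace.channel_kind == "fret":
            vals = apparent_fret(trace.donor, trace.acceptor)
            return np.nan_to_num(vals, nan=0.0)
        return normalize_pife(trace.intensity, baseline=trace.baseline)
    return np.asarray(trace, dtype=float)


def segment_binding_events(
    trace,
    threshold: float,
    min_frames: int = 2,
    observable: str | None = None,
) -> list[Interval]:
    """Split a trace into alternating unbound/bound intervals.

    A bound interval is a run of consecutive frames above ``threshold``
    lasting at least ``min_frames`` (shorter excursions are treated as
    noise and folded back into the surrounding unbound stretch -- the
    two-frame default suppresses single-frame noise spikes at the price of
    a resolution floor of one exposure). The first and last intervals are
    censored at the trace boundaries. ``trace`` may be a
    :class:`FrameTrace` (reduced automatically) or a plain value array.
    """
    values = _threshold_values(trace, observable)
    if values.size == 0:
        return []
    if threshold <= np.nanmin(values) or threshold >= np.nanmax(values):
        warnings.warn(
            f"threshold {threshold} outside the data range "
            f"[{np.nanmin(values):.3g}, {np.nanmax(values):.3g}]; "
            "no events segmented",
            stacklevel=2,
        )
        return []
    above = values > threshold
    # demote sub-minimum bound runs to unbound
    bound = above.copy()
    n = bound.size
    i = 0
    while i < n:
        if bound[i]:
            j = i
            while j < n and bound[j]:
                j += 1
            if j - i < min_frames:
                bound[i:j] = False
            i = j
        else:
            i += 1

    intervals: list[Interval] = []
    i = 0
    while i < n:
        j = i
        while j < n and bound[j] == bound[i]:
            j += 1
        intervals.append(
            Interval(
                kind="bound" if bound[i] else "unbound",
                start_frame=i,
                end_frame=j,
                censored_start=(i == 0),
                censored_end=(j == n),
            )
        )
        i = j
    return intervals


def extract_dwells(
    source,
    state_label: str = "bound",
    frame_time: float = 0.05,
) -> DwellSet:
    """Collect the dwell durations of one state.

    ``source`` is either the interval list from
    :func:`segment_binding_events` (durations in frames x ``frame_time``,
    boundary intervals censored) or an idealized path object with
    ``labeled_segments()`` (durations in seconds, destination labels filled
    from the following segment; boundary segments censored).
    """
    if hasattr(source, "labeled_segments"):
        segs = source.labeled_segments()
        durations, censored, dests = [], [], []
        for idx, (label, dur) in enumerate(segs):
            if label != state_label:
                continue
            durations.append(dur)
            last = idx == len(segs) - 1
            censored.append(idx == 0 or last)
            dests.append(None if last else segs[idx + 1][0])
        return DwellSet(
            np.asarray(durations, dtype=float),
            np.asarray(censored, dtype=bool),
            state_label=state_label,
            exit_destination=np.asarray(dests, dtype=object)
            if durations
            else np.empty(0, dtype=object),
        )

    intervals = list(source)
    durations, censored = [], []
    for iv in intervals:
        if iv.kind != state_label:
            continue
        durations.append(iv.n_frames * frame_time)
        censored.append(iv.censored_start or iv.censored_end)
    return DwellSet(
        np.asarray(durations, dtype=float),
        np.asarray(censored, dtype=bool),
        state_label=state_label,
    )


def fit_exponential_mle(dwells: DwellSet, min_uncensored: int = 10) -> RateEstimate:
    """Censored-exponential maximum-likelihood rate estimate.

    k_hat = n_uncensored / sum(all durations); censored dwells contribute
    observation time but no event count, which is exactly what removes the
    boundary-truncation bias. stderr = k_hat / sqrt(n_uncensored).
    """
    n_unc = dwells.n_uncensored
    if dwells.n_dwells == 0 or n_unc == 0:
        raise ValueError(
            "no uncensored dwells: every event touches a trace boundary or "
            "photobleach, so the rate is unidentifiable"
        )
    if n_unc < min_uncensored:
        raise ValueError(
            f"only {n_unc} uncensored dwells (< {min_uncensored}); "
            "collect more traces or lower min_uncensored explicitly"
        )
    total_time = float(dwells.durations.sum())
    k = n_unc / total_time
    return RateEstimate(value=k, stderr=k / math.sqrt(n_unc), n_events=n_unc)


def _value_err(k) -> tuple[float, float]:
    if isinstance(k, RateEstimate):
        return float(k.value), float(k.stderr)
    return float(k), 0.0


def fold_change(k_ref, k_test) -> FoldChange:
    """Ratio k_ref / k_test with first-order error propagation."""
    v1, s1 = _value_err(k_ref)
    v2, s2 = _value_err(k_test)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("rates must be positive")
    ratio = v1 / v2
    stderr = ratio * math.sqrt((s1 / v1) ** 2 + (s2 / v2) ** 2)
    return FoldChange(value=ratio, stderr=stderr)


def delta_g(
    k_fast, k_slow, temperature: float = DEFAULT_TEMPERATURE_K
) -> EnergyDifference:
    """Free-energy difference RT ln(k_fast / k_slow) in kcal/mol.

    A slower dissociation rate means a more stable complex; the returned
    value is positive when k_fast > k_slow, i.e. the stabilization gained
    by the slow-dissociating construct.
    """
    v1, s1 = _value_err(k_fast)
    v2, s2 = _value_err(k_slow)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("rates must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    rt = R_KCAL * temperature
    value = rt * math.log(v1 / v2)
    stderr = rt * math.sqrt((s1 / v1) ** 2 + (s2 / v2) ** 2)
    return EnergyDifference(value=value, stderr=stderr, temperature=temperature)
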