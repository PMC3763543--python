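"""Camera-integrated donor/acceptor and PIFE traces from ground-truth paths.

The experimental observables are per-frame fluorescence intensities at ~50 ms
time resolution. A camera frame averages the true emission over its exposure
window, so transitions faster than the frame time produce intermediate
apparent levels -- the exposure-time-integration artifact that any honest
comparison between simulated and measured trajectories has to include.
This module converts exact :class:`~polbind.kinetics.StatePath` realizations
into such traces: time-weighted averaging of the state emission levels
within each frame, additive Gaussian detection noise per channel, optional
single-step photobleaching, and the 5- or 7-point moving average used when
the experimental traces were analyzed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticScheme, StatePath, UNBOUND, make_preset, simulate_path

__all__ = [
    "EmissionModel",
    "FrameTrace",
    "Dataset",
    "frame_occupancy",
    "integrate_frames",
    "emit_fret_trace",
    "emit_pife_trace",
    "moving_average",
    "generate_dataset",
]

DEFAULT_FRAME_TIME = 0.05  # s; ~50 ms camera resolution


@dataclass(frozen=True)
class EmissionModel:
    """Detection model for one camera channel set.

    ``total_intensity`` is the summed donor+acceptor signal (or the PIFE
    baseline) in counts/frame; ``noise_sd`` is the per-channel additive
    Gaussian noise. The defaults are calibrated so that the apparent-FRET
    standard deviation is ~0.02 and (via :meth:`for_pife`) the normalized
    PIFE standard deviation is ~0.1, the stated experimental uncertainties.
    Bleach rates are exponential single-step photobleaching rates; zero
    disables bleaching.
    """

    total_intensity: float = 1000.0
    noise_sd: float = 30.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_intensity > 0:
            raise ValueError("total_intensity must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise ValueError("bleach rates must be nonnegative")

    @classmethod
    def for_pife(
        cls,
        baseline: float = 1000.0,
        noise_sd: float = 100.0,
        donor_bleach_rate: float = 0.0,
    ) -> "EmissionModel":
        """Single-channel PIFE model; noise_sd = 0.1 x baseline by default."""
        return cls(
            total_intensity=baseline,
            noise_sd=noise_sd,
            donor_bleach_rate=donor_bleach_rate,
        )


@dataclass
class FrameTrace:
    """Per-frame intensities for one molecule.

    ``channel_kind`` is ``"fret"`` (donor + acceptor arrays) or ``"pife"``
    (a single raw intensity array whose pre-normalization baseline is kept
    so normalization is recoverable).
    """

    frame_time: float
    channel_kind: str
    donor: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    intensity: np.ndarray | None = None
    baseline: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.channel_kind == "fret":
            if self.donor is None or self.acceptor is None:
                raise ValueError("fret traces need donor and acceptor channels")
            self.donor = np.asarray(self.donor, dtype=float)
            self.acceptor = np.asarray(self.acceptor, dtype=float)
            if self.donor.shape != self.acceptor.shape:
                raise ValueError("donor/acceptor length mismatch")
        elif self.channel_kind == "pife":
            if self.intensity is None:
                raise ValueError("pife traces need an intensity channel")
            self.intensity = np.asarray(self.intensity, dtype=float)
        else:
            raise ValueError(f"channel_kind must be 'fret' or 'pife', got {self.channel_kind!r}")

    @property
    def n_frames(self) -> int:
        arr = self.donor if self.channel_kind == "fret" else self.intensity
        return int(arr.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.frame_time


def frame_occupancy(
    path: StatePath, scheme: KineticScheme, frame_time: float = DEFAULT_FRAME_TIME
) -> np.ndarray:
    """Fractional state occupancy of each camera frame.

    Frames are half-open windows [j*dt, (j+1)*dt); a partial final frame is
    discarded. Returns an (n_frames, n_states) array whose rows sum to 1.
    """
    if frame_time <= 0:
        raise ValueError("frame_time must be positive")
    n_frames = int(np.floor(path.total_duration / frame_time + 1e-9))
    if n_frames < 1:
        raise ValueError("path shorter than one camera frame")
    occ = np.zeros((n_frames, scheme.n_states))
    horizon = n_frames * frame_time
    for seg in path.segments:
        if seg.start >= horizon:
            break
        s = scheme.index(seg.state)
        f0 = int(seg.start / frame_time)
        f1 = min(int(np.ceil(seg.end / frame_time - 1e-12)), n_frames)
        frames = np.arange(f0, f1)
        starts = np.maximum(seg.start, frames * frame_time)
        ends = np.minimum(seg.end, (frames + 1) * frame_time)
        occ[frames, s] += np.clip(ends - starts, 0.0, None)
    return occ / frame_time


def integrate_frames(
    path: StatePath, scheme: KineticScheme, frame_time: float = DEFAULT_FRAME_TIME
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-frame ideal FRET and ideal PIFE sequences.

    The ideal value of frame j is the time-weighted mean of the state
    emission levels over the exposure window.
    """
    occ = frame_occupancy(path, scheme, frame_time)
    ideal_fret = occ @ np.asarray(scheme.fret_level)
    ideal_pife = occ @ np.asarray(scheme.pife_level)
    return ideal_fret, ideal_pife


def emit_fret_trace(
    ideal_fret: Sequence[float],
    model: EmissionModel,
    seed,
    frame_time: float = DEFAULT_FRAME_TIME,
) -> FrameTrace:
    """Donor/acceptor camera trace from an ideal FRET sequence.

    acceptor = I_total * E + noise, donor = I_total * (1 - E) + noise, both
    floored at zero. If bleach rates are set, exponential bleach times are
    drawn: after acceptor bleaching the transfer efficiency is treated as
    zero (signal returns to the donor); after donor bleaching both channels
    drop to noise-only background. Bleach times (possibly inf) are recorded
    in ``meta``.
    """
    ideal = np.asarray(ideal_fret, dtype=float).copy()
    if ideal.ndim != 1 or ideal.size == 0:
        raise ValueError("ideal_fret must be a nonempty 1-D sequence")
    if np.any((ideal < -1e-9) | (ideal > 1 + 1e-9)):
        raise ValueError("ideal FRET values must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = ideal.size
    centers = (np.arange(n) + 0.5) * frame_time

    t_acc = np.inf
    if model.acceptor_bleach_rate > 0:
        t_acc = rng.exponential(1.0 / model.acceptor_bleach_rate)
        ideal[centers >= t_acc] = 0.0
    acceptor = model.total_intensity * ideal + rng.normal(0.0, model.noise_sd, n)
    donor = model.total_intensity * (1.0 - ideal) + rng.normal(0.0, model.noise_sd, n)
    t_don = np.inf
    if model.donor_bleach_rate > 0:
        t_don = rng.exponential(1.0 / model.donor_bleach_rate)
        dark = centers >= t_don
        donor[dark] = rng.normal(0.0, model.noise_sd, int(dark.sum()))
        acceptor[dark] = rng.normal(0.0, model.noise_sd, int(dark.sum()))
    np.clip(donor, 0.0, None, out=donor)
    np.clip(acceptor, 0.0, None, out=acceptor)
    return FrameTrace(
        frame_time=frame_time,
        channel_kind="fret",
        donor=donor,
        acceptor=acceptor,
        meta={"donor_bleach_s": t_don, "acceptor_bleach_s": t_acc},
    )


def emit_pife_trace(
    ideal_pife: Sequence[float],
    model: EmissionModel,
    seed,
    frame_time: float = DEFAULT_FRAME_TIME,
) -> FrameTrace:
    """Single-channel PIFE camera trace: intensity = baseline * PIFE + noise."""
    ideal = np.asarray(ideal_pife, dtype=float)
    if ideal.ndim != 1 or ideal.size == 0:
        raise ValueError("ideal_pife must be a nonempty 1-D sequence")
    if np.any(ideal < 0):
        raise ValueError("ideal PIFE values must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = ideal.size
    centers = (np.arange(n) + 0.5) * frame_time
    intensity = model.total_intensity * ideal + rng.normal(0.0, model.noise_sd, n)
    t_don = np.inf
    if model.donor_bleach_rate > 0:
        t_don = rng.exponential(1.0 / model.donor_bleach_rate)
        dark = centers >= t_don
        intensity[dark] = rng.normal(0.0, model.noise_sd, int(dark.sum()))
    np.clip(intensity, 0.0, None, out=intensity)
    return FrameTrace(
        frame_time=frame_time,
        channel_kind="pife",
        intensity=intensity,
        baseline=model.total_intensity,
        meta={"donor_bleach_s": t_don},
    )


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    ``window`` must be odd (5 and 7 are the standard analysis choices).
    Edge frames average over however much of the window lies inside the
    trace, so the output has the same length as the input -- idealization
    needs a value for every frame.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    values = np.asarray(values, dtype=float)
    if window > values.size:
        raise ValueError(f"window {window} exceeds trace length {values.size}")
    if window == 1:
        return values.copy()
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


@dataclass
class Dataset:
    """A collection of simulated traces with their ground-truth paths."""

    traces: list[FrameTrace]
    paths: list[StatePath]
    scheme: KineticScheme
    manifest: dict

    @property
    def n_traces(self) -> int:
        return len(self.traces)

    def bound_mask(self, i: int) -> np.ndarray:
        """Frames of trace ``i`` that are majority-bound in the ground truth."""
        occ = frame_occupancy(self.paths[i], self.scheme, self.traces[i].frame_time)
        u = self.scheme.index(UNBOUND)
        return occ[:, u] < 0.5

    def checksum(self) -> str:
        """Content hash of all intensity arrays (reproducibility checks)."""
        h = hashlib.sha256()
        for tr in self.traces:
            if tr.channel_kind == "fret":
                h.update(tr.donor.tobytes())
                h.update(tr.acceptor.tobytes())
            else:
                h.update(tr.intensity.tobytes())
        return h.hexdigest()


def generate_dataset(
    preset: str | KineticScheme,
    n_traces: int,
    duration: float,
    model: EmissionModel | None = None,
    seed=0,
    frame_time: float = DEFAULT_FRAME_TIME,
    channel: str = "fret",
) -> Dataset:
    """Simulate an experiment: ``n_traces`` independent molecules.

    Each trace gets its own Gillespie path and emission noise stream,
    spawned deterministically from ``seed``; the ground-truth paths are
    retained for supervised checks, and the manifest records every
    parameter needed to regenerate the data.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be at least 1")
    scheme = make_preset(preset) if isinstance(preset, str) else preset
    if model is None:
        model = EmissionModel() if channel == "fret" else EmissionModel.for_pife()
    if channel not in ("fret", "pife"):
        raise ValueError("channel must be 'fret' or 'pife'")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    traces: list[FrameTrace] = []
    paths: list[StatePath] = []
    for k in range(n_traces):
        path_ss, emit_ss = children[k].spawn(2)
        path = simulate_path(scheme, duration, np.random.default_rng(path_ss))
        ideal_fret, ideal_pife = integrate_frames(path, scheme, frame_time)
        if channel == "fret":
            trace = emit_fret_trace(
                ideal_fret, model, np.random.default_rng(emit_ss), frame_time
            )
        else:
            trace = emit_pife_trace(
                ideal_pife, model, np.random.default_rng(emit_ss), frame_time
            )
        trace.meta.update({"trace_index": k, "preset": scheme.name})
        traces.append(trace)
        paths.append(path)

    manifest = {
        "preset": scheme.name,
        "scheme": scheme.to_dict(),
        "n_traces": n_traces,
        "duration_s": duration,
        "frame_time_s": frame_time,
        "channel": channel,
        "total_intensity": model.total_intensity,
        "noise_sd": model.noise_sd,
        "donor_bleach_rate": model.donor_bleach_rate,
        "acceptor_bleach_rate": model.acceptor_bleach_rate,
        "seed": None if isinstance(seed, np.random.SeedSequence) else int(seed),
    }
    return Dataset(traces=traces, paths=paths, scheme=scheme, manifest=manifest)
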