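"""Reduction of raw traces to FRET/PIFE observables and population fitting.

Apparent FRET is the per-frame acceptor fraction I_A / (I_A + I_D); PIFE is
the raw Cy3 intensity normalized to 1.0 for the unbound-DNA level. Pooled
bound-state values are histogrammed and fit with Gaussian mixtures to
identify binding orientations -- e.g. the two populations near 0.50 and
0.63 that distinguish intermediate- from exo-site binding on an
AAF-adducted primer-template terminus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .synthetic_data import FrameTrace

__all__ = [
    "PopulationFit",
    "Histogram",
    "apparent_fret",
    "estimate_pife_baseline",
    "normalize_pife",
    "build_histogram",
    "fit_population_mixture",
    "fast_exchange_average",
]

#: Default histogram supports: apparent FRET lives on [0, 1]; normalized
#: PIFE between the unbound baseline and the strongest enhancements seen.
FRET_RANGE = (0.0, 1.0)
PIFE_RANGE = (0.5, 3.0)
DEFAULT_BINS = 50


def apparent_fret(donor: Sequence[float], acceptor: Sequence[float]) -> np.ndarray:
    """Per-frame apparent FRET efficiency I_A / (I_A + I_D).

    Frames with zero total intensity are undefined and returned as NaN so
    that downstream consumers exclude rather than silently impute them.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError(
            f"donor and acceptor lengths differ: {donor.shape} vs {acceptor.shape}"
        )
    if np.any(donor < 0) or np.any(acceptor < 0):
        raise ValueError("intensities must be nonnegative")
    total = donor + acceptor
    out = np.full(donor.shape, np.nan)
    ok = total > 0
    out[ok] = acceptor[ok] / total[ok]
    return out


def estimate_pife_baseline(raw: Sequence[float], seed=0) -> tuple[float, float]:
    """Estimate the unbound-state intensity as the lower-population center.

    A two-component Gaussian mixture is fit to the raw intensities; the
    smaller mean is the unbound level (for a Gaussian population the mean
    and mode coincide). Returns (baseline, weight of the lower component).
    On an all-unbound trace both components collapse onto the baseline, so
    the estimate degrades gracefully.
    """
    raw = np.asarray(raw, dtype=float)
    fit = fit_population_mixture(raw, n_components=2, seed=seed, n_restarts=3)
    return float(fit.means[0]), float(fit.weights[0])


def normalize_pife(
    raw: Sequence[float],
    baseline: float | None = None,
    min_unbound_weight: float = 0.02,
    seed=0,
) -> np.ndarray:
    """Normalize a raw PIFE trace so the unbound-DNA level sits at 1.0.

    With ``baseline=None`` the unbound level is estimated as the mode of
    the lower intensity population (via :func:`estimate_pife_baseline`);
    an explicit baseline is divided out directly. If the lower population
    holds less than ``min_unbound_weight`` of the frames, no credible
    unbound level exists and a :class:`ValueError` explains the remedy.
    """
    raw = np.asarray(raw, dtype=float)
    if baseline is None:
        if raw.size < 50:
            raise ValueError(
                "too few frames to estimate an unbound baseline; pass "
                "baseline= explicitly"
            )
        baseline, weight = estimate_pife_baseline(raw, seed=seed)
        if weight < min_unbound_weight:
            raise ValueError(
                f"no unbound frames detected (lower population weight "
                f"{weight:.3f} < {min_unbound_weight}); the molecule appears "
                "bound throughout -- supply baseline= from a calibration "
                "trace instead"
            )
    if not baseline > 0:
        raise ValueError("baseline must be positive")
    return raw / float(baseline)


@dataclass(frozen=True)
class Histogram:
    """Binned counts plus the density normalized to unit integral."""

    counts: np.ndarray
    edges: np.ndarray
    density: np.ndarray
    per_trace_counts: tuple[int, ...]
    observable: str

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _trace_values(trace, observable: str) -> np.ndarray:
    if isinstance(trace, FrameTrace):
        if observable == "fret":
            if trace.channel_kind != "fret":
                raise ValueError("fret observable requested from a PIFE trace")
            return apparent_fret(trace.donor, trace.acceptor)
        if trace.channel_kind != "pife":
            raise ValueError("pife observable requested from a FRET trace")
        return normalize_pife(trace.intensity, baseline=trace.baseline)
    return np.asarray(trace, dtype=float)


def build_histogram(
    traces: Sequence,
    observable: str = "fret",
    bins: int = DEFAULT_BINS,
    value_range: tuple[float, float] | None = None,
    frame_filter: Callable[[np.ndarray], np.ndarray] | None = None,
) -> Histogram:
    """Pool per-frame values from many traces into a normalized histogram.

    ``traces`` may be :class:`FrameTrace` objects or plain value arrays.
    ``frame_filter`` receives each trace's value array and returns a boolean
    keep-mask (e.g. a bound-frame selector). NaN (undefined) frames are
    always dropped. Per-trace frame counts are reported so over-weighting
    by long traces is visible.
    """
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    if observable not in ("fret", "pife"):
        raise ValueError("observable must be 'fret' or 'pife'")
    if value_range is None:
        value_range = FRET_RANGE if observable == "fret" else PIFE_RANGE

    pooled = []
    per_trace = []
    for tr in traces:
        vals = _trace_values(tr, observable)
        keep = ~np.isnan(vals)
        if frame_filter is not None:
            keep &= np.asarray(frame_filter(vals), dtype=bool)
        vals = vals[keep]
        per_trace.append(int(vals.size))
        pooled.append(vals)
    samples = np.concatenate(pooled)
    if samples.size == 0:
        raise ValueError("frame filter removed every frame")
    counts, edges = np.histogram(samples, bins=bins, range=value_range)
    width = np.diff(edges)
    total = counts.sum()
    density = counts / (total * width) if total else counts.astype(float)
    return Histogram(
        counts=counts,
        edges=edges,
        density=density,
        per_trace_counts=tuple(per_trace),
        observable=observable,
    )


@dataclass(frozen=True)
class PopulationFit:
    """Gaussian-mixture description of a pooled observable distribution."""

    n_components: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    bic: float
    converged: bool

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component sds must be positive")
        if list(self.means) != sorted(self.means):
            raise ValueError("means must be sorted ascending")


def _em_monotone_fit(X, k, random_state, max_iter, tol):
    """One EM run driven a single iteration at a time.

    Driving scikit-learn's GaussianMixture with warm starts lets us assert
    the EM guarantee -- the log-likelihood lower bound never decreases --
    on every fit rather than trusting it.
    """
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        max_iter=1,
        warm_start=True,
        init_params="k-means++",
        random_state=random_state,
        reg_covar=1e-10,
        tol=0.0,
    )
    n = X.shape[0]
    prev = -np.inf
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            lb = gm.lower_bound_  # mean per-sample log-likelihood
            if lb < prev - 1e-9 * max(1.0, abs(lb)):
                raise AssertionError(
                    f"EM log-likelihood decreased ({prev} -> {lb})"
                )
            # relative convergence of the total log-likelihood
            if abs(lb - prev) * n <= tol * max(1.0, abs(lb) * n):
                converged = True
                break
            prev = lb
    return gm, float(gm.lower_bound_), converged


def fit_population_mixture(
    samples: Sequence[float],
    n_components: int | None = 2,
    seed=0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    max_components: int = 4,
) -> PopulationFit:
    """Maximum-likelihood Gaussian mixture via EM with multiple restarts.

    The best log-likelihood over ``n_restarts`` k-means++-seeded runs is
    kept; components are reported sorted by mean. ``n_components=None``
    selects the component count in 1..``max_components`` by BIC.
    """
    X = np.asarray(samples, dtype=float).reshape(-1, 1)
    if X.shape[0] < 50:
        raise ValueError(f"need at least 50 samples, got {X.shape[0]}")

    if n_components is None:
        fits = [
            fit_population_mixture(
                samples, k, seed=seed, n_restarts=n_restarts, max_iter=max_iter, tol=tol
            )
            for k in range(1, max_components + 1)
        ]
        return min(fits, key=lambda f: f.bic)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    rng = np.random.default_rng(seed)
    best = None
    n_converged = 0
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        gm, lb, conv = _em_monotone_fit(X, n_components, rs, max_iter, tol)
        n_converged += conv
        if conv and (best is None or lb > best[1]):
            best = (gm, lb)
    if best is None:
        raise RuntimeError(
            f"EM failed to converge in any of {n_restarts} restarts "
            f"(max_iter={max_iter}, tol={tol}); inspect the sample "
            "distribution or raise max_iter"
        )
    gm, lb = best
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    weights = weights / weights.sum()
    return PopulationFit(
        n_components=n_components,
        means=tuple(float(m) for m in means),
        sds=tuple(float(s) for s in sds),
        weights=tuple(float(w) for w in weights),
        log_likelihood=float(lb * X.shape[0]),
        bic=float(gm.bic(X)),
        converged=True,
    )


def fast_exchange_average(
    levels: Sequence[float], occupancies: Sequence[float]
) -> float:
    """Occupancy-weighted mean signal under exchange faster than a frame.

    If a molecule shuttles between states faster than the camera resolves,
    every frame reports this weighted average instead of the individual
    levels -- e.g. equal-time exchange between the pol (PIFE 1.2) and
    exo-like (PIFE 1.8) signatures would read ~1.5, so the absence of a
    1.5 population rules that hypothesis out.
    """
    levels = np.asarray(levels, dtype=float)
    occupancies = np.asarray(occupancies, dtype=float)
    if levels.shape != occupancies.shape:
        raise ValueError("levels and occupancies must have equal length")
    if abs(occupancies.sum() - 1.0) > 1e-9:
        raise ValueError("occupancies must sum to 1")
    if np.any(occupancies < 0):
        raise ValueError("occupancies must be nonnegative")
    return float(levels @ occupancies)
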