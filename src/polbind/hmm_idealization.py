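"""Hidden-Markov idealization of FRET traces and transition statistics.

Each frame of an apparent-FRET trace is assigned to a discrete binding
state (unbound ~0 FRET, intermediate ~0.50, exo ~0.63) by a shared
Gaussian-emission HMM fit across traces (Baum-Welch) followed by Viterbi
decoding. Inter-state rate constants come from the idealized paths by the
transition-count estimator k(i->j) = N(i->j) / T(i); a matrix-logarithm
alternative derived from the fitted per-frame transition matrix is kept as
a cross-check because frame discretization and exposure-time integration
hide dwells shorter than the camera resolution from the count estimator.
Transition density plots bin the observed FRET before/after every
idealized transition and expose which state pairs actually interconvert.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from hmmlearn.hmm import GaussianHMM

from .kinetics import RateEstimate
from .trace_metrics import PopulationFit, fit_population_mixture

__all__ = [
    "HMMFit",
    "IdealizedPath",
    "TransitionDensity",
    "RateMatrix",
    "fit_hmm",
    "viterbi",
    "merge_short_segments",
    "rates_from_idealization",
    "rates_from_transition_matrix",
    "transition_density",
    "state_path_log_likelihood",
    "plot_transition_density",
]

logger = logging.getLogger(__name__)

_DEFAULT_LABELS = {
    2: ("unbound", "bound"),
    3: ("unbound", "intermediate", "exo"),
}


def _labels_for(n_states: int, labels: Sequence[str] | None) -> tuple[str, ...]:
    if labels is not None:
        if len(labels) != n_states:
            raise ValueError("one label per state is required")
        return tuple(labels)
    return _DEFAULT_LABELS.get(n_states, tuple(f"state_{i}" for i in range(n_states)))


@dataclass(frozen=True)
class HMMFit:
    """Shared-emission Gaussian HMM parameters, states sorted by mean.

    State 0 is always the lowest-mean state; for 3-state fits the labels
    are (unbound, intermediate, exo), a deterministic mapping that keeps
    close-lying components from swapping identities between runs.
    """

    n_states: int
    state_labels: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        tm = np.asarray(self.transition_matrix, dtype=float)
        if np.any(np.abs(tm.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("emission sds must be positive")
        if not np.isfinite(self.log_likelihood):
            raise ValueError("log-likelihood must be finite")
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(
            self, "initial_probs", np.asarray(self.initial_probs, dtype=float)
        )

    def to_model(self) -> GaussianHMM:
        """Materialize an hmmlearn model with these parameters."""
        m = GaussianHMM(
            n_components=self.n_states, covariance_type="diag", init_params=""
        )
        # floor the start distribution: a state never seen at frame 0 during
        # fitting must stay reachable when decoding new traces
        start = np.maximum(np.array(self.initial_probs), 1e-6)
        m.startprob_ = start / start.sum()
        m.transmat_ = np.array(self.transition_matrix)
        m.means_ = np.array(self.means).reshape(-1, 1)
        m.covars_ = (np.array(self.sds) ** 2).reshape(-1, 1)
        return m

    def state_weights(self, paths: Sequence["IdealizedPath"]) -> np.ndarray:
        """Fraction of idealized frames assigned to each state."""
        counts = np.zeros(self.n_states)
        for p in paths:
            counts += np.bincount(p.states, minlength=self.n_states)
        return counts / counts.sum()


def _segment_indices(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start, end) runs over a frame-label array; end exclusive."""
    segs = []
    n = states.size
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        segs.append((int(states[i]), i, j))
        i = j
    return segs


@dataclass
class IdealizedPath:
    """Per-frame discrete state assignment with compressed segments."""

    states: np.ndarray
    labels: tuple[str, ...]
    observed: np.ndarray
    frame_time: float

    segment_indices: list[tuple[int, int, int]] = field(init=False)
    segment_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.states.shape != self.observed.shape:
            raise ValueError("states and observed values must align per frame")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= len(self.labels)
        ):
            raise ValueError("state indices outside the label set")
        self.segment_indices = _segment_indices(self.states)
        self.segment_means = np.array(
            [self.observed[a:b].mean() for _, a, b in self.segment_indices]
        )

    @property
    def n_frames(self) -> int:
        return int(self.states.size)

    @property
    def segments(self) -> list[tuple[str, int, int]]:
        return [(self.labels[s], a, b) for s, a, b in self.segment_indices]

    def labeled_segments(self) -> list[tuple[str, float]]:
        """Ordered (label, duration-in-seconds) pairs; the same interface
        as ground-truth :class:`~polbind.kinetics.StatePath`."""
        return [
            (self.labels[s], (b - a) * self.frame_time)
            for s, a, b in self.segment_indices
        ]


def fit_hmm(
    traces: Sequence[np.ndarray],
    n_states: int = 3,
    init: PopulationFit | Sequence[float] | None = None,
    seed=0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    labels: Sequence[str] | None = None,
) -> HMMFit:
    """Baum-Welch fit of a Gaussian-emission HMM shared across traces.

    Emission means are initialized from a mixture fit of the pooled frames
    (or from ``init``) rather than at random -- the intermediate and exo
    components lie only ~0.13 apart and random starts make them swap.
    Restarts jitter the initial means; the best converged log-likelihood
    wins. The EM log-likelihood is asserted non-decreasing at every
    iteration by driving the underlying model one step at a time. If no
    restart reaches the relative tolerance, the best restart is returned
    with ``converged=False``.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    arrs = [np.asarray(t, dtype=float).ravel() for t in traces]
    lengths = [a.size for a in arrs]
    X = np.concatenate(arrs).reshape(-1, 1)
    n_params = n_states * 2 + n_states * (n_states - 1) + (n_states - 1)
    if X.shape[0] < 10 * n_params:
        raise ValueError(
            f"{X.shape[0]} pooled frames is too few for {n_params} parameters"
        )

    rng = np.random.default_rng(seed)
    if init is None:
        sub = X.ravel()
        if sub.size > 20000:
            sub = sub[np.linspace(0, sub.size - 1, 20000).astype(int)]
        init = fit_population_mixture(sub, n_components=n_states, seed=rng, n_restarts=5)
    if isinstance(init, PopulationFit):
        means0 = np.asarray(init.means, dtype=float)
        sds0 = np.maximum(np.asarray(init.sds, dtype=float), 1e-3)
        if means0.size != n_states:
            raise ValueError("init mixture component count != n_states")
    else:
        means0 = np.sort(np.asarray(init, dtype=float))
        sds0 = np.full(n_states, 0.03)

    best = None
    for restart in range(n_restarts):
        m0 = means0.copy()
        if restart > 0:
            m0 = np.sort(m0 + rng.normal(0.0, 0.02, n_states))
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=1,
            tol=0.0,
            init_params="",
            params="stmc",
            min_covar=1e-8,
            # a vanishing covariance prior keeps the M-step maximum
            # likelihood (not MAP), which is what makes the per-iteration
            # monotonicity assertion below valid
            covars_prior=1e-10,
            covars_weight=1.0,
        )
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        tm = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(tm, 0.9)
        model.transmat_ = tm
        model.means_ = m0.reshape(-1, 1)
        model.covars_ = (sds0**2).reshape(-1, 1)

        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            model.fit(X, lengths)
            ll = model.monitor_.history[-1]
            if ll < prev - 1e-7 * max(1.0, abs(ll)):
                raise AssertionError(
                    f"Baum-Welch log-likelihood decreased ({prev} -> {ll})"
                )
            if np.isfinite(prev) and abs(ll - prev) <= tol * max(1.0, abs(ll)):
                converged = True
                break
            prev = ll
        if best is None or (converged, ll) > (best[2], best[1]):
            best = (model, float(ll), converged, it)

    model, ll, converged, n_iter = best
    if not converged:
        logger.warning(
            "Baum-Welch did not reach tol=%g in %d iterations; returning the "
            "best restart (log-likelihood %.3f)",
            tol,
            max_iter,
            ll,
        )
    order = np.argsort(model.means_.ravel())
    means = model.means_.ravel()[order]
    sds = np.sqrt(np.asarray(model.covars_).reshape(model.n_components, -1).ravel()[order])
    transmat = model.transmat_[np.ix_(order, order)]
    transmat = transmat / transmat.sum(axis=1, keepdims=True)
    startprob = model.startprob_[order]
    startprob = startprob / startprob.sum()
    return HMMFit(
        n_states=n_states,
        state_labels=_labels_for(n_states, labels),
        means=tuple(float(x) for x in means),
        sds=tuple(float(x) for x in sds),
        transition_matrix=transmat,
        initial_probs=startprob,
        log_likelihood=ll,
        converged=converged,
        n_iter=n_iter,
    )


def viterbi(fit: HMMFit, traces, frame_time: float = 0.05):
    """Most-probable state path(s) for one trace or a list of traces.

    A single 1-D array returns one :class:`IdealizedPath`; a list returns a
    list. All traces are decoded in one batched pass.
    """
    single = not isinstance(traces, (list, tuple))
    arrs = [np.asarray(traces, dtype=float).ravel()] if single else [
        np.asarray(t, dtype=float).ravel() for t in traces
    ]
    model = fit.to_model()
    lengths = [a.size for a in arrs]
    states = model.predict(np.concatenate(arrs).reshape(-1, 1), lengths)
    paths = []
    off = 0
    for a, ln in zip(arrs, lengths):
        paths.append(
            IdealizedPath(
                states=states[off : off + ln],
                labels=fit.state_labels,
                observed=a,
                frame_time=frame_time,
            )
        )
        off += ln
    return paths[0] if single else paths


def merge_short_segments(path: IdealizedPath, min_frames: int = 2) -> IdealizedPath:
    """Absorb segments shorter than ``min_frames`` into a neighbor.

    Exchange faster than the 50 ms frame time is unresolvable, so
    single-frame segments are treated as assignment noise: the shortest
    offending segment is relabeled to its longer neighbor (ties keep the
    preceding one) until none remain. Deterministic by construction.
    """
    segs = [[s, a, b] for s, a, b in path.segment_indices]
    while len(segs) > 1:
        lengths = [b - a for _, a, b in segs]
        short = [i for i, ln in enumerate(lengths) if ln < min_frames]
        if not short:
            break
        idx = min(short, key=lambda i: (lengths[i], i))
        if idx == 0:
            nb = 1
        elif idx == len(segs) - 1:
            nb = idx - 1
        else:
            nb = idx - 1 if lengths[idx - 1] >= lengths[idx + 1] else idx + 1
        segs[idx][0] = segs[nb][0]
        merged = [segs[0]]
        for s in segs[1:]:
            if s[0] == merged[-1][0]:
                merged[-1][2] = s[2]
            else:
                merged.append(s)
        segs = merged
    states = np.empty(path.n_frames, dtype=int)
    for s, a, b in segs:
        states[a:b] = s
    return IdealizedPath(
        states=states,
        labels=path.labels,
        observed=path.observed,
        frame_time=path.frame_time,
    )


@dataclass(frozen=True)
class RateMatrix:
    """Pairwise rate constants estimated from idealized paths."""

    labels: tuple[str, ...]
    value: np.ndarray
    stderr: np.ndarray
    counts: np.ndarray
    total_time: np.ndarray

    def get(self, src: str, dst: str) -> RateEstimate:
        i, j = self.labels.index(src), self.labels.index(dst)
        return RateEstimate(
            value=float(self.value[i, j]),
            stderr=float(self.stderr[i, j]),
            n_events=int(self.counts[i, j]),
        )


def rates_from_idealization(
    paths: Sequence[IdealizedPath],
    frame_time: float | None = None,
    min_frames: int = 2,
    merge: bool = True,
) -> RateMatrix:
    """Transition-count MLE: k(i->j) = N(i->j) / T(i).

    Segments shorter than ``min_frames`` are merged first (resolution
    floor); each path's final segment is censored -- it contributes
    occupancy time but no exit event, the survival-analysis treatment that
    keeps truncated dwells from biasing the rates. Unobserved pairs report
    rate 0 with a zero event count.
    """
    if not paths:
        raise ValueError("at least one idealized path is required")
    labels = paths[0].labels
    n = len(labels)
    dt = frame_time if frame_time is not None else paths[0].frame_time
    counts = np.zeros((n, n), dtype=int)
    total_time = np.zeros(n)
    for p in paths:
        if p.labels != labels:
            raise ValueError("paths carry inconsistent state labels")
        q = merge_short_segments(p, min_frames) if merge else p
        segs = q.segment_indices
        for s, a, b in segs:
            total_time[s] += (b - a) * dt
        for (s1, _, _), (s2, _, _) in zip(segs, segs[1:]):
            counts[s1, s2] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(total_time[:, None] > 0, counts / total_time[:, None], 0.0)
        stderr = np.where(counts > 0, value / np.sqrt(np.maximum(counts, 1)), 0.0)
    return RateMatrix(
        labels=labels,
        value=value,
        stderr=stderr,
        counts=counts,
        total_time=total_time,
    )


def rates_from_lagged_transitions(
    paths: Sequence[IdealizedPath],
    frame_time: float | None = None,
    lag: int = 3,
) -> np.ndarray:
    """Generator-matrix rates from lagged Viterbi transition counts.

    Frame-averaged emissions smear every transition across one exposure, so
    per-frame transition counts underestimate fast rates. Counting state
    changes at a lag of several frames amortizes that single-frame
    assignment blur while the matrix logarithm Q = logm(P_lag) / (lag dt)
    still accounts for multiple jumps inside the lag window; the default
    lag of 3 frames (150 ms) keeps the lag time below typical dwell
    lengths. This is the estimator of choice when dwells approach the
    camera resolution; compare with :func:`rates_from_idealization`, whose
    dwell-count estimate documents the magnitude of the artifact.
    """
    if not paths:
        raise ValueError("at least one idealized path is required")
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    n = len(paths[0].labels)
    dt = frame_time if frame_time is not None else paths[0].frame_time
    C = np.zeros((n, n))
    for p in paths:
        s = p.states
        if s.size <= lag:
            continue
        np.add.at(C, (s[:-lag], s[lag:]), 1)
    row = C.sum(axis=1, keepdims=True)
    if np.any(row == 0):
        raise ValueError("a state is never occupied; cannot estimate rates")
    Q = scipy.linalg.logm(C / row).real / (lag * dt)
    off = np.clip(Q - np.diag(np.diag(Q)), 0.0, None)
    np.fill_diagonal(off, 0.0)
    return off


def rates_from_transition_matrix(fit: HMMFit, frame_time: float = 0.05) -> np.ndarray:
    """Generator-matrix rates from the fitted per-frame transition matrix.

    The per-frame matrix of a CTMC observed every dt is P = expm(Q dt), so
    Q = logm(P) / dt. Unlike the dwell-count estimator this accounts for
    multiple jumps within one exposure, which matters when dwells approach
    the frame time; small negative off-diagonal artifacts of the matrix
    logarithm are clipped to zero and the diagonal re-balanced.
    """
    P = np.asarray(fit.transition_matrix, dtype=float)
    Q = scipy.linalg.logm(P).real / frame_time
    off = Q - np.diag(np.diag(Q))
    off = np.clip(off, 0.0, None)
    np.fill_diagonal(off, 0.0)
    return off


@dataclass(frozen=True)
class TransitionDensity:
    """2-D histogram of (FRET before, FRET after) over idealized transitions."""

    counts: np.ndarray
    edges: np.ndarray
    total: int
    class_counts: dict
    points: np.ndarray

    def class_fraction(self, pair: tuple[str, str], symmetric: bool = True) -> float:
        """Fraction of transitions in a state-pair class (both directions
        pooled when ``symmetric``)."""
        if self.total == 0:
            return 0.0
        c = self.class_counts.get(pair, 0)
        if symmetric:
            c += self.class_counts.get((pair[1], pair[0]), 0)
        return c / self.total


def transition_density(
    paths: Sequence[IdealizedPath],
    bins: int = 50,
    min_frames: int = 2,
    merge: bool = True,
) -> TransitionDensity:
    """Pool every segment boundary into a transition density plot.

    Each transition contributes the mean observed FRET of the preceding
    and following segments, binned on [0, 1]^2; class tallies count the
    ordered label pairs so that e.g. direct unbound<->exo transitions can
    be quantified against the shuttling and association/dissociation
    classes.
    """
    before, after, pairs = [], [], []
    for p in paths:
        q = merge_short_segments(p, min_frames) if merge else p
        segs = q.segment_indices
        means = q.segment_means
        for k in range(len(segs) - 1):
            before.append(means[k])
            after.append(means[k + 1])
            pairs.append((q.labels[segs[k][0]], q.labels[segs[k + 1][0]]))
    if not before:
        raise ValueError("no transitions in the supplied paths")
    pts = np.column_stack([before, after])
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _, _ = np.histogram2d(
        np.clip(pts[:, 0], 0, 1), np.clip(pts[:, 1], 0, 1), bins=[edges, edges]
    )
    tally: dict = {}
    for pr in pairs:
        tally[pr] = tally.get(pr, 0) + 1
    return TransitionDensity(
        counts=counts, edges=edges, total=len(pairs), class_counts=tally, points=pts
    )


def state_path_log_likelihood(
    fit: HMMFit, states: np.ndarray, observed: np.ndarray
) -> float:
    """Joint log-likelihood of a specific state path and the observations.

    Used to verify Viterbi optimality: the decoded path must score at
    least as high as any other path, including the ground truth.
    """
    states = np.asarray(states, dtype=int)
    observed = np.asarray(observed, dtype=float)
    means = np.asarray(fit.means)
    sds = np.asarray(fit.sds)
    with np.errstate(divide="ignore"):
        ll = float(np.log(fit.initial_probs[states[0]]))
        ll += float(np.log(fit.transition_matrix[states[:-1], states[1:]]).sum())
    resid = (observed - means[states]) / sds[states]
    ll += float(
        (-0.5 * resid**2 - np.log(sds[states]) - 0.5 * np.log(2 * np.pi)).sum()
    )
    return ll


def plot_transition_density(td: TransitionDensity, ax=None):
    """Render a transition density plot (log-scaled counts)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    with np.errstate(divide="ignore"):
        img = np.log10(td.counts.T + 1)
    ax.imshow(
        img,
        origin="lower",
        extent=(td.edges[0], td.edges[-1], td.edges[0], td.edges[-1]),
        aspect="equal",
        cmap="viridis",
    )
    ax.set_xlabel("FRET before transition")
    ax.set_ylabel("FRET after transition")
    return ax
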