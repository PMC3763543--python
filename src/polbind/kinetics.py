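"""Kinetic schemes and exact stochastic simulation of polymerase-DNA binding.

A polymerase-DNA binding landscape is modelled as a continuous-time Markov
chain (CTMC) over a small set of states: the unbound DNA, the catalytic pol
site, the proofreading exo site and -- for adducted or mismatched
primer-template termini -- an intermediate binding orientation whose FRET
signature (~0.50) lies between the pol and exo values. Each state carries
the apparent FRET efficiency and the protein-induced fluorescence
enhancement (PIFE, normalized to 1.0 for unbound DNA) that it produces in a
camera trace.

:func:`simulate_path` draws exact Gillespie realizations of a scheme;
:func:`make_preset` returns schemes parameterized with the dissociation and
shuttling rate constants measured for the experimental constructs
(unmodified, 2-aminofluorene- and N-acetyl-2-aminofluorene-adducted
primer-templates, with the adduct either at the templating base or across
from the primer terminus); :func:`add_direct_dissociation` augments a
three-state unbound/intermediate/exo scheme with a direct exo->unbound exit
tuned so that a requested fraction of dissociation events terminates in the
exo state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import yaml

__all__ = [
    "UNBOUND",
    "SchemeError",
    "KineticScheme",
    "Segment",
    "StatePath",
    "RateEstimate",
    "simulate_path",
    "make_preset",
    "preset_catalog",
    "add_direct_dissociation",
]

#: Canonical label of the unbound-DNA state (FRET 0, PIFE 1.0 by definition).
UNBOUND = "unbound"


class SchemeError(ValueError):
    """Raised when a kinetic scheme violates its invariants."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class KineticScheme:
    """A CTMC over polymerase-DNA binding states with per-state emissions.

    Parameters
    ----------
    state_names
        State labels; the unbound state, when present, must be named
        ``"unbound"`` and have FRET 0 and PIFE 1.0.
    fret_level, pife_level
        Per-state apparent FRET (in [0, 1]) and normalized PIFE (>= 0).
    rates
        Square matrix of transition rate constants in s^-1; entry (i, j) is
        the i -> j rate, the diagonal is zero and off-diagonals nonnegative.
    initial_state
        Label of the state occupied at t = 0.
    """

    state_names: tuple[str, ...]
    fret_level: tuple[float, ...]
    pife_level: tuple[float, ...]
    rates: np.ndarray
    initial_state: str = UNBOUND
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_names", tuple(str(s) for s in self.state_names))
        object.__setattr__(self, "fret_level", tuple(float(x) for x in self.fret_level))
        object.__setattr__(self, "pife_level", tuple(float(x) for x in self.pife_level))
        rates = np.array(self.rates, dtype=float)
        rates.setflags(write=False)
        object.__setattr__(self, "rates", rates)
        self._validate()

    def _validate(self) -> None:
        n = len(self.state_names)
        if n == 0:
            raise SchemeError("scheme must contain at least one state")
        if len(set(self.state_names)) != n:
            raise SchemeError(f"duplicate state names in {self.state_names}")
        if len(self.fret_level) != n or len(self.pife_level) != n:
            raise SchemeError("fret_level and pife_level must have one entry per state")
        if self.rates.shape != (n, n):
            raise SchemeError(
                f"rate matrix shape {self.rates.shape} does not match {n} states"
            )
        if np.any(np.diag(self.rates) != 0.0):
            raise SchemeError("rate matrix diagonal must be zero (no self-transitions)")
        if np.any(self.rates < 0.0):
            raise SchemeError("transition rates must be nonnegative")
        for x in self.fret_level:
            if not 0.0 <= x <= 1.0:
                raise SchemeError(f"FRET level {x} outside [0, 1]")
        for x in self.pife_level:
            if x < 0.0:
                raise SchemeError(f"PIFE level {x} must be nonnegative")
        if self.initial_state not in self.state_names:
            raise SchemeError(
                f"initial state {self.initial_state!r} not among {self.state_names}"
            )
        if UNBOUND in self.state_names:
            i = self.state_names.index(UNBOUND)
            if self.fret_level[i] != 0.0 or self.pife_level[i] != 1.0:
                raise SchemeError(
                    "the unbound state must have FRET 0 and PIFE 1.0 "
                    f"(got FRET {self.fret_level[i]}, PIFE {self.pife_level[i]})"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, label: str) -> int:
        try:
            return self.state_names.index(label)
        except ValueError:
            raise SchemeError(
                f"unknown state {label!r}; states are {self.state_names}"
            ) from None

    def rate(self, src: str, dst: str) -> float:
        return float(self.rates[self.index(src), self.index(dst)])

    def exit_rate(self, label: str) -> float:
        """Total rate of leaving ``label`` (sum of its outgoing rates)."""
        return float(self.rates[self.index(label)].sum())

    def with_rate(self, src: str, dst: str, value: float) -> "KineticScheme":
        """Return a copy with the ``src -> dst`` rate set to ``value``."""
        if src == dst:
            raise SchemeError("cannot set a self-transition rate")
        rates = np.array(self.rates)
        rates[self.index(src), self.index(dst)] = float(value)
        return replace(self, rates=rates)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "state_names": list(self.state_names),
            "fret_level": list(self.fret_level),
            "pife_level": list(self.pife_level),
            "rates": [[float(x) for x in row] for row in self.rates],
            "initial_state": self.initial_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            state_names=tuple(d["state_names"]),
            fret_level=tuple(d["fret_level"]),
            pife_level=tuple(d["pife_level"]),
            rates=np.array(d["rates"], dtype=float),
            initial_state=d.get("initial_state", UNBOUND),
            name=d.get("name"),
        )

    def to_yaml(self) -> str:
        """Serialize to YAML; floats round-trip exactly via repr."""
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "KineticScheme":
        return cls.from_dict(yaml.safe_load(text))

    def __eq__(self, other) -> bool:  # ndarray field needs explicit handling
        if not isinstance(other, KineticScheme):
            return NotImplemented
        return (
            self.state_names == other.state_names
            and self.fret_level == other.fret_level
            and self.pife_level == other.pife_level
            and self.initial_state == other.initial_state
            and np.array_equal(self.rates, other.rates)
        )


class Segment(NamedTuple):
    """One constant-state stretch of a trajectory, in seconds."""

    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StatePath:
    """Ground-truth piecewise-constant state trajectory.

    Segments are contiguous, start at 0 and end at ``total_duration``; the
    final segment is right-censored by the observation window.
    """

    segments: tuple[Segment, ...]
    total_duration: float

    def __post_init__(self) -> None:
        segs = tuple(Segment(*s) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("a state path needs at least one segment")
        if segs[0].start != 0.0:
            raise ValueError("first segment must start at t = 0")
        if segs[-1].end != self.total_duration:
            raise ValueError("last segment must end at total_duration")
        for a, b in zip(segs, segs[1:]):
            if a.end != b.start:
                raise ValueError("segments must be contiguous")
        for s in segs:
            if s.duration <= 0:
                raise ValueError(f"segment {s} has nonpositive duration")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def state_sequence(self) -> list[str]:
        return [s.state for s in self.segments]

    def time_in(self, label: str) -> float:
        return sum(s.duration for s in self.segments if s.state == label)

    def labeled_segments(self) -> list[tuple[str, float]]:
        """Ordered (state, duration-in-seconds) pairs; shared interface with
        idealized paths so pause measurements run on either."""
        return [(s.state, s.duration) for s in self.segments]


@dataclass(frozen=True)
class RateEstimate:
    """A first-order rate constant with its standard error."""

    value: float
    stderr: float
    n_events: int

    def __post_init__(self) -> None:
        if self.n_events > 0 and not self.value > 0:
            raise ValueError("rate must be positive when events were observed")
        if self.stderr < 0:
            raise ValueError("stderr must be nonnegative")


def simulate_path(scheme: KineticScheme, duration: float, seed) -> StatePath:
    """Draw one exact Gillespie realization of ``scheme``.

    Dwell times in state i are exponential with rate equal to the sum of
    the outgoing rates; the jump destination is chosen with probability
    proportional to the individual rates. The trajectory is truncated at
    ``duration`` (the final segment is censored by the window). An
    absorbing state simply persists to the end of the window.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``; the event
    sequence is bitwise reproducible for a fixed seed and scheme.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(seed)
    rates = scheme.rates
    n = scheme.n_states
    # Per-state cumulative outgoing rates for fast destination sampling.
    cumrates = np.cumsum(rates, axis=1)
    totals = cumrates[:, -1]

    i = scheme.index(scheme.initial_state)
    t = 0.0
    segments: list[Segment] = []
    while t < duration:
        total = totals[i]
        if total == 0.0:  # absorbing: occupy the remainder of the window
            segments.append(Segment(scheme.state_names[i], t, duration))
            break
        dwell = rng.exponential(1.0 / total)
        end = t + dwell
        if end >= duration:
            segments.append(Segment(scheme.state_names[i], t, duration))
            break
        segments.append(Segment(scheme.state_names[i], t, end))
        j = int(np.searchsorted(cumrates[i], rng.random() * total, side="right"))
        j = min(j, n - 1)
        t = end
        i = j
    return StatePath(tuple(segments), duration)


# ---------------------------------------------------------------------------
# Preset catalog
# ---------------------------------------------------------------------------

#: Default pseudo-first-order association rate (s^-1). The experiments fix
#: the enzyme concentration but do not report k_on; 0.5 s^-1 yields several
#: binding events per 100 s trace, which is what the dwell-time and pathway
#: statistics need. Override via ``make_preset(..., k_on=...)``.
DEFAULT_K_ON = 0.5

# Per-construct bound states: label -> (FRET, PIFE, exit rate to unbound).
# Dissociation rate constants are the measured single-molecule k_off values;
# for the AAF-modified n+1 construct the intermediate<->exo shuttling rates
# are the HMM-derived k_exo (intermediate -> exo) and k_int (exo ->
# intermediate), and dissociation from the intermediate uses the AAF
# binary-complex k_off.
_PRESETS: dict[str, dict] = {
    "unmodified_templating": {
        "doc": "unmodified primer-template, adduct-free templating base; "
        "pol-site binding (FRET 0.59, PIFE 2.0), k_off 0.40 s^-1",
        "states": {"pol": (0.59, 2.0, 0.40)},
    },
    "af_templating": {
        "doc": "AF-dG on the templating base; pol-site binding unchanged "
        "(FRET 0.59, PIFE 2.0), k_off 0.10 s^-1 (4-fold stabilized)",
        "states": {"pol": (0.59, 2.0, 0.10)},
    },
    "aaf_templating": {
        "doc": "AAF-dG on the templating base; pol-site binding unchanged "
        "(FRET 0.59, PIFE 2.0), k_off 0.07 s^-1",
        "states": {"pol": (0.59, 2.0, 0.07)},
    },
    "unmodified_n1": {
        "doc": "unmodified primer-template extended by one base; pol-site "
        "binding one bp further from the donor (FRET 0.4, PIFE 1.2)",
        "states": {"pol": (0.40, 1.2, 0.40)},
    },
    "af_n1": {
        "doc": "AF-dG across from the primer terminus; intermediate-site "
        "binding only (FRET 0.51, PIFE 1.9), k_off 0.10 s^-1",
        "states": {"intermediate": (0.51, 1.9, 0.10)},
    },
    "aaf_n1": {
        "doc": "AAF-dG across from the primer terminus; intermediate "
        "(FRET 0.50) and exo (FRET 0.63) sites, PIFE 1.9, shuttling "
        "2.1 / 4.3 s^-1, intermediate k_off 0.07 s^-1",
        "states": {
            "intermediate": (0.50, 1.9, 0.07),
            "exo": (0.63, 1.9, 0.0),
        },
        "extra_rates": {("intermediate", "exo"): 2.1, ("exo", "intermediate"): 4.3},
    },
    "double_mismatch": {
        "doc": "two terminal mismatches; near-exclusive exo-site binding "
        "(FRET 0.60, PIFE 1.8)",
        "states": {"exo": (0.60, 1.8, 0.40)},
    },
    "single_mismatch": {
        "doc": "single terminal mismatch; intermediate-site binding "
        "(FRET 0.50, PIFE 1.9)",
        "states": {"intermediate": (0.50, 1.9, 0.40)},
    },
    "af_ternary": {
        "doc": "AF-dG n+1 construct with the next correct dNTP; pol-site "
        "binding restored (FRET 0.4, PIFE 1.2), k_off 2.5 s^-1",
        "states": {"pol": (0.40, 1.2, 2.5)},
    },
}


def preset_catalog() -> dict[str, str]:
    """Mapping of preset name -> one-line description."""
    return {name: info["doc"] for name, info in _PRESETS.items()}


def make_preset(
    name: str,
    k_on: float = DEFAULT_K_ON,
    hidden_exo_exchange: bool = False,
) -> KineticScheme:
    """Build the kinetic scheme for a characterized primer-template construct.

    Parameters
    ----------
    name
        One of :func:`preset_catalog`.
    k_on
        Pseudo-first-order association (unbound -> first bound state) rate.
    hidden_exo_exchange
        For ``af_n1`` only: add an exo state that exchanges with the
        intermediate at the AAF-construct shuttling rates but is
        spectroscopically identical to it (the data cannot distinguish a
        pure intermediate from one exchanging with an unresolved exo state;
        both variants are exposed, neither is privileged).
    """
    if name not in _PRESETS:
        known = ", ".join(sorted(_PRESETS))
        raise SchemeError(f"unknown preset {name!r}; available presets: {known}")
    info = _PRESETS[name]
    bound = dict(info["states"])
    if hidden_exo_exchange:
        if name != "af_n1":
            raise SchemeError("hidden_exo_exchange applies to the af_n1 preset only")
        fret, pife, _ = bound["intermediate"]
        bound["exo"] = (fret, pife, 0.0)

    names = [UNBOUND] + list(bound)
    fret = [0.0] + [v[0] for v in bound.values()]
    pife = [1.0] + [v[1] for v in bound.values()]
    n = len(names)
    rates = np.zeros((n, n))
    first_bound = names[1]
    rates[0, names.index(first_bound)] = k_on
    for label, (_, _, koff) in bound.items():
        rates[names.index(label), 0] = koff
    for (src, dst), k in info.get("extra_rates", {}).items():
        rates[names.index(src), names.index(dst)] = k
    if hidden_exo_exchange:
        rates[names.index("intermediate"), names.index("exo")] = 2.1
        rates[names.index("exo"), names.index("intermediate")] = 4.3
    return KineticScheme(
        state_names=tuple(names),
        fret_level=tuple(fret),
        pife_level=tuple(pife),
        rates=rates,
        initial_state=UNBOUND,
        name=name,
    )


def add_direct_dissociation(
    scheme: KineticScheme, direct_fraction: float
) -> KineticScheme:
    """Add an exo -> unbound exit so a target fraction of dissociations is direct.

    The scheme must contain ``unbound``, ``intermediate`` and ``exo`` states
    with the bound-state topology U <- I <-> X. Let

        a = k_IX / (k_IX + k_IU)   (embedded-chain probability I -> X)
        b = k_XU / (k_XU + k_XI)   (embedded-chain probability X -> U)

    A binding event enters at I. The probability p that it eventually
    dissociates from X satisfies the first-step relation

        p = a * (b + (1 - b) * p)        =>   p = a b / (1 - a (1 - b)).

    Setting p = f (the requested direct fraction) and solving for b gives

        b = f (1 - a) / (a (1 - f)),     k_XU = k_XI * b / (1 - b),

    which is valid for 0 < f < a; f = 0 removes the direct exit, and f = 1
    is only reachable by forcing k_IU = 0 (every dissociation then leaves
    from X regardless of k_XU, which is set to the removed k_IU so the
    overall dissociation propensity is preserved).
    """
    if not 0.0 <= direct_fraction <= 1.0:
        raise SchemeError(f"direct_fraction {direct_fraction} outside [0, 1]")
    for label in (UNBOUND, "intermediate", "exo"):
        if label not in scheme.state_names:
            raise SchemeError(f"scheme lacks required state {label!r}")
    k_ix = scheme.rate("intermediate", "exo")
    k_iu = scheme.rate("intermediate", UNBOUND)
    k_xi = scheme.rate("exo", "intermediate")
    if direct_fraction == 0.0:
        return scheme.with_rate("exo", UNBOUND, 0.0)
    if direct_fraction == 1.0:
        if not k_iu > 0:
            raise SchemeError(
                "direct_fraction 1 requires a positive intermediate->unbound "
                "rate to transfer to the exo exit"
            )
        return scheme.with_rate("intermediate", UNBOUND, 0.0).with_rate(
            "exo", UNBOUND, k_iu
        )
    if not k_ix > 0 or not k_xi > 0:
        raise SchemeError("intermediate<->exo shuttling rates must be positive")
    a = k_ix / (k_ix + k_iu)
    if direct_fraction >= a:
        raise SchemeError(
            f"direct_fraction {direct_fraction} unreachable: the embedded "
            f"chain reaches exo with probability {a:.4f} per intermediate "
            "visit, which bounds the direct-dissociation fraction; reduce "
            "the intermediate->unbound rate or request a smaller fraction"
        )
    b = direct_fraction * (1.0 - a) / (a * (1.0 - direct_fraction))
    k_xu = k_xi * b / (1.0 - b)
    return scheme.with_rate("exo", UNBOUND, k_xu)
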