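"""Kinetic schemes, Gillespie realizations and the preset catalog."""

import numpy as np
import pytest
import scipy.stats

import polbind as pb
from polbind.kinetics import SchemeError

from conftest import two_state_scheme


class TestSchemeValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(SchemeError, match="nonnegative"):
            two_state_scheme(-1.0, 0.0)

    def test_fret_outside_unit_interval_rejected(self):
        with pytest.raises(SchemeError, match="FRET"):
            two_state_scheme(1.0, 1.0, fret=(0.0, 1.2))

    def test_unknown_initial_state_rejected(self):
        with pytest.raises(SchemeError, match="initial state"):
            pb.KineticScheme(("A",), (0.1,), (1.0,), np.zeros((1, 1)), initial_state="Z")

    def test_unbound_state_emission_convention_enforced(self):
        with pytest.raises(SchemeError, match="unbound"):
            pb.KineticScheme(
                ("unbound", "pol"), (0.2, 0.5), (1.0, 2.0),
                np.array([[0.0, 0.5], [0.4, 0.0]]),
            )

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(SchemeError, match="diagonal"):
            pb.KineticScheme(("A", "B"), (0.1, 0.2), (1.0, 1.0), np.eye(2))

    def test_yaml_round_trip_exact(self, aaf_scheme):
        clone = pb.KineticScheme.from_yaml(aaf_scheme.to_yaml())
        assert clone == aaf_scheme


class TestSimulatePath:
    def test_absorbing_state_fills_window(self):
        scheme = pb.KineticScheme(("A",), (0.3,), (1.0,), np.zeros((1, 1)), initial_state="A")
        path = pb.simulate_path(scheme, 10.0, seed=0)
        assert path.segments == (pb.Segment("A", 0.0, 10.0),)

    def test_mean_first_dwell_matches_exponential(self):
        # A -> B at 2.0 s^-1: first dwell in A is Exp(2.0), mean 0.5 s
        scheme = two_state_scheme(2.0, 0.0)
        rng = np.random.default_rng(7)
        first = [pb.simulate_path(scheme, 10.0, rng).segments[0].duration
                 for _ in range(10_000)]
        assert np.mean(first) == pytest.approx(0.5, rel=0.02)

    def test_exo_dwell_mean_matches_shuttling_rate(self):
        # intermediate -> exo 2.1, exo -> intermediate 4.3; exo has no other
        # exit so its dwell mean is 1/4.3 s
        scheme = two_state_scheme(2.1, 4.3)
        rng = np.random.default_rng(11)
        dwells = []
        while len(dwells) < 10_000:
            path = pb.simulate_path(scheme, 500.0, rng)
            dwells.extend(
                s.duration for s in path.segments[:-1] if s.state == "B"
            )
        assert np.mean(dwells[:10_000]) == pytest.approx(1 / 4.3, rel=0.03)

    def test_dwell_distribution_is_exponential(self):
        scheme = two_state_scheme(1.5, 3.0)
        rng = np.random.default_rng(3)
        dwells = []
        while len(dwells) < 5_000:
            path = pb.simulate_path(scheme, 400.0, rng)
            dwells.extend(s.duration for s in path.segments[:-1] if s.state == "A")
        stat = scipy.stats.kstest(dwells[:5_000], "expon", args=(0, 1 / 1.5))
        assert stat.pvalue > 0.01

    def test_jump_destinations_match_branching_ratios(self, aaf_scheme):
        # from the intermediate: P(exo) = 2.1/2.17, P(unbound) = 0.07/2.17
        rng = np.random.default_rng(5)
        dest = {"exo": 0, "unbound": 0}
        n = 0
        while n < 5_000:
            path = pb.simulate_path(aaf_scheme, 300.0, rng)
            segs = path.segments
            for a, b in zip(segs, segs[1:]):
                if a.state == "intermediate":
                    dest[b.state] += 1
                    n += 1
        total = sum(dest.values())
        p = 2.1 / 2.17
        sigma = np.sqrt(p * (1 - p) / total)
        assert abs(dest["exo"] / total - p) < 3 * sigma

    def test_path_invariants_and_duration(self, aaf_scheme):
        path = pb.simulate_path(aaf_scheme, 77.3, seed=9)
        assert path.segments[0].start == 0.0
        assert path.segments[-1].end == 77.3
        for a, b in zip(path.segments, path.segments[1:]):
            assert a.end == b.start
        assert sum(s.duration for s in path.segments) == pytest.approx(77.3, abs=1e-9)

    def test_identical_seed_reproduces_path_bitwise(self, aaf_scheme):
        p1 = pb.simulate_path(aaf_scheme, 60.0, seed=123)
        p2 = pb.simulate_path(aaf_scheme, 60.0, seed=123)
        assert p1.segments == p2.segments

    def test_nonpositive_duration_rejected(self, aaf_scheme):
        with pytest.raises(ValueError, match="duration"):
            pb.simulate_path(aaf_scheme, 0.0, seed=0)


class TestPresets:
    @pytest.mark.parametrize(
        "name, state, fret, pife, koff",
        [
            ("unmodified_templating", "pol", 0.59, 2.0, 0.40),
            ("af_templating", "pol", 0.59, 2.0, 0.10),
            ("aaf_templating", "pol", 0.59, 2.0, 0.07),
            ("unmodified_n1", "pol", 0.40, 1.2, 0.40),
            ("af_n1", "intermediate", 0.51, 1.9, 0.10),
            ("double_mismatch", "exo", 0.60, 1.8, 0.40),
            ("af_ternary", "pol", 0.40, 1.2, 2.5),
        ],
    )
    def test_catalog_levels_and_rates(self, name, state, fret, pife, koff):
        scheme = pb.make_preset(name)
        i = scheme.index(state)
        assert scheme.fret_level[i] == fret
        assert scheme.pife_level[i] == pife
        assert scheme.rate(state, "unbound") == koff

    def test_aaf_n1_shuttling_rates(self, aaf_scheme):
        assert aaf_scheme.rate("intermediate", "exo") == 2.1
        assert aaf_scheme.rate("exo", "intermediate") == 4.3
        assert aaf_scheme.fret_level == (0.0, 0.50, 0.63)
        assert aaf_scheme.pife_level == (1.0, 1.9, 1.9)

    def test_unknown_preset_lists_catalog(self):
        with pytest.raises(SchemeError, match="af_ternary"):
            pb.make_preset("nonexistent")

    def test_af_n1_hidden_exo_variant(self):
        scheme = pb.make_preset("af_n1", hidden_exo_exchange=True)
        i, x = scheme.index("intermediate"), scheme.index("exo")
        assert scheme.fret_level[i] == scheme.fret_level[x]
        assert scheme.rate("intermediate", "exo") == 2.1


class TestDirectDissociation:
    def test_zero_fraction_removes_direct_exit(self, aaf_scheme):
        scheme = pb.add_direct_dissociation(aaf_scheme, 0.0)
        assert scheme.rate("exo", "unbound") == 0.0

    def test_full_fraction_forces_intermediate_exit_closed(self, aaf_scheme):
        scheme = pb.add_direct_dissociation(aaf_scheme, 1.0)
        assert scheme.rate("intermediate", "unbound") == 0.0
        assert scheme.rate("exo", "unbound") > 0.0

    def test_fraction_outside_unit_interval_rejected(self, aaf_scheme):
        with pytest.raises(SchemeError):
            pb.add_direct_dissociation(aaf_scheme, 1.5)

    def test_unreachable_fraction_explained(self, aaf_scheme):
        # max achievable fraction is a = 2.1/2.17 ~ 0.968
        with pytest.raises(SchemeError, match="unreachable"):
            pb.add_direct_dissociation(aaf_scheme, 0.99)

    def test_monte_carlo_terminal_exo_fraction(self, aaf_scheme):
        # closed form vs simulation: 60% of dissociations end at the exo site
        scheme = pb.add_direct_dissociation(aaf_scheme, 0.6)
        # isolate single binding events: start at the intermediate, make
        # unbound absorbing
        event = pb.KineticScheme(
            scheme.state_names,
            scheme.fret_level,
            scheme.pife_level,
            np.array(scheme.rates) * np.array([[0.0], [1.0], [1.0]]),
            initial_state="intermediate",
        )
        rng = np.random.default_rng(17)
        from_exo = 0
        for _ in range(10_000):
            path = pb.simulate_path(event, 400.0, rng)
            states = path.state_sequence()
            assert states[-1] == "unbound"
            from_exo += states[-2] == "exo"
        assert from_exo / 10_000 == pytest.approx(0.60, abs=0.02)
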