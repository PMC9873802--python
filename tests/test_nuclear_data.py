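"""Decay-network construction and Bateman evolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ac225rims import ActivityState, build_ac225_chain, evolve, ingrowth_factor
from ac225rims.nuclear_data import NuclearDataError

from conftest import ode_activities

DAY = 86400.0


class TestChainConstruction:
    def test_root_half_life_is_9_92_days(self, chain):
        assert chain.root.name == "Ac-225"
        assert chain.root.half_life_s == pytest.approx(9.92 * DAY)

    def test_branching_fractions_sum_to_one(self, chain):
        for nuc in chain:
            if not nuc.stable:
                assert sum(m.fraction for m in nuc.decay_modes) == pytest.approx(1.0, abs=1e-9)

    def test_all_nuclides_reachable_from_root(self, chain):
        for name in chain.names:
            assert chain.is_reachable("Ac-225", name)

    def test_terminal_is_stable_bi209(self, chain):
        assert chain["Bi-209"].stable
        assert not chain["Bi-209"].decay_modes

    def test_expected_gamma_lines_present(self, chain):
        def has_line(nuclide, kev):
            return any(abs(g.energy_kev - kev) < 1.0 for g in chain[nuclide].gamma_lines)

        assert has_line("Bi-213", 440.0)
        assert has_line("Fr-221", 218.0)
        assert has_line("Tl-209", 465.0)
        assert has_line("Tl-209", 1567.0)

    def test_malformed_table_names_nuclide(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text(
            '{"nuclides": [{"name": "Xx-999", "modes": [], "gammas": []}]}'
        )
        with pytest.raises(NuclearDataError, match="Xx-999"):
            build_ac225_chain(bad)


class TestEvolve:
    def test_dt_zero_is_identity(self, chain):
        s0 = ActivityState.pure(chain, "Ac-225", activity_bq=1e6)
        s1 = evolve(s0, 0.0, chain)
        assert s1.atoms == s0.atoms

    def test_negative_dt_rejected(self, chain):
        s0 = ActivityState.pure(chain, "Ac-225", activity_bq=1e6)
        with pytest.raises(ValueError):
            evolve(s0, -1.0, chain)

    def test_one_half_life_halves_root_activity(self, chain):
        s0 = ActivityState.pure(chain, "Ac-225", activity_bq=1e6)
        s1 = evolve(s0, chain.root.half_life_s, chain)
        assert s1.activity("Ac-225") == pytest.approx(5e5, rel=1e-12)

    def test_transient_equilibrium_fr_to_ac_ratio(self, chain):
        """After 24 h the ²²¹Fr/²²⁵Ac activity ratio is λ_Fr/(λ_Fr−λ_Ac)."""
        s = evolve(ActivityState.pure(chain, "Ac-225", activity_bq=1e6), DAY, chain)
        lam_fr, lam_ac = chain["Fr-221"].lam, chain["Ac-225"].lam
        ratio = s.activity("Fr-221") / s.activity("Ac-225")
        assert ratio == pytest.approx(lam_fr / (lam_fr - lam_ac), rel=1e-9)

    def test_additivity_of_time_steps(self, chain):
        s0 = ActivityState.pure(chain, "Ac-225", activity_bq=1e6)
        a = evolve(evolve(s0, 3 * 3600.0, chain), 21 * 3600.0, chain)
        b = evolve(s0, DAY, chain)
        for name in chain.names:
            assert a.atoms[name] == pytest.approx(b.atoms[name], rel=5e-9, abs=1e-16)

    def test_atom_conservation(self, chain):
        s0 = ActivityState.pure(chain, "Ac-225", atoms=1e12)
        for dt in (3600.0, DAY, 30 * DAY):
            s = evolve(s0, dt, chain)
            assert s.total_atoms() == pytest.approx(1e12, rel=1e-9)

    def test_po213_in_equilibrium_with_feeder(self, chain):
        s = evolve(ActivityState.pure(chain, "Ac-225", activity_bq=1e6), DAY, chain)
        beta = next(
            m.fraction for m in chain["Bi-213"].decay_modes if m.daughter == "Po-213"
        )
        assert s.activity("Po-213") == pytest.approx(
            beta * s.activity("Bi-213"), rel=1e-9
        )

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        fractions=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=8, max_size=8
        ),
        days=st.floats(0.01, 30.0, allow_nan=False),
    )
    def test_bateman_matches_ode_oracle(self, fractions, days):
        """Analytic evolution vs stiff ODE integration of the rate equations:
        < 1e-6 relative on every non-negligible activity, 0–30 d, random
        initial compositions."""
        chain = build_ac225_chain()
        if sum(fractions) == 0:
            fractions = [1.0] * 8
        atoms0 = {
            name: 1e12 * f / sum(fractions)
            for name, f in zip(chain.names, fractions)
        }
        state = ActivityState(0.0, dict(atoms0), chain)
        got = evolve(state, days * DAY, chain)
        expected = ode_activities(chain, atoms0, days * DAY)
        scale = max(chain[n].lam * a for n, a in atoms0.items())
        for name in chain.names:
            if chain.is_fast(name) or chain[name].stable:
                continue  # fast nuclides follow the equilibrium convention
            # below ~1e-6 of the dominant activity the comparison probes the
            # oracle's own integration error, not the analytic solution
            if expected[name] > 1e-6 * scale:
                assert got.activity(name) == pytest.approx(
                    expected[name], rel=1e-6
                ), name

    def test_daughter_ingrowth_monotone_before_equilibrium(self, chain):
        """From pure parent, each daughter's activity is non-decreasing while
        it grows toward equilibrium."""
        s0 = ActivityState.pure(chain, "Ac-225", activity_bq=1e6)
        for name in ("Fr-221", "Bi-213", "Tl-209", "Pb-209"):
            # growth phase: a few half-lives of the slowest feeder below it
            window = 3 * max(
                chain[n].half_life_s for n in chain.names
                if not chain[n].stable and not chain.is_fast(n)
                and chain.is_reachable(n, name) and n != "Ac-225"
            ) if name != "Fr-221" else 3 * chain["Fr-221"].half_life_s
            times = np.linspace(0.0, window, 20)
            acts = [evolve(s0, t, chain).activity(name) for t in times]
            assert all(b >= a * (1 - 1e-12) for a, b in zip(acts, acts[1:]))


class TestIngrowthFactor:
    def test_identity(self, chain):
        assert ingrowth_factor("Ac-225", "Ac-225", 12345.6, chain) == 1.0

    def test_zero_dt_no_ingrowth(self, chain):
        assert ingrowth_factor("Ac-225", "Bi-213", 0.0, chain) == 0.0

    def test_unreachable_pair_rejected(self, chain):
        with pytest.raises(NuclearDataError):
            ingrowth_factor("Bi-213", "Fr-221", 3600.0, chain)

    def test_tl209_factor_matches_ode_oracle(self, chain):
        """²²⁵Ac→²⁰⁹Tl at 24 h against the stiff ODE integration; the naive
        branch × λ_Tl/(λ_Tl−λ_Ac) expression is only good to ~0.5% because it
        drops the intermediate equilibrium factors."""
        got = ingrowth_factor("Ac-225", "Tl-209", DAY, chain)
        atoms = 1e12
        expected = ode_activities(chain, {"Ac-225": atoms}, DAY)
        assert got == pytest.approx(expected["Tl-209"] / expected["Ac-225"], rel=1e-6)

        beta_alpha = next(
            m.fraction for m in chain["Bi-213"].decay_modes if m.daughter == "Tl-209"
        )
        lam_tl, lam_ac = chain["Tl-209"].lam, chain["Ac-225"].lam
        naive = beta_alpha * lam_tl / (lam_tl - lam_ac)
        assert got == pytest.approx(naive, rel=5e-3)

    def test_long_dt_approaches_cumulative_branch(self, chain):
        got = ingrowth_factor("Ac-225", "Tl-209", 2 * DAY, chain)
        assert got == pytest.approx(chain.cumulative_branch("Ac-225", "Tl-209"), rel=5e-3)
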