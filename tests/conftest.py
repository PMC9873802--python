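import numpy as np
import pytest

from ac225rims import CampaignTruth, build_ac225_chain


@pytest.fixture(scope="session")
def chain():
    return build_ac225_chain()


@pytest.fixture(scope="session")
def truth():
    """Default synthetic campaign: the study-conditions regime."""
    return CampaignTruth()


def ode_activities(chain, atoms0: dict, dt: float) -> dict:
    """Independent oracle: stiff integration of the rate equations, built
    directly from the chain's constants (no package evolution code).

    Sub-millisecond nuclides (²¹³Po) are kept in instantaneous equilibrium
    with their feeder — the same convention the package states — otherwise
    the µs/day stiffness ratio makes tight-tolerance integration infeasible.
    Their initial atoms are handed to their daughters.
    """
    from scipy.integrate import solve_ivp

    fast = {n for n in chain.names if not chain[n].stable and chain[n].half_life_s < 1e-3}
    slow = [n for n in chain.names if n not in fast]
    idx = {n: i for i, n in enumerate(slow)}
    lam = np.array([chain[n].lam for n in slow])

    def terminal(name, frac):
        # (fraction, slow daughter) pairs reached through fast nuclides
        if name not in fast:
            return [(frac, name)]
        out = []
        for mode in chain[name].decay_modes:
            out += terminal(mode.daughter, frac * mode.fraction)
        return out

    mat = np.diag(-lam)
    for name in slow:
        for mode in chain[name].decay_modes:
            for f, dau in terminal(mode.daughter, mode.fraction):
                mat[idx[dau], idx[name]] += f * chain[name].lam

    y0 = np.zeros(len(slow))
    for name, n0 in atoms0.items():
        if name in fast:
            for f, dau in terminal(name, 1.0):
                y0[idx[dau]] += f * n0
        else:
            y0[idx[name]] += n0

    sol = solve_ivp(
        lambda t, y: mat @ y, (0.0, dt), y0, method="Radau",
        rtol=1e-11, atol=1e-14 * max(y0.sum(), 1.0), jac=lambda t, y: mat,
    )
    assert sol.success
    acts = {n: lam[idx[n]] * sol.y[idx[n], -1] for n in slow}
    for name in fast:
        feed = sum(
            acts.get(p.name, 0.0) * m.fraction
            for p in chain for m in p.decay_modes if m.daughter == name
        )
        acts[name] = feed
    return acts
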