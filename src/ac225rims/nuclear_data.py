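"""Decay network of the ²²⁵Ac alpha cascade and its time evolution.

The chain ²²⁵Ac → ²²¹Fr → ²¹⁷At → ²¹³Bi → {²¹³Po, ²⁰⁹Tl} → ²⁰⁹Pb → ²⁰⁹Bi
is the physics kernel of every stage of the collection analysis: spectroscopy
converts daughter count rates into activities, and the end-of-collection
back-extrapolation propagates those activities through this network.

Evolution uses the analytic Bateman solution summed over branch paths of the
directed acyclic decay graph.  Nuclides with half-lives far below the sampling
scale (²¹³Po, 3.7 µs) are treated in instantaneous equilibrium with their
feeder, which keeps the analytic path both exact and well conditioned; a
stiff ODE fallback covers the (never-occurring in the bundled chain) case of
near-degenerate decay constants, where the Bateman denominators cancel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "LN2",
    "DecayMode",
    "GammaLine",
    "Nuclide",
    "DecayChain",
    "ActivityState",
    "NuclearDataError",
    "build_ac225_chain",
    "evolve",
    "ingrowth_factor",
]

LN2 = math.log(2.0)

#: nuclides with half-life below this are evolved in instantaneous
#: (secular) equilibrium with their feeder rather than as ODE states
QSSA_HALF_LIFE_S = 1e-3

#: relative λ separation below which the analytic path formula is abandoned
#: for the stiff ODE route (catastrophic cancellation in the denominators)
DEGENERATE_REL_TOL = 1e-10


class NuclearDataError(ValueError):
    """Malformed nuclear-data table or inconsistent decay network."""


@dataclass(frozen=True)
class DecayMode:
    mode: str
    fraction: float
    daughter: str


@dataclass(frozen=True)
class GammaLine:
    energy_kev: float
    intensity: float


@dataclass(frozen=True)
class Nuclide:
    """One member of a decay network.

    ``half_life_s`` is ``None`` for a stable nuclide; ``lam`` is the decay
    constant ln2/t½ in 1/s (zero when stable).
    """

    name: str
    half_life_s: float | None
    decay_modes: tuple[DecayMode, ...] = ()
    gamma_lines: tuple[GammaLine, ...] = ()

    def __post_init__(self) -> None:
        if self.half_life_s is not None and not self.half_life_s > 0:
            raise NuclearDataError(f"{self.name}: half-life must be > 0")
        if self.stable and self.decay_modes:
            raise NuclearDataError(f"{self.name}: stable nuclide with decay modes")
        if not self.stable:
            total = sum(m.fraction for m in self.decay_modes)
            if abs(total - 1.0) > 1e-9:
                raise NuclearDataError(
                    f"{self.name}: branching fractions sum to {total!r}, not 1"
                )
            for m in self.decay_modes:
                if not 0.0 <= m.fraction <= 1.0:
                    raise NuclearDataError(f"{self.name}: branching fraction {m.fraction}")
        for g in self.gamma_lines:
            if not 0.0 <= g.intensity <= 1.0:
                raise NuclearDataError(f"{self.name}: gamma intensity {g.intensity}")

    @property
    def stable(self) -> bool:
        return self.half_life_s is None

    @property
    def lam(self) -> float:
        """Decay constant in 1/s (0 for a stable nuclide)."""
        return 0.0 if self.stable else LN2 / self.half_life_s


class DecayChain:
    """A validated, acyclic branching decay network.

    Nuclides are stored in topological order (parents before daughters).
    """

    def __init__(self, nuclides: Iterable[Nuclide]):
        self.nuclides: dict[str, Nuclide] = {}
        for n in nuclides:
            if n.name in self.nuclides:
                raise NuclearDataError(f"duplicate nuclide {n.name}")
            self.nuclides[n.name] = n
        for n in self.nuclides.values():
            for m in n.decay_modes:
                if m.daughter not in self.nuclides:
                    raise NuclearDataError(
                        f"{n.name}: daughter {m.daughter} not in chain"
                    )
        self._order = self._toposort()
        self.nuclides = {name: self.nuclides[name] for name in self._order}

    def _toposort(self) -> list[str]:
        indeg = {name: 0 for name in self.nuclides}
        for n in self.nuclides.values():
            for m in n.decay_modes:
                indeg[m.daughter] += 1
        queue = [name for name, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            name = queue.pop()
            order.append(name)
            for m in self.nuclides[name].decay_modes:
                indeg[m.daughter] -= 1
                if indeg[m.daughter] == 0:
                    queue.append(m.daughter)
        if len(order) != len(self.nuclides):
            raise NuclearDataError("decay graph contains a cycle")
        return order

    def __getitem__(self, name: str) -> Nuclide:
        try:
            return self.nuclides[name]
        except KeyError:
            raise NuclearDataError(f"nuclide {name!r} not in chain") from None

    def __contains__(self, name: str) -> bool:
        return name in self.nuclides

    def __iter__(self):
        return iter(self.nuclides.values())

    @property
    def names(self) -> list[str]:
        return list(self._order)

    @property
    def root(self) -> Nuclide:
        """The unique nuclide not fed by any other (raises if not unique)."""
        fed = {m.daughter for n in self for m in n.decay_modes}
        roots = [n for n in self if n.name not in fed]
        if len(roots) != 1:
            raise NuclearDataError(f"chain has {len(roots)} roots, expected 1")
        return roots[0]

    def parents_of(self, name: str) -> list[tuple[Nuclide, DecayMode]]:
        return [
            (n, m) for n in self for m in n.decay_modes if m.daughter == name
        ]

    def paths(self, parent: str, descendant: str) -> list[list[tuple[str, float]]]:
        """All simple decay paths parent→descendant in the *reduced* graph.

        Each path is a list of (nuclide name, branch fraction into the next
        node); the last entry has fraction 1.0.  Fast (QSSA) nuclides are
        bypassed, their branch fractions folded into the feeding edge.
        """
        edges = self._reduced_edges()
        out: list[list[tuple[str, float]]] = []

        def dfs(node: str, acc: list[tuple[str, float]]):
            if node == descendant:
                out.append(acc + [(node, 1.0)])
                return
            for frac, dau in edges.get(node, ()):
                dfs(dau, acc + [(node, frac)])

        dfs(parent, [])
        return out

    def is_reachable(self, parent: str, descendant: str) -> bool:
        if parent == descendant:
            return True
        seen = set()
        stack = [parent]
        while stack:
            node = stack.pop()
            for m in self[node].decay_modes:
                if m.daughter not in seen:
                    seen.add(m.daughter)
                    stack.append(m.daughter)
        return descendant in seen

    # -- QSSA bookkeeping -------------------------------------------------

    def is_fast(self, name: str) -> bool:
        n = self[name]
        return (not n.stable) and n.half_life_s < QSSA_HALF_LIFE_S

    def slow_names(self) -> list[str]:
        return [name for name in self._order if not self.is_fast(name)]

    def _fast_fanout(self, name: str) -> list[tuple[float, str]]:
        """Terminal (fraction, slow daughter) pairs reached through fast nuclides."""
        stack = [(1.0, name)]
        result: list[tuple[float, str]] = []
        first = True
        while stack:
            frac, node = stack.pop()
            if not first and not self.is_fast(node):
                result.append((frac, node))
                continue
            first = False
            for m in self[node].decay_modes:
                stack.append((frac * m.fraction, m.daughter))
        return result

    def _reduced_edges(self) -> dict[str, list[tuple[float, str]]]:
        """Slow-graph adjacency: fast intermediates folded into edge fractions."""
        edges: dict[str, list[tuple[float, str]]] = {}
        for name in self.slow_names():
            acc: dict[str, float] = {}
            for m in self[name].decay_modes:
                if self.is_fast(m.daughter):
                    for f2, dau in self._fast_fanout(m.daughter):
                        acc[dau] = acc.get(dau, 0.0) + m.fraction * f2
                else:
                    acc[m.daughter] = acc.get(m.daughter, 0.0) + m.fraction
            if acc:
                edges[name] = [(f, d) for d, f in acc.items()]
        return edges

    def cumulative_branch(self, parent: str, descendant: str) -> float:
        """Total branch probability that a decaying *parent* atom eventually
        passes through *descendant* (1.0 for parent itself)."""
        if parent == descendant:
            return 1.0
        total = 0.0
        stack = [(1.0, parent)]
        while stack:
            frac, node = stack.pop()
            for m in self[node].decay_modes:
                f = frac * m.fraction
                if m.daughter == descendant:
                    total += f
                else:
                    stack.append((f, m.daughter))
        return total


@dataclass
class ActivityState:
    """Atom inventory of the chain at one instant.

    ``timestamp`` is seconds on an arbitrary absolute axis; ``atoms`` maps
    nuclide name → atom count.  Activity of a nuclide is λ·N.
    """

    timestamp: float
    atoms: dict[str, float]
    chain: DecayChain

    def activity(self, name: str) -> float:
        """Activity in Bq of one nuclide (λ·N; 0 for a stable nuclide)."""
        return self.chain[name].lam * self.atoms.get(name, 0.0)

    def total_atoms(self) -> float:
        return float(sum(self.atoms.values()))

    @classmethod
    def pure(
        cls, chain: DecayChain, name: str, *, activity_bq: float | None = None,
        atoms: float | None = None, timestamp: float = 0.0,
    ) -> "ActivityState":
        """State holding a single nuclide, sized by activity or atom count."""
        nuc = chain[name]
        if (activity_bq is None) == (atoms is None):
            raise ValueError("give exactly one of activity_bq or atoms")
        if atoms is None:
            if nuc.stable:
                raise ValueError(f"{name} is stable; size it by atoms")
            atoms = activity_bq / nuc.lam
        inventory = {n: 0.0 for n in chain.names}
        inventory[name] = float(atoms)
        return cls(timestamp, inventory, chain)

    @classmethod
    def equilibrium(
        cls, chain: DecayChain, parent: str, activity_bq: float,
        timestamp: float = 0.0,
    ) -> "ActivityState":
        """Parent plus daughters in secular equilibrium.

        Each unstable descendant d carries activity A_parent × (cumulative
        branch fraction to d); valid because every daughter in this chain is
        much shorter-lived than ²²⁵Ac.  The stable terminus starts at zero.
        """
        inventory = {n: 0.0 for n in chain.names}
        for name in chain.names:
            nuc = chain[name]
            if nuc.stable:
                continue
            if not chain.is_reachable(parent, name):
                continue
            a = activity_bq * chain.cumulative_branch(parent, name)
            inventory[name] = a / nuc.lam
        return cls(timestamp, inventory, chain)


def build_ac225_chain(path=None) -> DecayChain:
    """Load the bundled ²²⁵Ac → ²⁰⁹Bi network (or a table at *path*).

    The table is configuration, not code: one JSON record per nuclide with
    half-life in seconds, decay modes with branch fractions, and the gamma
    lines used by the analysis (²¹³Bi 440 keV, ²²¹Fr 218 keV, ²⁰⁹Tl 465 and
    1567 keV).
    """
    if path is None:
        text = resources.files("ac225rims").joinpath("data/ac225_chain.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = json.loads(text)
    nuclides = []
    for rec in table["nuclides"]:
        name = rec.get("name", "<unnamed>")
        try:
            nuclides.append(
                Nuclide(
                    name=rec["name"],
                    half_life_s=rec["half_life_s"],
                    decay_modes=tuple(
                        DecayMode(m["mode"], m["fraction"], m["daughter"])
                        for m in rec.get("modes", ())
                    ),
                    gamma_lines=tuple(
                        GammaLine(g["keV"], g["intensity"])
                        for g in rec.get("gammas", ())
                    ),
                )
            )
        except (KeyError, TypeError) as exc:
            raise NuclearDataError(f"malformed record for nuclide {name}: {exc}") from exc
    return DecayChain(nuclides)


# ---------------------------------------------------------------------------
# evolution


def _bateman_path(n0: float, lams: list[float], fracs: list[float], t: float) -> float:
    """Atoms in the last node of a linear path after time t, starting from n0
    atoms in the first node.  λ values must be pairwise distinct (the terminal
    may be stable, λ=0)."""
    if len(lams) == 1:
        return n0 * math.exp(-lams[0] * t)
    coeff = n0
    for lam, frac in zip(lams[:-1], fracs[:-1]):
        coeff *= lam * frac
    total = 0.0
    for j, lj in enumerate(lams):
        denom = 1.0
        for k, lk in enumerate(lams):
            if k != j:
                denom *= lk - lj
        total += math.exp(-lj * t) / denom
    return coeff * total


def _lams_degenerate(lams: Iterable[float]) -> bool:
    ls = sorted(l for l in lams if l > 0)
    for a, b in zip(ls, ls[1:]):
        if b - a < DEGENERATE_REL_TOL * b:
            return True
    return False


def _evolve_ode(state: ActivityState, dt: float, chain: DecayChain) -> ActivityState:
    """Stiff-safe fallback: integrate the full rate equations with Radau."""
    from scipy.integrate import solve_ivp

    names = chain.names
    idx = {n: i for i, n in enumerate(names)}
    lam = np.array([chain[n].lam for n in names])
    A = np.diag(-lam)
    for n in chain:
        for m in n.decay_modes:
            A[idx[m.daughter], idx[n.name]] += m.fraction * n.lam

    y0 = np.array([state.atoms.get(n, 0.0) for n in names])
    sol = solve_ivp(
        lambda t, y: A @ y, (0.0, dt), y0, method="Radau",
        rtol=1e-10, atol=1e-12 * max(y0.sum(), 1.0),
        jac=lambda t, y: A,
    )
    if not sol.success:
        raise RuntimeError(f"stiff decay integration failed: {sol.message}")
    y = np.clip(sol.y[:, -1], 0.0, None)
    return ActivityState(state.timestamp + dt, dict(zip(names, y)), chain)


def evolve(state: ActivityState, dt: float, chain: DecayChain | None = None) -> ActivityState:
    """Advance an atom inventory by ``dt`` seconds.

    Analytic Bateman branch-path solution on the reduced (slow) graph; fast
    nuclides are re-equilibrated against their feeders afterwards.  Advancing
    by dt then dt' equals advancing by dt+dt' to numerical precision, and
    total atoms (stable terminus included) are conserved.
    """
    chain = chain if chain is not None else state.chain
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if dt == 0:
        return ActivityState(state.timestamp, dict(state.atoms), chain)

    slow = chain.slow_names()
    if _lams_degenerate(chain[n].lam for n in slow):
        return _evolve_ode(state, dt, chain)

    # initial inventory on the slow graph; fast atoms decay within any dt>0
    init: dict[str, float] = {n: state.atoms.get(n, 0.0) for n in slow}
    for name in chain.names:
        n0 = state.atoms.get(name, 0.0)
        if chain.is_fast(name) and n0 > 0:
            for frac, dau in chain._fast_fanout(name):
                init[dau] += frac * n0

    out = {n: 0.0 for n in chain.names}
    for src in slow:
        n0 = init[src]
        if n0 == 0.0:
            continue
        out[src] += n0 * math.exp(-chain[src].lam * dt)
        for dst in slow:
            if dst == src:
                continue
            for path in chain.paths(src, dst):
                lams = [chain[name].lam for name, _ in path]
                fracs = [f for _, f in path]
                out[dst] += _bateman_path(n0, lams, fracs, dt)

    # fast nuclides: instantaneous equilibrium with their feeders
    for name in chain.names:
        if chain.is_fast(name):
            feed = sum(
                chain[p.name].lam * out[p.name] * m.fraction
                for p, m in chain.parents_of(name)
            )
            out[name] = feed / chain[name].lam

    return ActivityState(state.timestamp + dt, out, chain)


def ingrowth_factor(
    parent: str | Nuclide, descendant: str | Nuclide, dt: float,
    chain: DecayChain,
) -> float:
    """Descendant activity per unit *contemporaneous* parent activity, after
    evolving a pure-parent inventory for ``dt`` seconds.

    Approaches the secular-equilibrium value (the cumulative branch fraction,
    to first order in λ_parent/λ_daughter) once dt exceeds every intermediate
    half-life.
    """
    pname = parent if isinstance(parent, str) else parent.name
    dname = descendant if isinstance(descendant, str) else descendant.name
    if not chain.is_reachable(pname, dname):
        raise NuclearDataError(f"{dname} is not reachable from {pname}")
    if pname == dname:
        return 1.0
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return 0.0
    state = evolve(ActivityState.pure(chain, pname, atoms=1.0), dt, chain)
    a_parent = state.activity(pname)
    if a_parent <= 0.0:
        raise NuclearDataError(f"parent {pname} activity vanished over dt={dt}")
    return state.activity(dname) / a_parent
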