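"""Continuous-time Markov chain simulation of protein binding to single DNA molecules.

Each surface-tethered DNA molecule is modelled as an independent CTMC whose
states record which proteins (clamp loader, beta clamp, polymerases) are
currently DNA-bound.  Dwell times in any state are exponential with mean
1/(total exit rate); association is pseudo-first-order with propensity
``kon_per_conc * conc`` because the solution reservoir is not depleted by
the femtomoles bound at the surface.

States are frozensets of bound-species names.  Names starting with an
underscore are internal stage markers (e.g. the productive/non-productive
branches of clamp unloading) and do not count as occupancy of any species.

Scheme presets mirror the experimental conditions of the study this package
reproduces: clamp loading with ATP or ATPgammaS, clamp unloading from
pre-loaded clamps, Pol IIIcore on clamp-DNA, Pol I on bare DNA, the
tau-complex (clamp loader with tethered Pol IIIcore), and open competition
of several polymerases for the clamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RateSet",
    "Transition",
    "KineticScheme",
    "StateTrajectory",
    "build_scheme",
    "simulate_trajectory",
    "simulate_many",
    "occupancy_runs",
    "expected_coloc_duration",
    "SCHEME_PRESETS",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateSet:
    """Kinetic parameters of one species.

    Parameters
    ----------
    kon_per_conc:
        Association propensity per unit concentration, 1/(nM s).
    koff:
        Dissociation rate, 1/s.  ``1/koff`` is the mean dwell time.
    conc:
        Species concentration in solution, nM.
    """

    kon_per_conc: float = 0.0
    koff: float = 0.0
    conc: float = 0.0

    def __post_init__(self) -> None:
        if self.kon_per_conc < 0 or self.koff < 0 or self.conc < 0:
            raise ValueError("rates and concentrations must be >= 0")

    @property
    def arrival_rate(self) -> float:
        """Effective pseudo-first-order arrival propensity, 1/s."""
        return self.kon_per_conc * self.conc

    @staticmethod
    def from_arrival(arrival_rate: float, koff: float, conc: float = 1.0) -> "RateSet":
        """Build a RateSet from a target arrival rate (1/s) at a given conc."""
        if conc <= 0:
            raise ValueError("conc must be > 0")
        return RateSet(kon_per_conc=arrival_rate / conc, koff=koff, conc=conc)


State = frozenset


@dataclass(frozen=True)
class Transition:
    source: State
    target: State
    rate: float
    # e.g. (("arrive", "loader"), ("arrive", "clamp")) for a co-arrival
    tags: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError(f"transition rate must be finite and >= 0, got {self.rate}")


@dataclass(frozen=True)
class KineticScheme:
    """A finite-state binding scheme on one DNA molecule."""

    name: str
    species: tuple[str, ...]
    transitions: tuple[Transition, ...]
    initial_state: State

    def __post_init__(self) -> None:
        states = {self.initial_state}
        for tr in self.transitions:
            states.add(tr.source)
            states.add(tr.target)
        object.__setattr__(self, "_states", frozenset(states))
        # consistency: atomic multi-species transitions must change occupancy
        # of every tagged species
        for tr in self.transitions:
            for verb, sp in tr.tags:
                if sp not in self.species:
                    continue
                if verb == "arrive" and not (sp not in tr.source and sp in tr.target):
                    raise ValueError(f"arrive tag inconsistent with occupancy in {tr}")
                if verb == "depart" and not (sp in tr.source and sp not in tr.target):
                    raise ValueError(f"depart tag inconsistent with occupancy in {tr}")

    @property
    def states(self) -> frozenset:
        return self._states  # type: ignore[attr-defined]

    def transitions_from(self, state: State) -> list[Transition]:
        return [tr for tr in self.transitions if tr.source == state]


@dataclass
class StateTrajectory:
    """Ground-truth occupancy of one DNA molecule over [0, duration].

    ``segments`` is an ordered list of (start_s, end_s, state); segments are
    contiguous, non-overlapping and cover the full duration.
    """

    molecule_id: int
    duration: float
    segments: list[tuple[float, float, State]] = field(default_factory=list)

    def state_at(self, t: float) -> State:
        for t0, t1, s in self.segments:
            if t0 <= t < t1 or (t == self.duration and t1 == self.duration):
                return s
        raise ValueError(f"time {t} outside [0, {self.duration}]")

    def occupancy(self, species: str, times: np.ndarray) -> np.ndarray:
        """Boolean occupancy of `species` sampled at `times` (vectorized)."""
        edges = np.array([seg[0] for seg in self.segments] + [self.duration])
        bound = np.array([species in seg[2] for seg in self.segments] + [False])
        idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(self.segments) - 1)
        return bound[idx] & (times <= self.duration) & (times >= 0)


def occupancy_runs(traj: StateTrajectory, species: str) -> list[tuple[float, float]]:
    """Maximal intervals during which `species` is DNA-bound.

    Consecutive segments where the species stays bound are merged, so a run
    corresponds to one physical binding event (one protein copy, one
    fluorophore).
    """
    runs: list[tuple[float, float]] = []
    for t0, t1, s in traj.segments:
        if species in s:
            if runs and runs[-1][1] == t0:
                runs[-1] = (runs[-1][0], t1)
            else:
                runs.append((t0, t1))
    return runs


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_trajectory(
    scheme: KineticScheme, duration: float, seed: int | np.random.Generator
) -> StateTrajectory:
    """Exact stochastic simulation (Gillespie) of one molecule.

    Dwell in a state with total exit rate lambda is Exp(1/lambda); the next
    transition is chosen with probability proportional to its rate.  A state
    with zero total exit rate is absorbing.  Identical seeds give identical
    trajectories.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # pre-index transitions per state
    table: dict[State, tuple[np.ndarray, list[Transition]]] = {}
    for st in scheme.states:
        trs = scheme.transitions_from(st)
        rates = np.array([tr.rate for tr in trs], dtype=float)
        keep = rates > 0
        table[st] = (rates[keep], [tr for tr, k in zip(trs, keep) if k])

    state = scheme.initial_state
    if not scheme.transitions_from(state) and len(scheme.states) > 1:
        # A start state with no defined exits (as opposed to exits with zero
        # propensity, e.g. a species at zero concentration) is a mis-specified
        # scheme: the molecule could never leave it by construction.
        raise ValueError(
            f"scheme {scheme.name!r}: initial state {set(state)} has no transitions"
        )
    t = 0.0
    segments: list[tuple[float, float, State]] = []
    while t < duration:
        rates, trs = table[state]
        total = rates.sum()
        if total == 0.0:
            segments.append((t, duration, state))
            t = duration
            break
        dt = rng.exponential(1.0 / total)
        t_next = t + dt
        if t_next >= duration:
            segments.append((t, duration, state))
            t = duration
            break
        # categorical draw
        u = rng.random() * total
        i = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        i = min(i, len(trs) - 1)
        segments.append((t, t_next, state))
        state = trs[i].target
        t = t_next
    return StateTrajectory(molecule_id=0, duration=duration, segments=segments)


def simulate_many(
    scheme: KineticScheme, duration: float, n_molecules: int, seed: int
) -> list[StateTrajectory]:
    """Simulate independent molecules with per-molecule child seeds."""
    ss = np.random.SeedSequence(seed)
    trajs = []
    for i, child in enumerate(ss.spawn(n_molecules)):
        traj = simulate_trajectory(scheme, duration, np.random.default_rng(child))
        traj.molecule_id = i
        trajs.append(traj)
    return trajs


def expected_coloc_duration(tau_a: float, tau_b: float) -> float:
    """Mean overlap time of two independently dissociating species.

    From the instant both are bound, each departs memorylessly with rates
    1/tau_a and 1/tau_b, so the overlap ends at rate 1/tau_a + 1/tau_b and
    its mean duration is 1/(1/tau_a + 1/tau_b).
    """
    if tau_a <= 0 or tau_b <= 0:
        raise ValueError("lifetimes must be > 0")
    return 1.0 / (1.0 / tau_a + 1.0 / tau_b)


# ---------------------------------------------------------------------------
# Scheme presets
# ---------------------------------------------------------------------------


def _require(rates: Mapping[str, RateSet], *names: str) -> None:
    missing = [n for n in names if n not in rates]
    if missing:
        raise KeyError(f"missing rates for {missing}")


def _loading_atp(rates: Mapping[str, RateSet], **opt) -> KineticScheme:
    """Loader+clamp co-arrive; loader departs quickly; clamp persists.

    Required rates: 'complex' (arrival of the pre-formed loader-clamp
    complex), 'loader' (koff of the loader on clamp-DNA), 'clamp' (koff of
    the loaded clamp).
    """
    _require(rates, "complex", "loader", "clamp")
    empty: State = frozenset()
    lc: State = frozenset({"loader", "clamp"})
    c: State = frozenset({"clamp"})
    trs = (
        Transition(empty, lc, rates["complex"].arrival_rate,
                   (("arrive", "loader"), ("arrive", "clamp"))),
        Transition(lc, c, rates["loader"].koff, (("depart", "loader"),)),
        Transition(c, empty, rates["clamp"].koff, (("depart", "clamp"),)),
    )
    return KineticScheme("loading_ATP", ("loader", "clamp"), trs, empty)


def _loading_atpgs(rates: Mapping[str, RateSet], **opt) -> KineticScheme:
    """With ATPgammaS the loader-clamp complex arrives and releases as one unit."""
    _require(rates, "complex")
    empty: State = frozenset()
    lc: State = frozenset({"loader", "clamp"})
    trs = (
        Transition(empty, lc, rates["complex"].arrival_rate,
                   (("arrive", "loader"), ("arrive", "clamp"))),
        Transition(lc, empty, rates["complex"].koff,
                   (("depart", "loader"), ("depart", "clamp"))),
    )
    return KineticScheme("loading_ATPgS", ("loader", "clamp"), trs, empty)


def _unloading(rates: Mapping[str, RateSet], *, p_productive: float = 0.47,
               release_lag_mean: float = 4.1, loader_total_mean: float = 10.8,
               nonproductive_mean: float = 2.5, **opt) -> KineticScheme:
    """Loader encounters with a pre-loaded clamp.

    A fraction ``p_productive`` of loader arrivals unload the clamp: the
    clamp is released after an exponential lag (mean ``release_lag_mean``)
    and the loader stays for a second exponential stage so that its total
    dwell has mean ``loader_total_mean``.  The remaining arrivals are
    non-productive: the loader departs (mean ``nonproductive_mean``) and the
    clamp stays.  Once the clamp is unloaded the molecule is empty and, with
    no clamp left in solution, absorbing.

    Required rates: 'loader' (arrival propensity of the loader).
    """
    _require(rates, "loader")
    if not 0.0 <= p_productive <= 1.0:
        raise ValueError("p_productive must be in [0, 1]")
    stage2_mean = loader_total_mean - release_lag_mean
    if stage2_mean <= 0:
        raise ValueError("loader_total_mean must exceed release_lag_mean")
    arr = rates["loader"].arrival_rate
    c: State = frozenset({"clamp"})
    prod: State = frozenset({"clamp", "loader", "_prod"})
    prod2: State = frozenset({"loader", "_prod"})
    nonp: State = frozenset({"clamp", "loader", "_nonprod"})
    empty: State = frozenset()
    trs = (
        Transition(c, prod, p_productive * arr, (("arrive", "loader"),)),
        Transition(c, nonp, (1.0 - p_productive) * arr, (("arrive", "loader"),)),
        Transition(prod, prod2, 1.0 / release_lag_mean, (("depart", "clamp"),)),
        Transition(prod2, empty, 1.0 / stage2_mean, (("depart", "loader"),)),
        Transition(nonp, c, 1.0 / nonproductive_mean, (("depart", "loader"),)),
    )
    return KineticScheme("unloading", ("loader", "clamp"), trs, c)


def _single_species(name: str, species: str, rates: Mapping[str, RateSet],
                    *, start_bound: bool = False) -> KineticScheme:
    _require(rates, species)
    empty: State = frozenset()
    bound: State = frozenset({species})
    trs = (
        Transition(empty, bound, rates[species].arrival_rate, (("arrive", species),)),
        Transition(bound, empty, rates[species].koff, (("depart", species),)),
    )
    return KineticScheme(name, (species,), trs, bound if start_bound else empty)


def _pol3_on_clamp(rates: Mapping[str, RateSet], **opt) -> KineticScheme:
    """Pol IIIcore binding a pre-loaded clamp (clamp held fixed).

    The loaded clamp outlives the acquisition by two orders of magnitude, so
    it is treated as permanently present; only Pol IIIcore cycles on and off.
    """
    return _single_species("pol3_on_clamp", "pol3", rates)


def _pol1_dna(rates: Mapping[str, RateSet], **opt) -> KineticScheme:
    """Pol I (Klenow fragment) binding bare DNA."""
    return _single_species("pol1_dna", "pol1", rates)


def _clamp_alone(rates: Mapping[str, RateSet], **opt) -> KineticScheme:
    """A pre-loaded clamp slowly dissociating; for interval-mode lifetime runs."""
    return _single_species("clamp_alone", "clamp", rates, start_bound=True)


_DEFAULT_EXCLUSIVE = (("pol3", "pol2"), ("pol4", "pol2"))


def _competition(rates: Mapping[str, RateSet], *, species: Sequence[str] = ("pol3", "pol4"),
                 mutual_exclusion: bool = False,
                 exclusive_pairs: Iterable[tuple[str, str]] = _DEFAULT_EXCLUSIVE,
                 coloc_koff_multiplier: float = 1.0,
                 initial: Sequence[str] = (), **opt) -> KineticScheme:
    """Several polymerases competing for a permanently loaded clamp.

    Pol IIIcore and Pol IV may occupy the two clamp grooves simultaneously
    with independent kinetics; Pol II is mutually exclusive with the others.
    ``mutual_exclusion=True`` forbids all co-occupancy.
    ``coloc_koff_multiplier`` scales every koff while two species are
    co-bound (default 1: strict independence).
    """
    species = tuple(species)
    _require(rates, *species)
    excl = {frozenset(p) for p in exclusive_pairs}

    def allowed(s: frozenset) -> bool:
        if mutual_exclusion and len(s) > 1:
            return False
        return not any(frozenset(p) <= s for p in excl)

    states = [frozenset(c) for c in _powerset(species) if allowed(frozenset(c))]
    trs: list[Transition] = []
    for st in states:
        for sp in species:
            if sp not in st:
                tgt = st | {sp}
                if allowed(tgt) and rates[sp].arrival_rate > 0:
                    trs.append(Transition(st, tgt, rates[sp].arrival_rate,
                                          (("arrive", sp),)))
            else:
                koff = rates[sp].koff
                if len(st) > 1:
                    koff *= coloc_koff_multiplier
                if koff > 0:
                    trs.append(Transition(st, st - {sp}, koff, (("depart", sp),)))
    start = frozenset(initial)
    if start and start not in set(states):
        raise ValueError(f"initial occupancy {set(start)} is not an allowed state")
    return KineticScheme("competition", species, tuple(trs), start)


def _tau_complex(rates: Mapping[str, RateSet], **opt) -> KineticScheme:
    """The tau clamp loader complex tethers Pol IIIcore.

    Loader and Pol IIIcore arrive at the clamp together and also leave
    together (they trade places on the clamp-DNA and release as a unit).
    Pol IV competes independently for the second groove.

    Required rates: 'pol3' (arrival/koff of the tau-complex-delivered
    Pol IIIcore, koff default 1/14.8 s) and optionally 'pol4'.
    """
    _require(rates, "pol3")
    has_pol4 = "pol4" in rates and rates["pol4"].arrival_rate > 0
    species = ("loader", "pol3", "pol4") if has_pol4 else ("loader", "pol3")
    trs: list[Transition] = []
    pol4_states = (False, True) if has_pol4 else (False,)
    for p4 in pol4_states:
        base = frozenset({"pol4"}) if p4 else frozenset()
        on = base | {"loader", "pol3"}
        trs.append(Transition(base, on, rates["pol3"].arrival_rate,
                              (("arrive", "loader"), ("arrive", "pol3"))))
        trs.append(Transition(on, base, rates["pol3"].koff,
                              (("depart", "loader"), ("depart", "pol3"))))
    if has_pol4:
        for p3 in (False, True):
            base = frozenset({"loader", "pol3"}) if p3 else frozenset()
            trs.append(Transition(base, base | {"pol4"}, rates["pol4"].arrival_rate,
                                  (("arrive", "pol4"),)))
            trs.append(Transition(base | {"pol4"}, base, rates["pol4"].koff,
                                  (("depart", "pol4"),)))
    return KineticScheme("tau_complex", species, tuple(trs), frozenset())


def _powerset(items: Sequence[str]):
    from itertools import chain, combinations
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


SCHEME_PRESETS = {
    "loading_ATP": _loading_atp,
    "loading_ATPgS": _loading_atpgs,
    "unloading": _unloading,
    "pol3_on_clamp": _pol3_on_clamp,
    "pol1_dna": _pol1_dna,
    "clamp_alone": _clamp_alone,
    "competition": _competition,
    "tau_complex": _tau_complex,
}


def build_scheme(preset: str, rates: Mapping[str, RateSet], **options) -> KineticScheme:
    """Build a named binding scheme from a collection of RateSets.

    Raises KeyError for an unknown preset or a missing rate entry.
    """
    try:
        factory = SCHEME_PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown scheme preset {preset!r}; known: {sorted(SCHEME_PRESETS)}"
        ) from None
    return factory(rates, **options)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def trajectories_to_frame(trajs: Iterable[StateTrajectory]):
    """Long-format table of trajectory segments (one row per segment)."""
    import pandas as pd

    rows = []
    for traj in trajs:
        for t0, t1, s in traj.segments:
            label = "+".join(sorted(x for x in s if not x.startswith("_"))) or "empty"
            rows.append((traj.molecule_id, t0, t1, label))
    return pd.DataFrame(rows, columns=["molecule_id", "t_start", "t_end", "state"])
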