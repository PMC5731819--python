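"""Interval algebra: classification of multi-channel binding events.

Under sequential (interleaved) channel acquisition two proteins that arrive
at the same instant are recorded one frame apart at worst, so "simultaneous"
is operationally defined as start frames within +/-1 frame; the same
tolerance is applied to co-departure.

Event kinds
-----------
loading
    Co-arriving loader + clamp; records the loader dwell, whether the clamp
    persists after loader departure, and whether the pair also co-released
    (the ATPgammaS signature).
unloading (productive / non-productive)
    A loader arriving at a clamp already on the DNA; productive when the
    clamp signal ends during the loader's visit (lag = arrival-to-release),
    non-productive when the loader leaves the clamp behind.
switch / colocalization
    Two polymerase channels merged into time order: adjacent cross-species
    intervals with no overlap are a switch (lag = gap), overlapping ones a
    colocalization (duration = overlap; which species was first in / first
    out is recorded to test arrival/departure independence).
solo
    An interval with no classifiable partner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection import Interval

__all__ = [
    "EventRecord",
    "ExchangeSummary",
    "classify_coarrival",
    "classify_loading",
    "classify_unloading",
    "classify_exchange",
    "estimate_label_efficiency",
    "lag_statistics",
    "group_by_molecule",
]

COARRIVAL_TOLERANCE_FRAMES = 1


@dataclass(frozen=True)
class EventRecord:
    kind: str  # loading | unloading_productive | unloading_nonproductive | switch | colocalization | solo
    molecule_id: int
    participants: tuple[str, ...]
    order: str | None = None       # species that was first (switch: direction "a->b")
    lag: float | None = None       # s; release->arrival (switch), arrival->release (unloading)
    duration: float | None = None  # s; overlap length (colocalization), dwell (loading/solo)
    censored: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "switch" and self.lag is not None and self.lag < 0:
            raise ValueError("switch lag must be >= 0 (overlapping pairs are colocalization)")
        if self.kind == "colocalization" and self.duration is not None and self.duration <= 0:
            raise ValueError("colocalization duration must be > 0")


@dataclass
class ExchangeSummary:
    """Counts, percentages and lag statistics of cross-species pair events."""

    species_a: str
    species_b: str
    n_ab: int = 0        # switches a -> b
    n_ba: int = 0
    n_coloc: int = 0
    n_pairs: int = 0
    lag_ab_mean: float = math.nan
    lag_ab_sem: float = math.nan
    lag_ba_mean: float = math.nan
    lag_ba_sem: float = math.nan
    coloc_duration_mean: float = math.nan
    coloc_duration_sem: float = math.nan
    # 2x2 contingency of colocalization order: rows first-in (a, b),
    # columns first-out (a, b); ties excluded
    first_in_out: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), int))

    @property
    def pct_ab(self) -> float:
        return 100.0 * self.n_ab / self.n_pairs if self.n_pairs else math.nan

    @property
    def pct_ba(self) -> float:
        return 100.0 * self.n_ba / self.n_pairs if self.n_pairs else math.nan

    @property
    def pct_coloc(self) -> float:
        return 100.0 * self.n_coloc / self.n_pairs if self.n_pairs else math.nan

    def to_row(self) -> dict:
        return {
            "pair": f"{self.species_a}/{self.species_b}",
            "n_pairs": self.n_pairs,
            f"pct_{self.species_a}_to_{self.species_b}": self.pct_ab,
            f"pct_{self.species_b}_to_{self.species_a}": self.pct_ba,
            "pct_coloc": self.pct_coloc,
            "lag_ab_s": self.lag_ab_mean,
            "lag_ab_sem_s": self.lag_ab_sem,
            "coloc_s": self.coloc_duration_mean,
            "coloc_sem_s": self.coloc_duration_sem,
        }


def group_by_molecule(intervals: Sequence[Interval]) -> dict[int, list[Interval]]:
    out: dict[int, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.molecule_id, []).append(iv)
    return out


def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    if len(values) == 0:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    sem = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else math.nan
    return float(arr.mean()), float(sem)


# ---------------------------------------------------------------------------
# Pairwise co-arrival
# ---------------------------------------------------------------------------


def classify_coarrival(interval_a: Interval, interval_b: Interval,
                       tolerance_frames: int = COARRIVAL_TOLERANCE_FRAMES) -> bool:
    """True if the two intervals (different channels, same molecule) started
    simultaneously up to the channel-interleave tolerance."""
    if interval_a.channel == interval_b.channel:
        raise ValueError("co-arrival is defined between different channels")
    return abs(interval_a.start_frame - interval_b.start_frame) <= tolerance_frames


def _codeparture(a: Interval, b: Interval,
                 tolerance_frames: int = COARRIVAL_TOLERANCE_FRAMES) -> bool:
    return abs(a.end_frame - b.end_frame) <= tolerance_frames


# ---------------------------------------------------------------------------
# Clamp loading / unloading
# ---------------------------------------------------------------------------


def classify_loading(
    loader_intervals: Sequence[Interval],
    clamp_intervals: Sequence[Interval],
    *,
    tolerance_frames: int = COARRIVAL_TOLERANCE_FRAMES,
) -> list[EventRecord]:
    """Pair co-arriving loader and clamp intervals into loading events.

    Each loader interval is matched to at most one clamp interval (nearest
    co-arriving start).  The record carries the loader dwell, whether the
    clamp persisted after loader departure, and a ``co_release`` flag for
    the ATPgammaS-style joint release.
    """
    events: list[EventRecord] = []
    loaders = group_by_molecule(loader_intervals)
    clamps = group_by_molecule(clamp_intervals)
    for mol, livs in loaders.items():
        civs = sorted(clamps.get(mol, []), key=lambda iv: iv.start_frame)
        used: set[int] = set()
        for liv in sorted(livs, key=lambda iv: iv.start_frame):
            best, best_d = None, None
            for j, civ in enumerate(civs):
                if j in used:
                    continue
                d = abs(civ.start_frame - liv.start_frame)
                if d <= tolerance_frames and (best_d is None or d < best_d):
                    best, best_d = j, d
            if best is None:
                events.append(EventRecord("solo", mol, ("loader",),
                                          duration=liv.dwell, censored=liv.censored))
                continue
            used.add(best)
            civ = civs[best]
            co_release = _codeparture(liv, civ, tolerance_frames)
            events.append(
                EventRecord(
                    "loading",
                    mol,
                    ("loader", "clamp"),
                    duration=liv.dwell,
                    censored=liv.censored or civ.left_censored,
                    extra={
                        "loader_dwell": liv.dwell,
                        "clamp_persists": (not co_release)
                        and (civ.end_frame > liv.end_frame + tolerance_frames
                             or civ.right_censored),
                        "co_release": co_release,
                        "clamp_right_censored": civ.right_censored,
                        "joint_dwell": civ.dwell if co_release else None,
                    },
                )
            )
    return events


def classify_unloading(
    loader_intervals: Sequence[Interval],
    clamp_intervals: Sequence[Interval],
    *,
    tolerance_frames: int = COARRIVAL_TOLERANCE_FRAMES,
) -> list[EventRecord]:
    """Classify loader encounters with a pre-loaded clamp.

    A loader interval is an unloading *encounter* when a clamp interval is
    already in progress at the loader's arrival (clamp started earlier than
    the co-arrival tolerance allows).  Productive: the clamp signal ends
    during the loader interval or within one frame after; lag = clamp end -
    loader start.  Non-productive: the clamp outlives the loader visit.
    Loader arrivals with no concurrent clamp are classified "solo".
    """
    events: list[EventRecord] = []
    loaders = group_by_molecule(loader_intervals)
    clamps = group_by_molecule(clamp_intervals)
    for mol, livs in loaders.items():
        civs = clamps.get(mol, [])
        for liv in sorted(livs, key=lambda iv: iv.start_frame):
            cover = [
                c for c in civs
                if c.start_frame < liv.start_frame - tolerance_frames
                and c.end_frame >= liv.start_frame
            ]
            if not cover:
                events.append(EventRecord("solo", mol, ("loader",),
                                          duration=liv.dwell, censored=liv.censored))
                continue
            civ = min(cover, key=lambda c: c.start_frame)
            productive = (
                not civ.right_censored
                and civ.end_frame <= liv.end_frame + tolerance_frames
            )
            if productive:
                lag_frames = civ.end_frame - liv.start_frame
                events.append(
                    EventRecord(
                        "unloading_productive",
                        mol,
                        ("loader", "clamp"),
                        lag=lag_frames * liv.period,
                        duration=liv.dwell,
                        censored=liv.censored,
                        extra={"loader_dwell": liv.dwell},
                    )
                )
            else:
                events.append(
                    EventRecord(
                        "unloading_nonproductive",
                        mol,
                        ("loader", "clamp"),
                        duration=liv.dwell,
                        censored=liv.censored or civ.right_censored,
                        extra={"loader_dwell": liv.dwell},
                    )
                )
    return events


# ---------------------------------------------------------------------------
# Polymerase exchange
# ---------------------------------------------------------------------------


def classify_exchange(
    intervals_a: Sequence[Interval],
    intervals_b: Sequence[Interval],
    *,
    species_a: str = "A",
    species_b: str = "B",
) -> tuple[ExchangeSummary, list[EventRecord]]:
    """Classify adjacent/overlapping cross-species interval pairs.

    Per molecule all intervals of both species are merged into time order;
    every consecutive cross-species pair is classified exactly once: a
    switch when disjoint (lag = gap between last bound frame of the first
    and first bound frame of the second), a colocalization when overlapping
    (duration = overlap).  Pairs whose first member is right-censored are
    not classifiable and are skipped.  Percentages are over all classified
    cross-species pairs.  Events cut off by the movie end are excluded from
    lag/duration means but still counted in the direction tallies.
    """
    for ivs in (intervals_a, intervals_b):
        by_mol = group_by_molecule(ivs)
        for mol, group in by_mol.items():
            srt = sorted(group, key=lambda iv: iv.start_frame)
            for u, v in zip(srt, srt[1:]):
                if v.start_frame <= u.end_frame:
                    raise ValueError(
                        f"overlapping same-channel intervals on molecule {mol}"
                    )

    tagged = [(iv, species_a) for iv in intervals_a] + [(iv, species_b) for iv in intervals_b]
    by_mol: dict[int, list[tuple[Interval, str]]] = {}
    for iv, sp in tagged:
        by_mol.setdefault(iv.molecule_id, []).append((iv, sp))

    summary = ExchangeSummary(species_a, species_b)
    events: list[EventRecord] = []
    lags_ab: list[float] = []
    lags_ba: list[float] = []
    durs: list[float] = []

    for mol, group in by_mol.items():
        group.sort(key=lambda t: (t[0].start_frame, t[0].end_frame))
        for (u, su), (v, sv) in zip(group, group[1:]):
            if su == sv:
                continue
            if v.start_frame <= u.end_frame:
                # colocalization
                overlap_frames = min(u.end_frame, v.end_frame) - v.start_frame + 1
                dur = overlap_frames * u.period
                cens = u.right_censored or v.right_censored
                first_in = su if u.start_frame < v.start_frame else (
                    sv if v.start_frame < u.start_frame else "tie")
                if u.end_frame != v.end_frame:
                    first_out = su if u.end_frame < v.end_frame else sv
                elif cens:
                    first_out = "tie"
                else:
                    first_out = "tie"
                summary.n_coloc += 1
                summary.n_pairs += 1
                if not cens:
                    durs.append(dur)
                if first_in != "tie" and first_out != "tie":
                    i = 0 if first_in == species_a else 1
                    j = 0 if first_out == species_a else 1
                    summary.first_in_out[i, j] += 1
                events.append(
                    EventRecord(
                        "colocalization", mol, (su, sv), order=first_in,
                        duration=dur, censored=cens,
                        extra={"first_in": first_in, "first_out": first_out},
                    )
                )
            else:
                if u.right_censored:
                    continue  # release not observed; direction/lag undefined
                gap_frames = v.start_frame - u.end_frame - 1
                lag = gap_frames * u.period
                direction = f"{su}->{sv}"
                if su == species_a:
                    summary.n_ab += 1
                    lags_ab.append(lag)
                else:
                    summary.n_ba += 1
                    lags_ba.append(lag)
                summary.n_pairs += 1
                events.append(
                    EventRecord("switch", mol, (su, sv), order=direction, lag=lag)
                )

    summary.lag_ab_mean, summary.lag_ab_sem = _mean_sem(lags_ab)
    summary.lag_ba_mean, summary.lag_ba_sem = _mean_sem(lags_ba)
    summary.coloc_duration_mean, summary.coloc_duration_sem = _mean_sem(durs)
    return summary, events


# ---------------------------------------------------------------------------
# Label efficiency from two-channel co-binding
# ---------------------------------------------------------------------------


def estimate_label_efficiency(n_both: int, n_a_only: int, n_b_only: int):
    """Labeling efficiencies from co-binding events of an obligate pair.

    Events where the partner's label certifies the complex estimate the
    other label's efficiency: p_a = n_both/(n_both + n_b_only) and
    p_b = n_both/(n_both + n_a_only).  Doubly-dark events are invisible and
    carry no information.  Returns (p_a, se_a, p_b, se_b) with binomial
    standard errors.
    """
    if min(n_both, n_a_only, n_b_only) < 0:
        raise ValueError("counts must be >= 0")
    den_a = n_both + n_b_only
    den_b = n_both + n_a_only
    if den_a == 0 or den_b == 0:
        raise ValueError("label efficiency undefined: empty certifying denominator")
    p_a = n_both / den_a
    p_b = n_both / den_b
    se_a = math.sqrt(p_a * (1 - p_a) / den_a)
    se_b = math.sqrt(p_b * (1 - p_b) / den_b)
    return p_a, se_a, p_b, se_b


# ---------------------------------------------------------------------------
# Lag statistics
# ---------------------------------------------------------------------------


def lag_statistics(event_records: Sequence[EventRecord]):
    """Mean lag +/- s.e.m. per (kind, order), over uncensored events with a lag.

    Returns a DataFrame; an empty selection yields an empty frame (never a
    fabricated zero).
    """
    import pandas as pd

    rows = []
    groups: dict[tuple[str, str | None], list[float]] = {}
    for ev in event_records:
        if ev.lag is None or ev.censored:
            continue
        groups.setdefault((ev.kind, ev.order), []).append(ev.lag)
    for (kind, order), lags in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        mean, sem = _mean_sem(lags)
        rows.append({"kind": kind, "order": order, "n": len(lags),
                     "lag_mean_s": mean, "lag_sem_s": sem})
    return pd.DataFrame(rows, columns=["kind", "order", "n", "lag_mean_s", "lag_sem_s"])
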