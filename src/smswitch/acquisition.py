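"""Forward model of interleaved multi-channel TIRF acquisition.

Ground-truth binding trajectories are converted into per-molecule,
per-channel intensity traces the way the microscope would record them:

* channels are exposed sequentially within an acquisition cycle (50 ms
  exposure; 220 ms per channel slot in multi-channel mode, 86 ms when a
  single channel needs no filter changes), for a fixed number of frames;
* an optional stroboscopic/interval mode samples each cycle only every
  ``interval_mode_period`` seconds to cut cumulative illumination;
* each binding arrival carries a fluorophore only with probability
  ``p_label`` (labeling is incomplete, and a departing protein is replaced
  from solution by a fresh, independently labeled copy);
* fluorophores photobleach with a constant hazard per second of
  illumination, so the apparent on-DNA lifetime scales with the duty cycle
  exposure/cycle;
* intensity is background + summed brightness of bound, labeled,
  unbleached fluorophores in that channel + additive Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kinetics import StateTrajectory, occupancy_runs

__all__ = [
    "AcquisitionSchedule",
    "LabelModel",
    "BleachModel",
    "TraceSet",
    "make_schedule",
    "render_traces",
    "calibrate_bleach_hazard",
    "expected_apparent_lifetime",
    "render_movie",
]


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Timing of an interleaved multi-channel acquisition.

    In continuous mode the cycle period is ``n_channels * per_frame_period``
    (660 ms for 3 colors, 440 ms for 2, 86 ms for 1); in interval mode one
    cycle of exposures is taken every ``interval_mode_period`` seconds.
    Channel c is exposed at offset ``c * per_frame_period`` within a cycle.
    """

    n_channels: int
    exposure: float = 0.050
    per_frame_period: float = 0.220
    n_frames: int = 1000
    channel_offsets: tuple[float, ...] = ()
    interval_mode_period: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= 3:
            raise ValueError("n_channels must be 1..3")
        if self.exposure > self.per_frame_period:
            raise ValueError("exposure cannot exceed per_frame_period")
        if not self.channel_offsets:
            object.__setattr__(
                self,
                "channel_offsets",
                tuple(c * self.per_frame_period for c in range(self.n_channels)),
            )
        if len(self.channel_offsets) != self.n_channels:
            raise ValueError("need one offset per channel")
        if any(b <= a for a, b in zip(self.channel_offsets, self.channel_offsets[1:])):
            raise ValueError("channel_offsets must be strictly increasing")
        if any(off >= self.cycle_period for off in self.channel_offsets):
            raise ValueError("channel offsets must fall within one cycle")

    @property
    def cycle_period(self) -> float:
        """Per-channel sampling period in seconds."""
        if self.interval_mode_period is not None:
            return float(self.interval_mode_period)
        return self.n_channels * self.per_frame_period

    @property
    def duration(self) -> float:
        return self.n_frames * self.cycle_period

    def sample_times(self, channel: int) -> np.ndarray:
        """Start-of-exposure times of `channel`, one per frame."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range")
        return np.arange(self.n_frames) * self.cycle_period + self.channel_offsets[channel]


def make_schedule(
    n_channels: int,
    exposure: float = 0.050,
    per_frame_period: float | None = None,
    n_frames: int = 1000,
    interval_mode_period: float | None = None,
) -> AcquisitionSchedule:
    """Build a schedule with the study's default timings.

    ``per_frame_period`` defaults to 0.220 s in multi-channel mode and
    0.086 s single-channel (no filter-wheel changes needed).
    """
    if per_frame_period is None:
        per_frame_period = 0.086 if n_channels == 1 else 0.220
    return AcquisitionSchedule(
        n_channels=n_channels,
        exposure=exposure,
        per_frame_period=per_frame_period,
        n_frames=n_frames,
        interval_mode_period=interval_mode_period,
    )


# ---------------------------------------------------------------------------
# Label / bleach models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelModel:
    """Fluorophore assignment and imaging noise.

    ``channel_of`` maps a species to the channel index of its dye; species
    absent from the map are dark (e.g. an unlabeled clamp).  ``p_label`` is
    the per-protein-copy labeling probability (drawn once per binding
    arrival).  Background and noise are per channel.
    """

    channel_of: Mapping[str, int]
    p_label: Mapping[str, float] = field(default_factory=dict)
    brightness: Mapping[str, float] = field(default_factory=dict)
    background: float | Sequence[float] = 20.0
    noise_sd: float | Sequence[float] = 1.0

    def __post_init__(self) -> None:
        for sp, p in self.p_label.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_label[{sp!r}] must be in [0, 1]")

    def p(self, species: str) -> float:
        return float(self.p_label.get(species, 1.0))

    def bright(self, species: str) -> float:
        return float(self.brightness.get(species, 10.0))

    def channel_background(self, channel: int, n_channels: int) -> float:
        return _per_channel(self.background, channel, n_channels)

    def channel_noise(self, channel: int, n_channels: int) -> float:
        return _per_channel(self.noise_sd, channel, n_channels)


def _per_channel(value, channel: int, n_channels: int) -> float:
    if np.isscalar(value):
        return float(value)
    vals = list(value)
    if len(vals) != n_channels:
        raise ValueError("per-channel value length mismatch")
    return float(vals[channel])


@dataclass(frozen=True)
class BleachModel:
    """Constant photobleaching hazard per second of illumination, per species."""

    hazard: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.hazard.values()):
            raise ValueError("bleach hazards must be >= 0")

    def rate(self, species: str) -> float:
        return float(self.hazard.get(species, 0.0))


def calibrate_bleach_hazard(apparent_lifetime: float, schedule: AcquisitionSchedule) -> float:
    """Hazard per illuminated second giving a target apparent on-DNA lifetime.

    A fluorophore is illuminated only during its channel's exposures, i.e.
    for ``exposure/cycle`` of every second on DNA, so the mean illuminated
    time to bleach (1/hazard) maps to an apparent wall-clock lifetime of
    ``(1/hazard) * cycle/exposure``.  Inverting:
    hazard = cycle / (exposure * apparent_lifetime).
    """
    if schedule.exposure <= 0:
        raise ValueError("schedule exposure must be > 0")
    if apparent_lifetime <= 0:
        raise ValueError("apparent_lifetime must be > 0")
    if math.isinf(apparent_lifetime):
        return 0.0
    return schedule.cycle_period / (schedule.exposure * apparent_lifetime)


def expected_apparent_lifetime(hazard: float, schedule: AcquisitionSchedule) -> float:
    """Apparent on-DNA lifetime of an otherwise immortal fluorophore."""
    if hazard < 0:
        raise ValueError("hazard must be >= 0")
    if hazard == 0:
        return math.inf
    return schedule.cycle_period / (schedule.exposure * hazard)


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------


@dataclass
class TraceSet:
    """Sampled intensity traces: shape (n_molecules, n_channels, n_frames)."""

    intensity: np.ndarray
    schedule: AcquisitionSchedule
    molecule_ids: np.ndarray

    @property
    def n_molecules(self) -> int:
        return self.intensity.shape[0]

    def trace(self, molecule: int, channel: int) -> np.ndarray:
        return self.intensity[molecule, channel]

    def times(self, channel: int) -> np.ndarray:
        return self.schedule.sample_times(channel)

    def to_frame(self):
        """Long-format table: molecule_id, channel, frame, time_s, intensity."""
        import pandas as pd

        n_mol, n_ch, n_fr = self.intensity.shape
        mol = np.repeat(self.molecule_ids, n_ch * n_fr)
        ch = np.tile(np.repeat(np.arange(n_ch), n_fr), n_mol)
        fr = np.tile(np.arange(n_fr), n_mol * n_ch)
        t = np.stack([self.schedule.sample_times(c) for c in range(n_ch)])
        return pd.DataFrame(
            {
                "molecule_id": mol,
                "channel": ch,
                "frame": fr,
                "time_s": t[ch, fr],
                "intensity": self.intensity.reshape(-1),
            }
        )

    @classmethod
    def from_frame(cls, df, schedule: AcquisitionSchedule) -> "TraceSet":
        mols = np.sort(df["molecule_id"].unique())
        n_ch = int(df["channel"].max()) + 1
        n_fr = int(df["frame"].max()) + 1
        arr = np.zeros((len(mols), n_ch, n_fr))
        idx = {m: i for i, m in enumerate(mols)}
        arr[
            df["molecule_id"].map(idx).to_numpy(),
            df["channel"].to_numpy(),
            df["frame"].to_numpy(),
        ] = df["intensity"].to_numpy()
        return cls(intensity=arr, schedule=schedule, molecule_ids=mols)


def render_traces(
    trajectories: Iterable[StateTrajectory],
    schedule: AcquisitionSchedule,
    label_model: LabelModel,
    bleach_model: BleachModel | None = None,
    seed: int | np.random.Generator = 0,
) -> TraceSet:
    """Render observed fluorescence traces from ground-truth trajectories.

    For every binding arrival of a labeled species one Bernoulli(p_label)
    draw decides whether that protein copy carries a dye; if it does, an
    exponential illuminated-time-to-bleach budget is drawn and the dye emits
    during an exposure only while its cumulative illuminated time is within
    budget.  Emission is integrated as a point sample at the start of each
    exposure (exposure << any kinetic time scale simulated here).
    """
    bleach_model = bleach_model or BleachModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trajectories = list(trajectories)

    species_all: set[str] = set()
    for traj in trajectories:
        for _, _, s in traj.segments:
            species_all.update(x for x in s if not x.startswith("_"))
    dark = species_all - set(label_model.channel_of)
    for sp in dark:
        if label_model.p_label.get(sp, 0.0) > 0:
            raise ValueError(f"species {sp!r} has p_label > 0 but no channel assignment")

    n_ch = schedule.n_channels
    n_fr = schedule.n_frames
    ts = np.stack([schedule.sample_times(c) for c in range(n_ch)])

    intensity = np.zeros((len(trajectories), n_ch, n_fr))
    for i, traj in enumerate(trajectories):
        for sp, ch in label_model.channel_of.items():
            p = label_model.p(sp)
            b = label_model.bright(sp)
            h = bleach_model.rate(sp)
            t_ch = ts[ch]
            for t_on, t_off in occupancy_runs(traj, sp):
                if rng.random() >= p:
                    continue
                # half-open occupancy [t_on, t_off): sample at exactly t_off is
                # after the departure
                k0 = int(np.searchsorted(t_ch, t_on, side="left"))
                k1 = int(np.searchsorted(t_ch, t_off, side="left"))
                n_samples = k1 - k0
                if n_samples <= 0:
                    continue
                if h > 0:
                    budget = rng.exponential(1.0 / h)
                    # emits during exposure j (0-based within the run) while
                    # j * exposure < budget
                    n_vis = min(n_samples, int(budget / schedule.exposure) + 1)
                else:
                    n_vis = n_samples
                intensity[i, ch, k0 : k0 + n_vis] += b

    for c in range(n_ch):
        bg = label_model.channel_background(c, n_ch)
        sd = label_model.channel_noise(c, n_ch)
        intensity[:, c, :] += bg
        if sd > 0:
            intensity[:, c, :] += rng.normal(0.0, sd, size=(len(trajectories), n_fr))

    ids = np.array([traj.molecule_id for traj in trajectories])
    return TraceSet(intensity=intensity, schedule=schedule, molecule_ids=ids)


# ---------------------------------------------------------------------------
# Optional image-stack rendering
# ---------------------------------------------------------------------------


def render_movie(
    trace_set: TraceSet,
    psf_sigma: float = 1.2,
    image_size: tuple[int, int] = (128, 128),
    molecule_positions: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    background: float = 0.0,
    noise_sd: float = 0.0,
):
    """Render per-channel image stacks with Gaussian spots (optional feature).

    Each molecule is a 2-D Gaussian of unit integral scaled by its trace
    intensity at that frame.  Returns (stacks, positions, metadata); stacks
    has shape (n_channels, n_frames, H, W).  Molecules closer than
    2*psf_sigma are flagged in the metadata rather than rejected.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = image_size
    n_mol, n_ch, n_fr = trace_set.intensity.shape
    if molecule_positions is None:
        margin = max(4.0, 3 * psf_sigma)
        molecule_positions = np.column_stack(
            [rng.uniform(margin, h - margin, n_mol), rng.uniform(margin, w - margin, n_mol)]
        )
    pos = np.asarray(molecule_positions, dtype=float)
    if pos.shape != (n_mol, 2):
        raise ValueError("molecule_positions must be (n_molecules, 2)")
    if ((pos < 0) | (pos >= np.array([h, w]))).any():
        raise ValueError("molecule positions must lie within the image")

    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    crowded = np.where((d2 < (2 * psf_sigma) ** 2).any(axis=1))[0]

    half = int(np.ceil(4 * psf_sigma))
    stacks = np.full((n_ch, n_fr, h, w), background, dtype=float)
    for m in range(n_mol):
        r, c = pos[m]
        r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        kern = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * psf_sigma**2))
        kern /= 2 * np.pi * psf_sigma**2
        for ch in range(n_ch):
            amp = trace_set.intensity[m, ch]  # (n_frames,)
            stacks[ch, :, r0:r1, c0:c1] += amp[:, None, None] * kern[None, :, :]
    if noise_sd > 0:
        stacks += rng.normal(0.0, noise_sd, size=stacks.shape)
    meta = {
        "schedule": trace_set.schedule,
        "positions": pos,
        "crowded_molecules": crowded,
        "psf_sigma": psf_sigma,
    }
    return stacks, pos, meta
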