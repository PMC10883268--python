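"""Synthetic photon streams and lag tables with known ground truth.

The generator emulates a diffusion-based confocal PIE measurement of
dual-labelled SecYEG in proteoliposomes at picomolar concentration: rare
single-molecule bursts on top of per-stream Poisson background.  Within a
dual-labelled burst the channel interconverts between an open (low-FRET) and
a closed (high-FRET) conformation as a two-state telegraph process with
exponential dwell times.  Incompletely labelled molecules contribute static
donor-only and acceptor-only bursts.  When SecA is present, liposome
insertion is bidirectional, so a configurable fraction ``w`` (default 0.5)
of dual-labelled molecules cannot bind SecA and retains apo kinetics.

Bursts are generated directly (exponential durations, constant within-burst
photon rate) rather than by explicit 3-D diffusion through a Gaussian
confocal volume; this reproduces the statistical structure every downstream
stage consumes while remaining orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import PhotonData, DEFAULT_CLOCK_PERIOD

# Hidden-state / species codes used in ground-truth annotations.
OPEN, CLOSED, DONOR_ONLY, ACCEPTOR_ONLY = 0, 1, 2, 3
BACKGROUND = -1
STATE_NAMES = ("open", "closed", "donor-only", "acceptor-only")


def stream_probs(e: float, s: float) -> np.ndarray:
    """Per-photon stream probabilities for a state with raw (E, S).

    p(DexDem) = S(1-E), p(DexAem) = S*E, p(AexAem) = 1-S; sums to 1 exactly.
    """
    if not (0.0 <= e <= 1.0 and 0.0 <= s <= 1.0):
        raise ValueError(f"(E, S) must lie in [0,1]^2, got ({e}, {s})")
    return np.array([s * (1.0 - e), s * e, 1.0 - s])


@dataclass
class SimConfig:
    """Study conditions for one simulated measurement.

    Species fractions follow stochastic maleimide labelling: about half the
    detected molecules carry both dyes, with the remainder dominated by
    donor-only molecules.  Kinetic defaults are the apo SecYEG dwell times
    (tau_open = 6.1 ms, tau_closed = 27.5 ms).  Per-state (E, S) signatures
    place the closed channel at high FRET and the open channel at lower
    FRET, with photophysical species at the stoichiometry extremes.
    """

    f_da: float = 0.50
    f_d: float = 0.35
    f_a: float = 0.15
    orientation_weight: float = 0.5
    emissions: dict = field(
        default_factory=lambda: {
            OPEN: (0.40, 0.60),
            CLOSED: (0.75, 0.60),
            DONOR_ONLY: (0.05, 0.95),
            ACCEPTOR_ONLY: (0.80, 0.05),
        }
    )
    tau_open_ms: float = 6.1
    tau_closed_ms: float = 27.5
    mean_burst_duration_ms: float = 2.5
    burst_photon_rate_khz: float = 40.0
    bursts_per_second: float = 5.0
    background_khz: tuple = (1.0, 0.6, 0.8)
    acquisition_duration_s: float = 60.0
    n_repeats: int = 5
    clock_period: float = DEFAULT_CLOCK_PERIOD
    seed: int = 0

    def validate(self) -> None:
        total = self.f_da + self.f_d + self.f_a
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"species fractions sum to {total}, not 1")
        if not 0.0 <= self.orientation_weight <= 1.0:
            raise ValueError("orientation_weight must lie in [0, 1]")
        if self.tau_open_ms <= 0 or self.tau_closed_ms <= 0:
            raise ValueError("dwell time means must be > 0")
        if min(self.background_khz) < 0 or self.burst_photon_rate_khz < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class StateTrajectory:
    """Alternating open/closed segments of a telegraph realization."""

    states: np.ndarray       # per-segment state code
    durations_ms: np.ndarray  # per-segment duration, > 0
    total_ms: float

    @property
    def n_segments(self) -> int:
        return int(self.states.size)

    def occupancy(self, state: int) -> float:
        """Fraction of total time spent in ``state``."""
        return float(self.durations_ms[self.states == state].sum() / self.total_ms)


@dataclass
class LagTable:
    """Chemiluminescence lag versus probe insertion position.

    The NanoLuc split-luciferase transport assay reports, for a probe strand
    inserted ``position`` amino acids from the substrate's N-terminus, the
    lag in seconds before luminescence onset; the inverse slope of lag
    against position is the translocation rate in aa/s.
    """

    positions_aa: np.ndarray
    lags_s: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.positions_aa = np.asarray(self.positions_aa, dtype=float)
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        if np.any(self.positions_aa <= 0):
            raise ValueError("insertion positions must be strictly positive")


def simulate_two_state_trajectory(
    tau_open_ms: float,
    tau_closed_ms: float,
    duration_ms: float,
    rng: np.random.Generator | int | None = None,
) -> StateTrajectory:
    """Realize a two-state telegraph (continuous-time Markov) process.

    Dwell durations are exponential with means ``tau_open_ms`` /
    ``tau_closed_ms``; the initial state is drawn from the stationary
    distribution and the final segment is truncated at ``duration_ms``.
    """
    if tau_open_ms <= 0 or tau_closed_ms <= 0:
        raise ValueError("dwell time means must be > 0")
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(rng)
    taus = {OPEN: tau_open_ms, CLOSED: tau_closed_ms}
    p_open = tau_open_ms / (tau_open_ms + tau_closed_ms)
    state = OPEN if rng.random() < p_open else CLOSED
    states: list[int] = []
    durations: list[float] = []
    t = 0.0
    while t < duration_ms:
        dwell = rng.exponential(taus[state])
        dwell = min(dwell, duration_ms - t)
        states.append(state)
        durations.append(dwell)
        t += dwell
        state = CLOSED if state == OPEN else OPEN
    return StateTrajectory(
        states=np.array(states, dtype=np.int8),
        durations_ms=np.array(durations),
        total_ms=duration_ms,
    )


def emit_photons(
    traj: StateTrajectory,
    emissions: dict,
    photon_rate_khz: float,
    background_khz: tuple = (0.0, 0.0, 0.0),
    rng: np.random.Generator | int | None = None,
    clock_period: float = DEFAULT_CLOCK_PERIOD,
) -> PhotonData:
    """Emit a photon stream from a state trajectory.

    Photons arrive as a homogeneous Poisson process at ``photon_rate_khz``
    over the trajectory; each photon's stream is multinomial with the
    occupying state's probabilities.  Independent per-stream Poisson
    background is superposed.  Timestamps are quantized to clock ticks and
    ground truth (state per photon, -1 for background) is attached.
    """
    if photon_rate_khz < 0 or min(background_khz) < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(rng)
    total_ms = traj.total_ms
    edges = np.concatenate([[0.0], np.cumsum(traj.durations_ms)])

    n_sig = rng.poisson(photon_rate_khz * total_ms)
    t_sig = np.sort(rng.uniform(0.0, total_ms, n_sig))
    seg = np.clip(np.searchsorted(edges, t_sig, side="right") - 1, 0,
                  traj.n_segments - 1)
    state_sig = traj.states[seg]
    streams_sig = np.empty(n_sig, dtype=np.int8)
    for code, (e, s) in emissions.items():
        mask = state_sig == code
        if mask.any():
            streams_sig[mask] = rng.choice(
                3, size=int(mask.sum()), p=stream_probs(e, s)
            )

    t_parts = [t_sig]
    s_parts = [streams_sig]
    state_parts = [state_sig.astype(np.int8)]
    for stream_code, rate in enumerate(background_khz):
        n_bg = rng.poisson(rate * total_ms)
        t_parts.append(rng.uniform(0.0, total_ms, n_bg))
        s_parts.append(np.full(n_bg, stream_code, dtype=np.int8))
        state_parts.append(np.full(n_bg, BACKGROUND, dtype=np.int8))

    t_all = np.concatenate(t_parts)
    order = np.argsort(t_all, kind="stable")
    ticks = np.floor(t_all[order] * 1e-3 / clock_period).astype(np.int64)
    return PhotonData(
        timestamps=ticks,
        streams=np.concatenate(s_parts)[order],
        clock_period=clock_period,
        acquisition_duration=total_ms * 1e-3,
        ground_truth={"state": np.concatenate(state_parts)[order]},
    )


def simulate_measurement(
    config: SimConfig,
    kinetics: tuple[float, float] | None = None,
    seed: int | None = None,
    condition_label: str = "",
    repeat_id: int = 0,
) -> PhotonData:
    """Simulate one full measurement (bursts + background) with ground truth.

    ``kinetics`` is the (tau_open, tau_closed) of the SecA-accessible
    population, in ms; dual-labelled bursts draw it with probability
    ``1 - orientation_weight`` and otherwise use the apo kinetics stored in
    the config.  Pass ``kinetics=None`` for an apo-only condition.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dur_ms = config.acquisition_duration_s * 1e3
    apo = (config.tau_open_ms, config.tau_closed_ms)
    active = apo if kinetics is None else tuple(kinetics)

    n_bursts = rng.poisson(config.bursts_per_second * config.acquisition_duration_s)
    burst_starts = np.sort(rng.uniform(0.0, dur_ms, n_bursts))

    t_parts: list[np.ndarray] = []
    s_parts: list[np.ndarray] = []
    state_parts: list[np.ndarray] = []
    species_parts: list[np.ndarray] = []
    spans: list[tuple[float, float]] = []

    species_p = np.array([config.f_da, config.f_d, config.f_a])
    for start in burst_starts:
        b_dur = min(rng.exponential(config.mean_burst_duration_ms),
                    dur_ms - start)
        if b_dur <= 0:
            continue
        species = rng.choice(3, p=species_p)
        if species == 0:  # dual label: telegraph kinetics
            tau_o, tau_c = (apo if rng.random() < config.orientation_weight
                            else active)
            traj = simulate_two_state_trajectory(tau_o, tau_c, b_dur, rng)
            edges = np.concatenate([[0.0], np.cumsum(traj.durations_ms)])
            n_ph = rng.poisson(config.burst_photon_rate_khz * b_dur)
            t_rel = np.sort(rng.uniform(0.0, b_dur, n_ph))
            seg = np.clip(np.searchsorted(edges, t_rel, side="right") - 1,
                          0, traj.n_segments - 1)
            ph_state = traj.states[seg].astype(np.int8)
        else:
            static_state = DONOR_ONLY if species == 1 else ACCEPTOR_ONLY
            n_ph = rng.poisson(config.burst_photon_rate_khz * b_dur)
            t_rel = np.sort(rng.uniform(0.0, b_dur, n_ph))
            ph_state = np.full(n_ph, static_state, dtype=np.int8)
        streams = np.empty(n_ph, dtype=np.int8)
        for code, (e, s) in config.emissions.items():
            mask = ph_state == code
            if mask.any():
                streams[mask] = rng.choice(
                    3, size=int(mask.sum()), p=stream_probs(e, s)
                )
        t_parts.append(start + t_rel)
        s_parts.append(streams)
        state_parts.append(ph_state)
        species_parts.append(np.full(n_ph, species, dtype=np.int8))
        spans.append((start * 1e-3, (start + b_dur) * 1e-3))

    for stream_code, rate in enumerate(config.background_khz):
        n_bg = rng.poisson(rate * dur_ms)
        t_parts.append(rng.uniform(0.0, dur_ms, n_bg))
        s_parts.append(np.full(n_bg, stream_code, dtype=np.int8))
        state_parts.append(np.full(n_bg, BACKGROUND, dtype=np.int8))
        species_parts.append(np.full(n_bg, BACKGROUND, dtype=np.int8))

    t_all = np.concatenate(t_parts) if t_parts else np.empty(0)
    order = np.argsort(t_all, kind="stable")
    ticks = np.floor(t_all[order] * 1e-3 / config.clock_period).astype(np.int64)
    return PhotonData(
        timestamps=ticks,
        streams=np.concatenate(s_parts)[order] if t_parts else np.empty(0, np.int8),
        clock_period=config.clock_period,
        acquisition_duration=config.acquisition_duration_s,
        condition_label=condition_label,
        repeat_id=repeat_id,
        ground_truth={
            "state": np.concatenate(state_parts)[order],
            "species": np.concatenate(species_parts)[order],
            "burst_spans": np.array(spans).reshape(-1, 2),
        },
    )


def repeat_seeds(master_seed: int, n_repeats: int) -> list[int]:
    """Deterministic, independent per-repeat seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in
            ss.spawn(n_repeats)]


def simulate_repeats(
    config: SimConfig,
    kinetics: tuple[float, float] | None = None,
    n_repeats: int | None = None,
    condition_label: str = "",
) -> list[PhotonData]:
    """Simulate independent technical repeats of one condition."""
    n = config.n_repeats if n_repeats is None else n_repeats
    if n < 1:
        raise ValueError("n_repeats must be >= 1")
    return [
        simulate_measurement(
            config, kinetics, seed=s, condition_label=condition_label,
            repeat_id=i,
        )
        for i, s in enumerate(repeat_seeds(config.seed, n))
    ]


def simulate_lag_table(
    v_aa_per_s: float,
    t0_s: float,
    positions_aa,
    noise_sd_s: float = 0.0,
    rng: np.random.Generator | int | None = None,
    condition_label: str = "",
) -> LagTable:
    """Lag table from a linear transport model: lag = t0 + position / v."""
    if v_aa_per_s <= 0:
        raise ValueError("transport rate must be > 0")
    rng = np.random.default_rng(rng)
    positions = np.asarray(positions_aa, dtype=float)
    lags = t0_s + positions / v_aa_per_s
    if noise_sd_s > 0:
        lags = lags + rng.normal(0.0, noise_sd_s, positions.size)
    return LagTable(positions_aa=positions, lags_s=lags,
                    condition_label=condition_label)
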