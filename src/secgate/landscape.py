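"""Simplified free-energy profiles and the ATPase 'clock' trajectory.

A two-state channel at equilibrium determines the free-energy difference
between its conformations directly from the dwell times,
``ΔG(open - closed) = -ln(tau_open / tau_closed)`` in units of k_B·T.
Barrier heights additionally require an attempt-frequency prefactor k0
that smFRET cannot determine, so barriers are reported relative to an
explicit, user-supplied k0 and always flagged as qualitative; the
difference of the two barriers equals ΔG for any k0 (detailed balance).

The 'clock' projects a telegraph trajectory of channel gating onto one
average SecA ATP-turnover cycle: the cycle period is 1/k_cat, the
ATP-bound phase lasts until phosphate release (1/k_Pi), and the remainder
is the post-hydrolysis ADP phase; each phase drives the channel with its
own dwell-time pair, the channel state carrying over continuously across
phase boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def equilibrium_free_energy(tau_open_ms: float, tau_closed_ms: float) -> float:
    """ΔG(open - closed) in k_B·T; positive when the open state lies higher."""
    if tau_open_ms <= 0 or tau_closed_ms <= 0:
        raise ValueError("dwell times must be > 0")
    return float(-np.log(tau_open_ms / tau_closed_ms))


@dataclass
class Landscape:
    """Relative two-well profile along the opening/closure coordinate."""

    dg_open_minus_closed: float          # k_B T
    barrier_open_to_closed: float        # k_B T, relative to ln k0
    barrier_closed_to_open: float        # k_B T, relative to ln k0
    prefactor_per_ms: float
    qualitative_barriers: bool = True    # barriers depend on the assumed k0


def barrier_profile(tau_open_ms: float, tau_closed_ms: float,
                    prefactor_per_ms: float) -> Landscape:
    """Arrhenius-style barriers against an explicit prefactor k0.

    ΔG‡(open→closed) = ln(k0 tau_open), ΔG‡(closed→open) = ln(k0 tau_closed);
    their difference equals the equilibrium ΔG for any k0 (gauge property),
    which is the only quantitatively meaningful output.
    """
    if tau_open_ms <= 0 or tau_closed_ms <= 0:
        raise ValueError("dwell times must be > 0")
    if prefactor_per_ms <= 0:
        raise ValueError("prefactor k0 must be > 0")
    return Landscape(
        dg_open_minus_closed=equilibrium_free_energy(tau_open_ms,
                                                     tau_closed_ms),
        barrier_open_to_closed=float(np.log(prefactor_per_ms * tau_open_ms)),
        barrier_closed_to_open=float(np.log(prefactor_per_ms * tau_closed_ms)),
        prefactor_per_ms=prefactor_per_ms,
    )


@dataclass
class ClockConfig:
    """Phase structure of one average SecA ATP-turnover cycle.

    Defaults: k_cat = 6.52 /s for ATP hydrolysis during translocation and
    phosphate release at 17.9 /s, giving an ATP-bound phase of 1000/17.9 =
    55.9 ms and a post-hydrolysis ADP phase of 97.5 ms in a 153.4 ms
    cycle.  Phase dwell-time defaults use the ATPγS complex for the
    ATP-bound phase and the ADP·AlFx (post-hydrolysis proxy) complex for
    the ADP phase; a loosely-bound ADP phase is off by default since its
    contribution to the cycle is marginal.
    """

    k_cat_per_s: float = 6.52
    phosphate_release_per_s: float = 17.9
    atp_kinetics_ms: tuple = (0.4, 1.1)
    adp_ph_kinetics_ms: tuple = (3.5, 1.9)
    include_adp_l: bool = False
    adp_l_duration_ms: float = 0.0
    adp_l_kinetics_ms: tuple = (0.5, 14.5)

    def __post_init__(self) -> None:
        if self.k_cat_per_s <= 0 or self.phosphate_release_per_s <= 0:
            raise ValueError("rates must be > 0")
        if self.phosphate_release_per_s <= self.k_cat_per_s:
            raise ValueError(
                "phosphate release must be faster than overall turnover"
            )
        if self.adp_ph_duration_ms <= 0:
            raise ValueError("ADP-PH phase duration is not positive; "
                             "reduce adp_l_duration_ms")

    @property
    def cycle_ms(self) -> float:
        return 1000.0 / self.k_cat_per_s

    @property
    def atp_duration_ms(self) -> float:
        return 1000.0 / self.phosphate_release_per_s

    @property
    def adp_ph_duration_ms(self) -> float:
        adp_l = self.adp_l_duration_ms if self.include_adp_l else 0.0
        return self.cycle_ms - self.atp_duration_ms - adp_l

    def phases(self) -> list[tuple[str, float, tuple]]:
        out = [("ATP", self.atp_duration_ms, self.atp_kinetics_ms),
               ("ADP_PH", self.adp_ph_duration_ms, self.adp_ph_kinetics_ms)]
        if self.include_adp_l:
            out.append(("ADP_L", self.adp_l_duration_ms,
                        self.adp_l_kinetics_ms))
        return out


@dataclass
class ClockTrajectory:
    """Simulated channel gating around the ATPase cycle."""

    phase_names: list
    phase_durations_ms: dict
    phase_open_occupancy: dict       # equilibrated (burn-in excluded)
    cycle_ms: float
    n_cycles: int
    segments: list = field(default_factory=list)  # (state, dur_ms, phase)
    phase_open_occupancy_raw: dict = field(default_factory=dict)


def simulate_atpase_clock(
    config: ClockConfig,
    n_cycles: int = 1,
    seed: int | None = None,
    keep_segments: bool | None = None,
) -> ClockTrajectory:
    """Telegraph gating driven through the deterministic phase clock.

    Within each phase the channel switches with that phase's (tau_open,
    tau_closed); the occupied state carries over across phase and cycle
    boundaries (the exponential dwell clock restarts with the new phase's
    rates, which is exact for a memoryless process).  Per-phase open
    occupancies are accumulated over all cycles.

    Because the state carries over, each phase starts from the previous
    phase's stationary distribution and relaxes to its own over a few
    relaxation times tau_relax = 1/(1/tau_open + 1/tau_closed).  The
    reported ``phase_open_occupancy`` is the quasi-stationary occupancy of
    the phase: a burn-in of ``5 * tau_relax`` (at most a quarter of the
    phase) after each boundary is excluded, which removes the O(tau_relax /
    phase duration) carry-over bias.  The uncorrected time average is kept
    as ``phase_open_occupancy_raw``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    phases = config.phases()
    if keep_segments is None:
        keep_segments = n_cycles <= 1000
    open_time = {name: 0.0 for name, _, _ in phases}
    total_time = {name: 0.0 for name, _, _ in phases}
    open_eq = {name: 0.0 for name, _, _ in phases}
    total_eq = {name: 0.0 for name, _, _ in phases}
    burn_in = {}
    for name, phase_dur, (tau_o, tau_c) in phases:
        tau_relax = 1.0 / (1.0 / tau_o + 1.0 / tau_c)
        burn_in[name] = min(5.0 * tau_relax, phase_dur / 4.0)
    segments: list = []

    tau_o0, tau_c0 = phases[0][2]
    state_open = rng.random() < tau_o0 / (tau_o0 + tau_c0)
    for _ in range(n_cycles):
        for name, phase_dur, (tau_o, tau_c) in phases:
            t = 0.0
            while t < phase_dur:
                tau = tau_o if state_open else tau_c
                dwell = min(rng.exponential(tau), phase_dur - t)
                if state_open:
                    open_time[name] += dwell
                total_time[name] += dwell
                eq_dwell = min(t + dwell, phase_dur) - max(t, burn_in[name])
                if eq_dwell > 0:
                    total_eq[name] += eq_dwell
                    if state_open:
                        open_eq[name] += eq_dwell
                if keep_segments:
                    segments.append(
                        ("open" if state_open else "closed", dwell, name))
                t += dwell
                if t < phase_dur:
                    state_open = not state_open
    return ClockTrajectory(
        phase_names=[name for name, _, _ in phases],
        phase_durations_ms={name: dur for name, dur, _ in phases},
        phase_open_occupancy={
            name: open_eq[name] / total_eq[name] for name in open_eq},
        cycle_ms=config.cycle_ms,
        n_cycles=n_cycles,
        segments=segments,
        phase_open_occupancy_raw={
            name: open_time[name] / total_time[name] for name in open_time},
    )
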