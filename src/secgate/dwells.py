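"""Dwell-time observables: residence times, percent open, repeat CIs.

The fitted model and its Viterbi state paths are reduced to the kinetic
observables of channel gating: per-burst dwell segments with their raw
(E, S), mean residence times tau_open / tau_closed, the open-state
occupancy ``percent open = 100 * tau_open / (tau_open + tau_closed)``, and
Student-t confidence intervals over technical repeats.

Because SecYEG inserts into liposomes in both orientations, roughly half
the molecules in +SecA conditions cannot bind SecA and retain apo
kinetics; the orientation correction removes that admixed apo population,
either by linear unmixing of the open-state occupancy or by fitting dwell
durations as a two-component exponential mixture with the apo component
fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .h2mm import H2MMModel, StatePath, BurstPhotons
from .io import DEX_DEM, DEX_AEM, AEX_AEM

logger = logging.getLogger("secgate")

PHOTOPHYSICAL_LABELS = ("donor-only", "acceptor-only")


@dataclass
class Dwell:
    """One maximal constant-state run of a burst's Viterbi path."""

    state: int
    label: str
    duration_ms: float
    position: str        # initial | mid | terminal | whole-burst
    burst_id: int
    e_raw: float
    s_raw: float
    n_photons: int
    n_dd: int = 0
    n_da: int = 0
    n_aa: int = 0

    @property
    def photophysical(self) -> bool:
        return self.label in PHOTOPHYSICAL_LABELS


def extract_dwells(
    paths: StatePath,
    photons: BurstPhotons,
    state_labels: list[str] | None = None,
) -> list[Dwell]:
    """Maximal constant-state runs per burst, with durations and (E, S).

    A dwell's duration runs from its first to its last photon plus half of
    each flanking inter-photon gap (no flank at burst edges).  Dwells in
    photophysical states are retained but flagged via their label.
    """
    labels = state_labels or [str(i) for i in range(paths.n_states)]
    dwells: list[Dwell] = []
    for burst_id, path in enumerate(paths.paths):
        t = photons.times_ms[photons.ptr[burst_id]:photons.ptr[burst_id + 1]]
        st = photons.streams[photons.ptr[burst_id]:photons.ptr[burst_id + 1]]
        if path.size == 0:
            continue
        breaks = np.nonzero(np.diff(path) != 0)[0]
        starts = np.concatenate([[0], breaks + 1])
        stops = np.concatenate([breaks + 1, [path.size]])
        n_runs = starts.size
        for r, (a, b) in enumerate(zip(starts, stops)):
            duration = t[b - 1] - t[a]
            if a > 0:
                duration += (t[a] - t[a - 1]) / 2.0
            if b < path.size:
                duration += (t[b] - t[b - 1]) / 2.0
            if n_runs == 1:
                position = "whole-burst"
            elif r == 0:
                position = "initial"
            elif r == n_runs - 1:
                position = "terminal"
            else:
                position = "mid"
            seg = st[a:b]
            n_dd = int(np.count_nonzero(seg == DEX_DEM))
            n_da = int(np.count_nonzero(seg == DEX_AEM))
            n_aa = int(np.count_nonzero(seg == AEX_AEM))
            dex = n_dd + n_da
            dwells.append(Dwell(
                state=int(path[a]),
                label=labels[int(path[a])],
                duration_ms=float(max(duration, 1e-9)),
                position=position,
                burst_id=burst_id,
                e_raw=n_da / dex if dex else np.nan,
                s_raw=dex / (dex + n_aa) if dex + n_aa else np.nan,
                n_photons=int(b - a),
                n_dd=n_dd, n_da=n_da, n_aa=n_aa,
            ))
    return dwells


def state_emission_summary(dwells: list[Dwell], background=None) -> dict:
    """Aggregate per-state (E, S) from dwell photon counts.

    With a :class:`~secgate.bursts.BackgroundRates`, the expected background
    counts (rate x dwell duration, per stream) are subtracted from the
    aggregated counts before forming E and S — the routine burst-analysis
    background correction, which removes the dilution of state signatures
    by background photons assigned to the dwell.
    """
    counts: dict = {}
    time_ms: dict = {}
    for d in dwells:
        c = counts.setdefault(d.label, np.zeros(3))
        c += (d.n_dd, d.n_da, d.n_aa)
        time_ms[d.label] = time_ms.get(d.label, 0.0) + d.duration_ms
    out: dict = {}
    for label, c in counts.items():
        if background is not None:
            c = np.clip(c - background.rates_khz * time_ms[label], 0.0, None)
        dex = c[0] + c[1]
        total = dex + c[2]
        out[label] = (
            float(c[1] / dex) if dex > 0 else np.nan,
            float(dex / total) if total > 0 else np.nan,
        )
    return out


def dwell_times_from_model(model: H2MMModel) -> dict:
    """Mean residence time per state from the fitted exit rates.

    tau_i = 1 / sum_j k_ij; for the conformational pair, only the
    open<->closed rates count (exits into photophysical states represent
    distinct molecules, not kinetic exchange), so tau_open = 1/k(open->
    closed) and tau_closed = 1/k(closed->open) when states are labelled.
    Absorbing states report ``inf``.
    """
    labels = model.state_labels or [str(i) for i in range(model.n_states)]
    rates = model.rates_per_ms
    taus: dict = {}
    idx = {lab: i for i, lab in enumerate(labels)}
    for i, lab in enumerate(labels):
        if lab == "open" and "closed" in idx:
            k_exit = rates[i, idx["closed"]]
        elif lab == "closed" and "open" in idx:
            k_exit = rates[i, idx["open"]]
        else:
            k_exit = rates[i].sum() - rates[i, i]
        taus[lab] = 1.0 / k_exit if k_exit > 0 else np.inf
    return taus


def conformational_taus(model: H2MMModel) -> tuple[float, float]:
    """(tau_open, tau_closed) in ms from a classified model."""
    taus = dwell_times_from_model(model)
    if "open" not in taus or "closed" not in taus:
        raise ValueError("model has no classified open/closed states")
    return taus["open"], taus["closed"]


def percent_open(tau_open_ms: float, tau_closed_ms: float) -> float:
    """Open-state occupancy in %: 100 * tau_open / (tau_open + tau_closed)."""
    if tau_open_ms < 0 or tau_closed_ms < 0:
        raise ValueError("dwell times must be >= 0")
    total = tau_open_ms + tau_closed_ms
    if total == 0:
        raise ValueError("tau_open and tau_closed cannot both be 0")
    return 100.0 * tau_open_ms / total


def aggregate_repeats(values, level: float = 0.90) -> tuple[float, float]:
    """Mean and two-sided Student-t CI half-width over technical repeats.

    Returns (mean, half_width); the half-width is NaN (flagged undefined)
    for a single repeat, and 0 for ``level = 0``.
    """
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    n = values.size
    if n < 2:
        return mean, np.nan
    if level <= 0:
        return mean, 0.0
    sd = float(values.std(ddof=1))
    t_crit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    return mean, float(t_crit * sd / np.sqrt(n))


@dataclass
class DwellStats:
    """Per-condition kinetic summary over technical repeats."""

    condition_label: str
    tau_open_ms: np.ndarray      # per repeat
    tau_closed_ms: np.ndarray    # per repeat
    ci_level: float = 0.90

    def __post_init__(self) -> None:
        self.tau_open_ms = np.atleast_1d(np.asarray(self.tau_open_ms, float))
        self.tau_closed_ms = np.atleast_1d(
            np.asarray(self.tau_closed_ms, float))
        if np.any(self.tau_open_ms <= 0) or np.any(self.tau_closed_ms <= 0):
            raise ValueError("dwell times must be > 0")

    @property
    def n_repeats(self) -> int:
        return int(self.tau_open_ms.size)

    @property
    def percent_open(self) -> np.ndarray:
        """Per-repeat open occupancy (%); the mean of these is reported."""
        return np.array([percent_open(o, c) for o, c in
                         zip(self.tau_open_ms, self.tau_closed_ms)])

    def summary(self) -> dict:
        out = {"condition": self.condition_label,
               "n_repeats": self.n_repeats}
        for name, vals in (("tau_open_ms", self.tau_open_ms),
                           ("tau_closed_ms", self.tau_closed_ms),
                           ("percent_open", self.percent_open)):
            mean, ci = aggregate_repeats(vals, self.ci_level)
            out[name] = mean
            out[name + "_ci"] = ci
        return out


@dataclass
class CorrectionConfig:
    """Settings for removing the non-participating apo population."""

    apo_reference: DwellStats
    w: float = 0.5
    mode: str = "occupancy-unmixing"  # or "dwell-mixture"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w < 1.0:
            raise ValueError("mixture weight w must lie in [0, 1)")
        if self.mode not in ("occupancy-unmixing", "dwell-mixture"):
            raise ValueError(f"unknown correction mode {self.mode!r}")


def unmix_occupancy(p_obs: float, p_apo: float, w: float) -> float:
    """Linear unmixing of open occupancy: (P_obs - w*P_apo)/(1 - w).

    Operates on whatever scale the inputs share (fractions or percent);
    results outside the physical range are clipped with a warning.
    """
    if not 0.0 <= w < 1.0:
        raise ValueError("w must lie in [0, 1)")
    corrected = (p_obs - w * p_apo) / (1.0 - w)
    full = 100.0 if max(p_obs, p_apo) > 1.0 else 1.0
    if corrected < 0.0 or corrected > full:
        logger.warning(
            "corrected occupancy %.3f outside [0, %g]; clipping", corrected,
            full,
        )
        corrected = float(np.clip(corrected, 0.0, full))
    return corrected


def unmix_dwell_tau(durations_ms, tau_apo_ms: float, w: float) -> float:
    """ML estimate of the free component of an exponential dwell mixture.

    Dwell durations are modelled as w * Exp(tau_apo) + (1-w) * Exp(tau);
    the apo component is fixed and tau is maximized by profile likelihood.
    """
    x = np.asarray(durations_ms, dtype=float)
    if x.size == 0:
        raise ValueError("no dwell durations supplied")
    if not 0.0 <= w < 1.0:
        raise ValueError("w must lie in [0, 1)")

    def nll(log_tau: float) -> float:
        tau = np.exp(log_tau)
        f = (w / tau_apo_ms * np.exp(-x / tau_apo_ms)
             + (1.0 - w) / tau * np.exp(-x / tau))
        return -np.log(np.clip(f, 1e-300, None)).sum()

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(1e-3), np.log(1e4)), method="bounded")
    return float(np.exp(res.x))


def orientation_correction(
    observed: DwellStats,
    config: CorrectionConfig,
    open_dwells_ms=None,
    closed_dwells_ms=None,
) -> DwellStats:
    """Remove the admixed apo population from an observed DwellStats.

    In ``occupancy-unmixing`` mode, the per-repeat open occupancy is
    linearly unmixed against the apo reference and the dwell times rescaled
    to preserve the per-repeat relaxation rate (1/tau_open + 1/tau_closed).
    In ``dwell-mixture`` mode, per-repeat open/closed dwell-duration lists
    are fit as exponential mixtures with the apo component fixed.
    """
    apo_p = float(np.mean(observed_apo := config.apo_reference.percent_open))
    if config.mode == "occupancy-unmixing":
        new_open, new_closed = [], []
        for tau_o, tau_c in zip(observed.tau_open_ms, observed.tau_closed_ms):
            p_corr = unmix_occupancy(percent_open(tau_o, tau_c), apo_p,
                                     config.w) / 100.0
            p_corr = float(np.clip(p_corr, 1e-6, 1 - 1e-6))
            k_relax = 1.0 / tau_o + 1.0 / tau_c
            # stationary open fraction p = k_co/(k_oc + k_co) with
            # k_oc + k_co = k_relax kept fixed
            new_open.append(1.0 / ((1.0 - p_corr) * k_relax))
            new_closed.append(1.0 / (p_corr * k_relax))
        return replace(observed, tau_open_ms=np.array(new_open),
                       tau_closed_ms=np.array(new_closed))
    # dwell-mixture mode
    if open_dwells_ms is None or closed_dwells_ms is None:
        raise ValueError(
            "dwell-mixture mode needs per-repeat open/closed dwell durations"
        )
    apo_tau_o = float(np.mean(config.apo_reference.tau_open_ms))
    apo_tau_c = float(np.mean(config.apo_reference.tau_closed_ms))
    new_open = [unmix_dwell_tau(d, apo_tau_o, config.w)
                for d in open_dwells_ms]
    new_closed = [unmix_dwell_tau(d, apo_tau_c, config.w)
                  for d in closed_dwells_ms]
    return replace(observed, tau_open_ms=np.array(new_open),
                   tau_closed_ms=np.array(new_closed))


def condition_report(stats_list: list[DwellStats]) -> pd.DataFrame:
    """Tidy per-condition summary table for the 2-D dwell-time plots."""
    rows = [s.summary() for s in stats_list]
    columns = ["condition", "n_repeats", "tau_open_ms", "tau_open_ms_ci",
               "tau_closed_ms", "tau_closed_ms_ci", "percent_open",
               "percent_open_ci"]
    return pd.DataFrame(rows, columns=columns)


def plot_dwell_scatter(stats_list: list[DwellStats], ax=None):
    """tau_open vs tau_closed scatter (log-log), one point per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in stats_list:
        summary = s.summary()
        ax.errorbar(
            summary["tau_open_ms"], summary["tau_closed_ms"],
            xerr=summary["tau_open_ms_ci"] or None,
            yerr=summary["tau_closed_ms_ci"] or None,
            marker="o", capsize=3, label=s.condition_label,
        )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$\tau_\mathrm{open}$ (ms)")
    ax.set_ylabel(r"$\tau_\mathrm{closed}$ (ms)")
    ax.legend(fontsize=8)
    return ax
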