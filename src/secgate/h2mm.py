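"""Multi-parameter photon-by-photon hidden Markov modelling.

The hidden state of a molecule (channel conformation or photophysical
species) evolves as a continuous-time Markov chain with rate matrix Q
(off-diagonal rates in 1/ms); every detected photon reports the state
through a per-state multinomial over the three PIE streams.  The likelihood
of a burst with photon streams c_1..c_K at inter-photon intervals
Δt_2..Δt_K is

    L = π ∘ b(c_1) · Π_k  P(Δt_k) ∘ b(c_k),   P(Δt) = expm(Q Δt),

evaluated with scaled forward recursions so 10^4-photon bursts do not
underflow.  P(Δt) and the expected sufficient statistics of the hidden
chain (time spent per state, number of transitions, emission counts) are
computed exactly through the eigendecomposition of Q, which makes EM
(Baum–Welch with interval-resolved expected transition counts) exact and
fast; the per-photon kernels are numba-compiled.

Model-order selection uses the normalized Bayes information criterion
BIC' = (BIC - min BIC)/|min BIC| with the smallest state count achieving
BIC' below a threshold (0.005 by default) selected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .io import PhotonData, Burst, DEX_DEM, DEX_AEM, AEX_AEM, \
    DEFAULT_CLOCK_PERIOD

logger = logging.getLogger("secgate")

_EIG_DEGENERACY_TOL = 1e-10


class ClassificationError(ValueError):
    """State geometry too ambiguous for automatic labelling."""


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class H2MMModel:
    """Hidden-state kinetic/emission model.

    Parameters
    ----------
    rates_per_ms
        (N, N) off-diagonal transition rates k_ij in 1/ms; the diagonal is
        ignored (the generator diagonal is minus the row sum).  The
        per-tick transition matrix is I + Q·δ to first order, and exact
        interval propagators are expm(Q Δt).
    emissions
        (N, 3) per-state stream probabilities (rows sum to 1).
    pi
        (N,) initial state distribution.
    clock_period
        Seconds per timestamp tick.
    state_labels
        Optional per-state labels, e.g. from :func:`classify_states`.
    """

    rates_per_ms: np.ndarray
    emissions: np.ndarray
    pi: np.ndarray
    clock_period: float = DEFAULT_CLOCK_PERIOD
    state_labels: list | None = None

    def __post_init__(self) -> None:
        self.rates_per_ms = np.array(self.rates_per_ms, dtype=float)
        np.fill_diagonal(self.rates_per_ms, 0.0)
        self.emissions = np.array(self.emissions, dtype=float)
        self.pi = np.array(self.pi, dtype=float)

    @property
    def n_states(self) -> int:
        return int(self.pi.size)

    @property
    def generator(self) -> np.ndarray:
        """Rate matrix Q with diagonal -sum of off-diagonal rates."""
        q = self.rates_per_ms.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def per_tick_matrix(self) -> np.ndarray:
        """A = I + Q·δ (δ in ms); valid for the small per-tick steps."""
        return np.eye(self.n_states) + self.generator * (self.clock_period * 1e3)

    def transition_matrix(self, dt_ms: float) -> np.ndarray:
        """Exact propagator expm(Q·Δt) via eigendecomposition."""
        mu, u = np.linalg.eig(self.generator)
        uinv = np.linalg.inv(u)
        p = (u * np.exp(mu * dt_ms)) @ uinv
        return np.clip(p.real, 0.0, None)

    def validate(self, tol: float = 1e-10) -> None:
        if np.any(self.rates_per_ms < 0) or np.any(self.emissions < 0) or \
                np.any(self.pi < 0):
            raise ValueError("model entries must be non-negative")
        if abs(self.pi.sum() - 1.0) > tol:
            raise ValueError(f"pi sums to {self.pi.sum()}, not 1")
        if np.max(np.abs(self.emissions.sum(axis=1) - 1.0)) > tol:
            raise ValueError("emission rows must sum to 1")

    # -- raw FRET / stoichiometry parameterization of the emission rows ----

    @staticmethod
    def emission_row(e: float, s: float) -> np.ndarray:
        return np.array([s * (1 - e), s * e, 1 - s])

    @classmethod
    def from_es(cls, es_pairs, rates_per_ms, pi=None,
                clock_period: float = DEFAULT_CLOCK_PERIOD) -> "H2MMModel":
        b = np.array([cls.emission_row(e, s) for e, s in es_pairs])
        n = b.shape[0]
        if pi is None:
            pi = np.full(n, 1.0 / n)
        return cls(rates_per_ms=np.asarray(rates_per_ms, float),
                   emissions=b, pi=np.asarray(pi, float),
                   clock_period=clock_period)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rates_per_ms": self.rates_per_ms.tolist(),
            "emissions": self.emissions.tolist(),
            "pi": self.pi.tolist(),
            "clock_period": self.clock_period,
            "state_labels": self.state_labels,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "H2MMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            rates_per_ms=np.array(payload["rates_per_ms"]),
            emissions=np.array(payload["emissions"]),
            pi=np.array(payload["pi"]),
            clock_period=payload["clock_period"],
            state_labels=payload.get("state_labels"),
        )


def state_es(model: H2MMModel) -> np.ndarray:
    """Per-state (E_raw, S_raw) implied by the emission matrix.

    E = B[:,DexAem]/(B[:,DexDem]+B[:,DexAem]); S = B[:,DexDem]+B[:,DexAem].
    """
    b = model.emissions
    s = b[:, DEX_DEM] + b[:, DEX_AEM]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(s > 0, b[:, DEX_AEM] / np.where(s > 0, s, 1.0), np.nan)
    return np.column_stack([e, s])


def classify_states(es_pairs) -> list[str]:
    """Label states as open/closed/donor-only/acceptor-only from (E, S).

    States at stoichiometry extremes are photophysical (S >= 0.8 donor-only,
    S <= 0.2 acceptor-only); exactly two mid-S FRET states must remain and
    are ranked by FRET efficiency — the high-FRET state is the closed
    channel, the low-FRET state the open channel.
    """
    es = np.asarray(es_pairs, dtype=float)
    labels = [None] * es.shape[0]
    fret_idx = []
    for i, (e, s) in enumerate(es):
        if s >= 0.8:
            labels[i] = "donor-only"
        elif s <= 0.2:
            labels[i] = "acceptor-only"
        else:
            fret_idx.append(i)
    if sum(1 for l in labels if l == "donor-only") > 1 or \
            sum(1 for l in labels if l == "acceptor-only") > 1:
        raise ClassificationError(
            "more than one state at a stoichiometry extreme; label manually"
        )
    if len(fret_idx) != 2:
        raise ClassificationError(
            f"expected exactly 2 FRET states at intermediate S, found "
            f"{len(fret_idx)}; label manually"
        )
    e_vals = es[fret_idx, 0]
    if abs(e_vals[0] - e_vals[1]) < 0.05:
        raise ClassificationError(
            "FRET states not separated in E; label manually"
        )
    lo, hi = (fret_idx[0], fret_idx[1]) if e_vals[0] < e_vals[1] else \
        (fret_idx[1], fret_idx[0])
    labels[lo] = "open"
    labels[hi] = "closed"
    return labels


# ---------------------------------------------------------------------------
# Photon tables
# ---------------------------------------------------------------------------

@dataclass
class BurstPhotons:
    """Concatenated per-burst photon arrays ready for the HMM kernels."""

    times_ms: np.ndarray   # absolute arrival times, ms
    streams: np.ndarray    # int64 stream codes
    ptr: np.ndarray        # (n_bursts + 1,) burst boundaries
    clock_period: float = DEFAULT_CLOCK_PERIOD
    dt_ms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.streams = np.asarray(self.streams, dtype=np.int64)
        self.ptr = np.asarray(self.ptr, dtype=np.int64)
        dt = np.zeros_like(self.times_ms)
        dt[1:] = np.diff(self.times_ms)
        dt[self.ptr[:-1]] = 0.0  # no propagation into a burst's first photon
        if np.any(dt < 0):
            raise ValueError("negative inter-photon interval within a burst")
        self.dt_ms = dt

    @property
    def n_bursts(self) -> int:
        return int(self.ptr.size - 1)

    @property
    def n_photons(self) -> int:
        return int(self.times_ms.size)

    @classmethod
    def from_bursts(cls, data: PhotonData,
                    bursts: list[Burst]) -> "BurstPhotons":
        times_ms = data.times_s * 1e3
        t_parts, s_parts, ptr = [], [], [0]
        for b in bursts:
            t_parts.append(times_ms[b.start:b.stop])
            s_parts.append(data.streams[b.start:b.stop].astype(np.int64))
            ptr.append(ptr[-1] + (b.stop - b.start))
        if not bursts:
            return cls(np.empty(0), np.empty(0, np.int64),
                       np.array([0], np.int64), data.clock_period)
        return cls(np.concatenate(t_parts), np.concatenate(s_parts),
                   np.array(ptr, np.int64), data.clock_period)

    def burst_es(self) -> np.ndarray:
        """Per-burst raw (E, S) used to seed emission initialization."""
        out = np.empty((self.n_bursts, 2))
        for b in range(self.n_bursts):
            st = self.streams[self.ptr[b]:self.ptr[b + 1]]
            n_dd = np.count_nonzero(st == DEX_DEM)
            n_da = np.count_nonzero(st == DEX_AEM)
            n_aa = np.count_nonzero(st == AEX_AEM)
            dex = n_dd + n_da
            out[b, 0] = n_da / dex if dex else np.nan
            out[b, 1] = dex / (dex + n_aa) if dex + n_aa else np.nan
        return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _propagator(u, uinv, ea, out):
    n = u.shape[0]
    for x in range(n):
        for y in range(n):
            acc = 0.0j
            for a in range(n):
                acc += u[x, a] * ea[a] * uinv[a, y]
            v = acc.real
            out[x, y] = v if v > 0.0 else 0.0


@njit(cache=True)
def _forward_loglik(dt, streams, ptr, pi, b_emit, u, uinv, mu):
    n = pi.size
    loglik = 0.0
    alpha = np.empty(n)
    tmp = np.empty(n)
    p = np.empty((n, n))
    ea = np.empty(n, dtype=np.complex128)
    for bi in range(ptr.size - 1):
        s0, s1 = ptr[bi], ptr[bi + 1]
        c = streams[s0]
        tot = 0.0
        for i in range(n):
            alpha[i] = pi[i] * b_emit[i, c]
            tot += alpha[i]
        if tot <= 0.0:
            return -np.inf
        loglik += np.log(tot)
        for i in range(n):
            alpha[i] /= tot
        for k in range(s0 + 1, s1):
            for a in range(n):
                ea[a] = np.exp(mu[a] * dt[k])
            _propagator(u, uinv, ea, p)
            c = streams[k]
            tot = 0.0
            for j in range(n):
                acc = 0.0
                for i in range(n):
                    acc += alpha[i] * p[i, j]
                tmp[j] = acc * b_emit[j, c]
                tot += tmp[j]
            if tot <= 0.0:
                return -np.inf
            loglik += np.log(tot)
            for j in range(n):
                alpha[j] = tmp[j] / tot
    return loglik


@njit(cache=True)
def _estep(dt, streams, ptr, pi, b_emit, q, u, uinv, mu):
    """One exact E-step; returns loglik and expected sufficient statistics.

    The expected time per state and expected transition counts over each
    inter-photon interval use the spectral integrals
    ∫_0^t e^{μ_a s} e^{μ_b (t-s)} ds = (e^{μ_a t} - e^{μ_b t})/(μ_a - μ_b).
    """
    n = pi.size
    n_ph = dt.size
    nb = ptr.size - 1
    alpha = np.empty((n_ph, n))
    scales = np.empty(n_ph)
    p = np.empty((n, n))
    ea = np.empty(n, dtype=np.complex128)
    loglik = 0.0
    # forward
    for bi in range(nb):
        s0, s1 = ptr[bi], ptr[bi + 1]
        c = streams[s0]
        tot = 0.0
        for i in range(n):
            alpha[s0, i] = pi[i] * b_emit[i, c]
            tot += alpha[s0, i]
        scales[s0] = tot
        loglik += np.log(tot)
        for i in range(n):
            alpha[s0, i] /= tot
        for k in range(s0 + 1, s1):
            for a in range(n):
                ea[a] = np.exp(mu[a] * dt[k])
            _propagator(u, uinv, ea, p)
            c = streams[k]
            tot = 0.0
            for j in range(n):
                acc = 0.0
                for i in range(n):
                    acc += alpha[k - 1, i] * p[i, j]
                alpha[k, j] = acc * b_emit[j, c]
                tot += alpha[k, j]
            scales[k] = tot
            loglik += np.log(tot)
            for j in range(n):
                alpha[k, j] /= tot
    # backward + statistics
    e_time = np.zeros(n)
    e_jump = np.zeros((n, n))
    e_emit = np.zeros((n, 3))
    e_init = np.zeros(n)
    beta = np.empty(n)
    beta_prev = np.empty(n)
    v = np.empty(n)
    iab = np.empty((n, n), dtype=np.complex128)
    m1 = np.empty((n, n), dtype=np.complex128)
    m2 = np.empty((n, n), dtype=np.complex128)
    t1 = np.empty((n, n), dtype=np.complex128)
    for bi in range(nb):
        s0, s1 = ptr[bi], ptr[bi + 1]
        for i in range(n):
            beta[i] = 1.0
        c = streams[s1 - 1]
        for i in range(n):
            e_emit[i, c] += alpha[s1 - 1, i]  # gamma at last photon
        for k in range(s1 - 1, s0, -1):
            tk = dt[k]
            for a in range(n):
                ea[a] = np.exp(mu[a] * tk)
            _propagator(u, uinv, ea, p)
            c = streams[k]
            sc = scales[k]
            for y in range(n):
                v[y] = b_emit[y, c] * beta[y] / sc
            # beta at k-1
            for x in range(n):
                acc = 0.0
                for y in range(n):
                    acc += p[x, y] * v[y]
                beta_prev[x] = acc
            # gamma at k-1 -> emission stats
            c_prev = streams[k - 1]
            for i in range(n):
                e_emit[i, c_prev] += alpha[k - 1, i] * beta_prev[i]
            # interval statistics
            for a in range(n):
                for b in range(n):
                    d = mu[a] - mu[b]
                    if abs(d) > _EIG_DEGENERACY_TOL:
                        iab[a, b] = (ea[a] - ea[b]) / d
                    else:
                        iab[a, b] = tk * ea[a]
            # m1[a, i] = (sum_x alpha[k-1,x] u[x,a]) * uinv[a, i]
            for a in range(n):
                acc = 0.0j
                for x in range(n):
                    acc += alpha[k - 1, x] * u[x, a]
                for i in range(n):
                    m1[a, i] = acc * uinv[a, i]
            # m2[b, j] = u[j, b] * (sum_y uinv[b, y] v[y])
            for b in range(n):
                acc = 0.0j
                for y in range(n):
                    acc += uinv[b, y] * v[y]
                for j in range(n):
                    m2[b, j] = u[j, b] * acc
            # t1[b, i] = sum_a m1[a, i] * iab[a, b]
            for b in range(n):
                for i in range(n):
                    acc = 0.0j
                    for a in range(n):
                        acc += m1[a, i] * iab[a, b]
                    t1[b, i] = acc
            for i in range(n):
                for j in range(n):
                    acc = 0.0j
                    for b in range(n):
                        acc += t1[b, i] * m2[b, j]
                    s_ij = acc.real
                    if i == j:
                        if s_ij > 0.0:
                            e_time[i] += s_ij
                    elif q[i, j] > 0.0 and s_ij > 0.0:
                        e_jump[i, j] += q[i, j] * s_ij
            for i in range(n):
                beta[i] = beta_prev[i]
        for i in range(n):
            e_init[i] += alpha[s0, i] * beta[i]
    return loglik, e_time, e_jump, e_emit, e_init


@njit(cache=True)
def _viterbi(dt, streams, ptr, pi, b_emit, u, uinv, mu):
    n = pi.size
    n_ph = dt.size
    path = np.empty(n_ph, dtype=np.int64)
    back = np.empty((n_ph, n), dtype=np.int64)
    delta = np.empty(n)
    delta_new = np.empty(n)
    p = np.empty((n, n))
    ea = np.empty(n, dtype=np.complex128)
    for bi in range(ptr.size - 1):
        s0, s1 = ptr[bi], ptr[bi + 1]
        c = streams[s0]
        for i in range(n):
            delta[i] = np.log(pi[i] * b_emit[i, c])
        for k in range(s0 + 1, s1):
            for a in range(n):
                ea[a] = np.exp(mu[a] * dt[k])
            _propagator(u, uinv, ea, p)
            c = streams[k]
            for j in range(n):
                best = -np.inf
                arg = 0
                for i in range(n):
                    cand = delta[i] + np.log(p[i, j])
                    if cand > best:
                        best = cand
                        arg = i
                delta_new[j] = best + np.log(b_emit[j, c])
                back[k, j] = arg
            for j in range(n):
                delta[j] = delta_new[j]
        best = -np.inf
        arg = 0
        for i in range(n):
            if delta[i] > best:
                best = delta[i]
                arg = i
        path[s1 - 1] = arg
        for k in range(s1 - 1, s0, -1):
            path[k - 1] = back[k, path[k]]
    return path


# ---------------------------------------------------------------------------
# Likelihood / fitting / decoding API
# ---------------------------------------------------------------------------

def _eig(model: H2MMModel):
    q = model.generator
    mu, u = np.linalg.eig(q.astype(float))
    try:
        uinv = np.linalg.inv(u)
    except np.linalg.LinAlgError:
        # near-defective generator: tiny symmetric perturbation
        mu, u = np.linalg.eig(q + 1e-12 * np.eye(q.shape[0]))
        uinv = np.linalg.inv(u)
    return mu.astype(np.complex128), u.astype(np.complex128), \
        uinv.astype(np.complex128)


def burst_log_likelihood(model: H2MMModel, ticks, streams) -> float:
    """Log-likelihood of one burst's photon record under the model."""
    ticks = np.asarray(ticks, dtype=np.int64)
    streams = np.asarray(streams, dtype=np.int64)
    if ticks.size == 0:
        raise ValueError("burst must contain at least one photon")
    if np.any(np.diff(ticks) < 0):
        raise ValueError("negative inter-photon interval")
    dt = np.zeros(ticks.size)
    dt[1:] = np.diff(ticks) * model.clock_period * 1e3
    ptr = np.array([0, ticks.size], dtype=np.int64)
    mu, u, uinv = _eig(model)
    return float(_forward_loglik(dt, streams, ptr, model.pi,
                                 model.emissions, u, uinv, mu))


def total_log_likelihood(model: H2MMModel, photons: BurstPhotons) -> float:
    mu, u, uinv = _eig(model)
    return float(_forward_loglik(photons.dt_ms, photons.streams, photons.ptr,
                                 model.pi, model.emissions, u, uinv, mu))


@dataclass
class FitResult:
    model: H2MMModel
    loglik_trace: list
    converged: bool
    n_iter: int
    n_photons: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _em_iterations(model: H2MMModel, photons: BurstPhotons, n_iter: int,
                   tol: float):
    """Run up to ``n_iter`` EM updates; yields the loglik trace."""
    trace = []
    rates = model.rates_per_ms.copy()
    b_emit = model.emissions.copy()
    pi = model.pi.copy()
    n = pi.size
    converged = False
    for _ in range(n_iter):
        current = H2MMModel(rates, b_emit, pi,
                            clock_period=model.clock_period)
        mu, u, uinv = _eig(current)
        loglik, e_time, e_jump, e_emit, e_init = _estep(
            photons.dt_ms, photons.streams, photons.ptr,
            pi, b_emit, current.generator, u, uinv, mu,
        )
        if not np.isfinite(loglik):
            raise FloatingPointError(
                f"non-finite log-likelihood during EM (loglik={loglik}); "
                f"rates={rates.tolist()}"
            )
        trace.append(float(loglik))
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # M-step
        pi = np.clip(e_init, 1e-12, None)
        pi = pi / pi.sum()
        b_emit = np.clip(e_emit, 1e-12, None)
        b_emit = b_emit / b_emit.sum(axis=1, keepdims=True)
        new_rates = np.zeros_like(rates)
        for i in range(n):
            if e_time[i] > 1e-12:
                new_rates[i] = e_jump[i] / e_time[i]
        np.fill_diagonal(new_rates, 0.0)
        rates = new_rates
    final = H2MMModel(rates, b_emit, pi, clock_period=model.clock_period)
    return final, trace, converged


def _kmeans_es(points: np.ndarray, k: int, rng: np.random.Generator,
               n_iter: int = 30) -> np.ndarray:
    """Plain k-means on burst (E, S) points; returns k centers."""
    pts = points[np.all(np.isfinite(points), axis=1)]
    if pts.shape[0] < k:
        return rng.uniform(0.1, 0.9, size=(k, 2))
    centers = pts[rng.choice(pts.shape[0], size=k, replace=False)]
    for _ in range(n_iter):
        d = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d.argmin(axis=1)
        for j in range(k):
            sel = pts[assign == j]
            if sel.shape[0]:
                centers[j] = sel.mean(axis=0)
            else:
                centers[j] = pts[rng.integers(pts.shape[0])]
    return centers


def initial_model(photons: BurstPhotons, n_states: int,
                  rng: np.random.Generator, jitter: float = 0.0,
                  dwell_guess_ms: float = 1.0) -> H2MMModel:
    """Seeded starting point: uniform π, 1 ms dwell guesses, k-means (E, S).

    Emission rows come from k-means clustering of burst-level (E_raw,
    S_raw), optionally jittered for multi-start fitting.
    """
    n = n_states
    pi = np.full(n, 1.0 / n)
    rates = np.full((n, n), 1.0 / dwell_guess_ms / max(n - 1, 1))
    np.fill_diagonal(rates, 0.0)
    if jitter > 0:
        rates = rates * rng.lognormal(0.0, 0.5, size=(n, n))
        np.fill_diagonal(rates, 0.0)
    centers = _kmeans_es(photons.burst_es(), n, rng)
    if jitter > 0:
        centers = centers + rng.normal(0.0, jitter, size=centers.shape)
    centers = np.clip(centers, 0.02, 0.98)
    b = np.array([H2MMModel.emission_row(e, s) for e, s in centers])
    b = np.clip(b, 1e-6, None)
    b = b / b.sum(axis=1, keepdims=True)
    return H2MMModel(rates, b, pi, clock_period=photons.clock_period)


def fit_model(
    photons: BurstPhotons,
    n_states: int | None = None,
    initial: H2MMModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 3000,
    restarts: int = 5,
    pre_iter: int = 30,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood fit of (π, Q, B) at fixed state count by EM.

    Runs ``restarts`` seeded initializations for ``pre_iter`` iterations
    each, then continues the best to convergence (per-iteration gain below
    ``tol``) or ``max_iter``.  EM guarantees a non-decreasing likelihood,
    so the final model's likelihood is at least the initial one's.
    """
    if photons.n_photons == 0:
        raise ValueError("no photons to fit")
    rng = np.random.default_rng(seed)
    if initial is not None:
        candidates = [(initial, [], False)]
    else:
        if n_states is None:
            raise ValueError("either n_states or an initial model is needed")
        inits = [initial_model(photons, n_states, rng,
                               jitter=0.0 if r == 0 else 0.05)
                 for r in range(max(restarts, 1))]
        candidates = []
        for m in inits:
            mod, trace, conv = _em_iterations(m, photons,
                                              min(pre_iter, max_iter), tol)
            candidates.append((mod, trace, conv))
    best = max(candidates, key=lambda c: c[1][-1] if c[1] else -np.inf)
    model, trace, converged = best
    if not converged and len(trace) < max_iter:
        model, trace2, converged = _em_iterations(
            model, photons, max_iter - len(trace), tol)
        trace = trace + trace2
    return FitResult(model=model, loglik_trace=trace, converged=converged,
                     n_iter=len(trace), n_photons=photons.n_photons)


@dataclass
class StatePath:
    """Viterbi state indices per photon, per burst."""

    paths: list  # list of int arrays, one per burst
    n_states: int

    def flat(self) -> np.ndarray:
        return np.concatenate(self.paths) if self.paths else np.empty(0, int)


def viterbi_paths(model: H2MMModel, photons: BurstPhotons) -> StatePath:
    """Most likely state sequence per burst (deterministic given model)."""
    mu, u, uinv = _eig(model)
    flat = _viterbi(photons.dt_ms, photons.streams, photons.ptr,
                    model.pi, model.emissions, u, uinv, mu)
    paths = [flat[photons.ptr[b]:photons.ptr[b + 1]]
             for b in range(photons.n_bursts)]
    return StatePath(paths=paths, n_states=model.n_states)


def conformational_burst_mask(
    model: H2MMModel, photons: BurstPhotons
) -> np.ndarray:
    """Mask of bursts whose Viterbi path stays in the open/closed states.

    Requires a labelled model (``state_labels`` set, e.g. from
    :func:`classify_states`).  Bursts visiting a photophysical state are
    either donor-only / acceptor-only molecules or artefacts in which a
    dual-labelled molecule co-occurs with another species; both are
    excluded from conformational kinetics.  The returned boolean mask
    selects bursts for a second, conformational-only fit.
    """
    if model.state_labels is None:
        raise ValueError("model.state_labels must be set; run classify_states")
    conf = {i for i, lab in enumerate(model.state_labels)
            if lab in ("open", "closed")}
    paths = viterbi_paths(model, photons).paths
    mask = np.array([set(int(s) for s in np.unique(p)) <= conf
                     for p in paths], dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# Model-order selection
# ---------------------------------------------------------------------------

def n_free_parameters(n_states: int) -> int:
    """Free parameters: N(N-1) rates + 2N emission + (N-1) initial probs."""
    return n_states * (n_states - 1) + 2 * n_states + (n_states - 1)


@dataclass
class ModelSelection:
    bic: dict
    bic_prime: dict
    chosen_n: int
    threshold: float
    fits: dict
    failed: list = field(default_factory=list)


def bic_prime_from_bic(bic: dict) -> dict:
    """BIC'(N) = (BIC(N) - min BIC) / |min BIC| (0 at the minimum)."""
    bic_min = min(bic.values())
    return {n: (v - bic_min) / abs(bic_min) for n, v in bic.items()}


def select_states(
    photons: BurstPhotons,
    n_range=range(1, 5),
    threshold: float = 0.005,
    **fit_kwargs,
) -> ModelSelection:
    """Choose the number of state classes by normalized BIC.

    The smallest candidate with BIC' below ``threshold`` is selected; fits
    that fail are flagged and selection proceeds on the rest.
    """
    bic, fits, failed = {}, {}, []
    for n in n_range:
        try:
            fit = fit_model(photons, n_states=n, **fit_kwargs)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("fit with %d states failed: %s", n, exc)
            failed.append(n)
            continue
        fits[n] = fit
        bic[n] = -2.0 * fit.loglik + \
            n_free_parameters(n) * np.log(photons.n_photons)
    if not bic:
        raise ValueError("all candidate fits failed")
    bic_p = bic_prime_from_bic(bic)
    passing = sorted(n for n, v in bic_p.items() if v < threshold)
    chosen = passing[0] if passing else min(bic, key=bic.get)
    return ModelSelection(bic=bic, bic_prime=bic_p, chosen_n=chosen,
                          threshold=threshold, fits=fits, failed=failed)
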