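"""Photon data model and container I/O.

Diffusion-based confocal smFRET experiments with pulsed interleaved
excitation (PIE) record, for every detected photon, a macrotime (an integer
number of clock ticks since the start of the acquisition) and a stream label
identifying the excitation/emission channel combination:

* ``DexDem`` — donor excitation, donor emission,
* ``DexAem`` — donor excitation, acceptor emission (FRET photons),
* ``AexAem`` — acceptor excitation, acceptor emission.

Two on-disk dialects are supported: a photon-HDF5-style container (groups
for timestamps, stream codes and setup metadata) and a human-diffable TSV
with a small header.  Both round-trip timestamps and streams bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

logger = logging.getLogger("secgate")

#: Canonical stream order; integer codes are indices into this tuple.
STREAMS = ("DexDem", "DexAem", "AexAem")
DEX_DEM, DEX_AEM, AEX_AEM = 0, 1, 2

#: Default macrotime clock: 20 MHz (50 ns per tick).  The instrument clock is
#: configurable everywhere; this is only a plumbing default.
DEFAULT_CLOCK_PERIOD = 1.0 / 20e6


@dataclass
class PhotonData:
    """Timestamped, stream-labelled photon record for one measurement.

    Parameters
    ----------
    timestamps
        Integer clock ticks, non-decreasing, all >= 0.
    streams
        Per-photon stream code (0 = DexDem, 1 = DexAem, 2 = AexAem).
    clock_period
        Seconds per clock tick (> 0).
    acquisition_duration
        Length of the measurement in seconds.
    condition_label
        Free-text condition tag, e.g. ``"SecYEG:A:ATP"``.
    repeat_id
        Technical-repeat index.
    ground_truth
        Optional simulator annotations: a dict with per-photon arrays
        (``state``: hidden-state index, -1 for background photons;
        ``species``: species index per photon) and optionally a
        ``burst_spans`` array of true (start, stop) times in seconds.
    """

    timestamps: np.ndarray
    streams: np.ndarray
    clock_period: float = DEFAULT_CLOCK_PERIOD
    acquisition_duration: float = 0.0
    condition_label: str = ""
    repeat_id: int = 0
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.streams = np.asarray(self.streams, dtype=np.int8)
        if self.acquisition_duration == 0.0 and self.timestamps.size:
            self.acquisition_duration = float(
                self.timestamps[-1] * self.clock_period
            )

    @property
    def n_photons(self) -> int:
        return int(self.timestamps.size)

    @property
    def times_s(self) -> np.ndarray:
        """Photon arrival times in seconds."""
        return self.timestamps * self.clock_period

    def validate(self) -> list[str]:
        return validate_photon_data(self)

    def require_valid(self) -> "PhotonData":
        problems = self.validate()
        if problems:
            raise ValueError("invalid PhotonData: " + "; ".join(problems))
        return self


@dataclass
class Burst:
    """Half-open photon index range [start, stop) into one PhotonData."""

    start: int
    stop: int
    n_dd: int
    n_da: int
    n_aa: int
    start_ms: float
    stop_ms: float

    @property
    def size(self) -> int:
        return self.stop - self.start

    @property
    def duration_ms(self) -> float:
        return self.stop_ms - self.start_ms


@dataclass
class BurstMetrics:
    """Raw (uncorrected) burst quantities.

    ``E_raw = n_DA / (n_DD + n_DA)`` is the raw FRET efficiency and
    ``S_raw = (n_DD + n_DA) / (n_DD + n_DA + n_AA)`` the raw stoichiometry.
    ``E_raw`` is undefined (``e_defined = False``) when the burst has no
    donor-excitation photons.
    """

    e_raw: float
    s_raw: float
    size: int
    duration_ms: float
    e_defined: bool = True
    s_defined: bool = True


def validate_photon_data(data: PhotonData) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    problems: list[str] = []
    ts, st = data.timestamps, data.streams
    if ts.shape != st.shape:
        problems.append(
            f"timestamps ({ts.size}) and streams ({st.size}) differ in length"
        )
    if data.clock_period <= 0:
        problems.append(f"clock_period must be > 0, got {data.clock_period}")
    if ts.size:
        if ts[0] < 0:
            problems.append(f"negative timestamp at photon 0: {ts[0]}")
        bad = np.nonzero(np.diff(ts) < 0)[0]
        if bad.size:
            problems.append(
                f"non-monotonic timestamps at photon {int(bad[0]) + 1}"
            )
        if data.acquisition_duration > 0 and data.clock_period > 0:
            max_tick = data.acquisition_duration / data.clock_period
            over = np.nonzero(ts > max_tick)[0]
            if over.size:
                problems.append(
                    f"timestamp exceeds acquisition window at photon "
                    f"{int(over[0])}"
                )
    bad_stream = np.nonzero((st < 0) | (st >= len(STREAMS)))[0]
    if bad_stream.size:
        problems.append(
            f"unknown stream code at photon {int(bad_stream[0])}: "
            f"{int(st[bad_stream[0]])}"
        )
    if data.ground_truth is not None:
        for key in ("state", "species"):
            arr = data.ground_truth.get(key)
            if arr is not None and np.asarray(arr).shape[0] != ts.size:
                problems.append(
                    f"ground_truth[{key!r}] length {np.asarray(arr).shape[0]} "
                    f"!= n_photons {ts.size}"
                )
    return problems


# ---------------------------------------------------------------------------
# HDF5-style dialect
# ---------------------------------------------------------------------------

def _write_hdf5(data: PhotonData, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        pd_grp = h5.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=data.timestamps)
        pd_grp.create_dataset("detectors", data=data.streams)
        setup = h5.create_group("setup")
        setup.attrs["clock_period"] = data.clock_period
        setup.attrs["acquisition_duration"] = data.acquisition_duration
        setup.attrs["condition_label"] = data.condition_label
        setup.attrs["repeat_id"] = data.repeat_id
        setup.attrs["stream_names"] = ",".join(STREAMS)
        if data.ground_truth is not None:
            gt = h5.create_group("ground_truth")
            for key, arr in data.ground_truth.items():
                gt.create_dataset(key, data=np.asarray(arr))


def _read_hdf5(path: Path) -> PhotonData:
    with h5py.File(path, "r") as h5:
        try:
            ts = h5["photon_data/timestamps"][()]
            st = h5["photon_data/detectors"][()]
        except KeyError as exc:
            raise ValueError(
                f"{path}: malformed container, missing {exc.args[0]!r}"
            ) from exc
        kwargs: dict = {}
        if "setup" in h5:
            attrs = h5["setup"].attrs
            kwargs["clock_period"] = float(
                attrs.get("clock_period", DEFAULT_CLOCK_PERIOD)
            )
            kwargs["acquisition_duration"] = float(
                attrs.get("acquisition_duration", 0.0)
            )
            kwargs["condition_label"] = str(attrs.get("condition_label", ""))
            kwargs["repeat_id"] = int(attrs.get("repeat_id", 0))
        else:
            logger.warning("%s: no setup group; using default metadata", path)
        gt = None
        if "ground_truth" in h5:
            gt = {key: h5["ground_truth"][key][()] for key in h5["ground_truth"]}
        return PhotonData(timestamps=ts, streams=st, ground_truth=gt, **kwargs)


# ---------------------------------------------------------------------------
# Tabular dialect: header lines '# key\tvalue', then 'tick\tstream' rows
# ---------------------------------------------------------------------------

def _write_tabular(data: PhotonData, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# clock_period\t{data.clock_period!r}\n")
        fh.write(f"# acquisition_duration\t{data.acquisition_duration!r}\n")
        fh.write(f"# condition_label\t{data.condition_label}\n")
        fh.write(f"# repeat_id\t{data.repeat_id}\n")
        fh.write("tick\tstream\n")
        for t, s in zip(data.timestamps, data.streams):
            fh.write(f"{int(t)}\t{int(s)}\n")


def _read_tabular(path: Path) -> PhotonData:
    meta: dict = {}
    ticks: list[int] = []
    codes: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    key, value = line[1:].strip().split("\t")
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    ) from exc
                meta[key] = value
                continue
            if line.startswith("tick"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'tick\\tstream', got {line!r}"
                )
            try:
                ticks.append(int(parts[0]))
                codes.append(int(parts[1]))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer record {line!r}"
                ) from exc
    if "clock_period" not in meta:
        logger.warning("%s: no clock_period header; using default", path)
    return PhotonData(
        timestamps=np.array(ticks, dtype=np.int64),
        streams=np.array(codes, dtype=np.int8),
        clock_period=float(meta.get("clock_period", DEFAULT_CLOCK_PERIOD)),
        acquisition_duration=float(meta.get("acquisition_duration", 0.0)),
        condition_label=meta.get("condition_label", ""),
        repeat_id=int(meta.get("repeat_id", 0)),
    )


def write_photon_data(
    data: PhotonData, path: str | Path, dialect: str = "hdf5"
) -> Path:
    """Write a PhotonData record; returns the path written.

    ``dialect`` is ``"hdf5"`` (photon-HDF5-style container) or ``"tabular"``
    (TSV; note ground-truth annotations are only preserved by the HDF5
    dialect).
    """
    path = Path(path)
    if dialect == "hdf5":
        _write_hdf5(data, path)
    elif dialect == "tabular":
        _write_tabular(data, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_photon_data(path: str | Path, dialect: str = "hdf5") -> PhotonData:
    """Read and validate a PhotonData record from disk."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "hdf5":
        data = _read_hdf5(path)
    elif dialect == "tabular":
        data = _read_tabular(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return data.require_valid()


def burst_metrics(burst: Burst) -> BurstMetrics:
    """Raw FRET efficiency and stoichiometry of one burst.

    E_raw = n_DA/(n_DD+n_DA); S_raw = (n_DD+n_DA)/(n_DD+n_DA+n_AA).
    Degenerate denominators set the corresponding ``*_defined`` flag.
    """
    n_dex = burst.n_dd + burst.n_da
    total = n_dex + burst.n_aa
    if n_dex == 0:
        e_raw, e_def = np.nan, False
    else:
        e_raw, e_def = burst.n_da / n_dex, True
    if total == 0:
        s_raw, s_def = np.nan, False
    else:
        s_raw, s_def = n_dex / total, True
    return BurstMetrics(
        e_raw=e_raw,
        s_raw=s_raw,
        size=burst.size,
        duration_ms=burst.duration_ms,
        e_defined=e_def,
        s_defined=s_def,
    )
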