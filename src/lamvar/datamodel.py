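"""Core data containers and readers/writers.

Conventions
-----------
* Time in milliseconds, stimulus onset at 0; spike times are stimulus-locked,
  negative times are pre-stimulus.
* Every trial covers the pre-stimulus baseline [-400, 0) ms and the stimulus
  period [0, 500) ms.
* Counting windows are half-open, [start, end): a spike exactly at ``start``
  is counted, one exactly at ``end`` is not.
* Layer labels come from the fixed vocabulary {SG, G, IG, unassigned}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

LAYERS = ("SG", "G", "IG")
LAYER_VOCAB = LAYERS + ("unassigned",)

BASELINE_WINDOW_MS = (-400.0, 0.0)
STIM_WINDOW_MS = (50.0, 450.0)       # default analysis window
FIG_AVG_WINDOW_MS = (50.0, 350.0)    # alternative averaging window
TIME_RESOLUTION_MS = 0.1


class SchemaError(ValueError):
    """A session file or table violates the container schema."""


@dataclass(frozen=True)
class UnitRecord:
    unit_id: str
    penetration: int
    channel: int
    depth_um: float
    layer: str = "unassigned"

    def __post_init__(self) -> None:
        if self.layer not in LAYER_VOCAB:
            raise SchemaError(
                f"unit {self.unit_id}: layer {self.layer!r} not in {LAYER_VOCAB}")


@dataclass
class TrialSpikeData:
    """Spike times for units x diameters x trials.

    ``spikes[u][d]`` is a list of per-trial 1-D arrays of spike times (ms).
    """

    units: list[UnitRecord]
    diameters: np.ndarray
    spikes: list[list[list[np.ndarray]]]
    t_start_ms: float = BASELINE_WINDOW_MS[0]
    t_stop_ms: float = 500.0

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.diameters) <= 0):
            raise SchemaError("diameters must be strictly increasing")
        if np.any(self.diameters <= 0):
            raise SchemaError("diameters must be positive")
        if self.t_start_ms > BASELINE_WINDOW_MS[0] or self.t_stop_ms < 500.0:
            raise SchemaError(
                "trials must cover the baseline [-400, 0) ms and stimulus [0, 500) ms")
        if len(self.spikes) != len(self.units):
            raise SchemaError("spikes outer dimension must match units")
        for u, per_unit in zip(self.units, self.spikes):
            if len(per_unit) != self.diameters.size:
                raise SchemaError(f"unit {u.unit_id}: expected one trial list per diameter")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def n_trials(self, diameter_index: int = 0) -> int:
        return len(self.spikes[0][diameter_index])

    def units_in_layer(self, layer: str) -> list[int]:
        return [i for i, u in enumerate(self.units) if u.layer == layer]


@dataclass
class SpikeCountTable:
    """Per-trial spike counts in a named window; shape (units, diameters, trials)."""

    counts: np.ndarray
    window_ms: tuple[float, float]
    label: str = "custom"
    unit_ids: list[str] = field(default_factory=list)
    diameters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise SchemaError("counts must be 3-D (units, diameters, trials)")
        if np.any(self.counts < 0):
            raise SchemaError("counts must be non-negative")
        a, b = self.window_ms
        if not a < b:
            raise SchemaError(f"inverted window {self.window_ms}")

    @property
    def duration_ms(self) -> float:
        return self.window_ms[1] - self.window_ms[0]


@dataclass
class SizeTuningCurve:
    """Per-unit size tuning of rate, Fano-factor and (optionally) shared variance."""

    unit_id: str
    diameters: np.ndarray
    rate_hz: np.ndarray
    fano: np.ndarray
    fano_boot_sd: np.ndarray | None = None
    baseline_rate_hz: float = np.nan
    baseline_fano: float = np.nan
    shared_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        self.fano = np.asarray(self.fano, dtype=float)
        if self.rate_hz.shape != self.diameters.shape or self.fano.shape != self.diameters.shape:
            raise SchemaError("curve arrays must share the diameter axis")
        if np.any(self.rate_hz < 0) or np.any(self.fano < 0):
            raise SchemaError("rates and Fano-factors must be >= 0")


# ---------------------------------------------------------------------------
# counting


def count_in_window(data: TrialSpikeData, start_ms: float, end_ms: float,
                    label: str = "custom") -> SpikeCountTable:
    """Count spikes per trial inside the half-open window [start_ms, end_ms)."""
    if not start_ms < end_ms:
        raise ValueError(f"inverted window [{start_ms}, {end_ms})")
    if start_ms < data.t_start_ms or end_ms > data.t_stop_ms:
        raise ValueError("window outside the recorded span")
    n_trials = data.n_trials()
    counts = np.zeros((data.n_units, data.diameters.size, n_trials), dtype=np.int64)
    for ui, per_unit in enumerate(data.spikes):
        for di, trials in enumerate(per_unit):
            for ti, t in enumerate(trials):
                counts[ui, di, ti] = int(np.count_nonzero((t >= start_ms) & (t < end_ms)))
    return SpikeCountTable(
        counts=counts, window_ms=(start_ms, end_ms), label=label,
        unit_ids=[u.unit_id for u in data.units], diameters=data.diameters.copy())


# ---------------------------------------------------------------------------
# HDF5 container

_SCHEMA_VERSION = 1


def save_session(data: TrialSpikeData, path) -> None:
    """Write a session to the HDF5 container.

    Layout: ``/penetrations/<p>/units/<unit_id>`` holds attributes
    (channel, depth_um, layer) and, per diameter index ``d``, datasets
    ``d<d>/times`` (concatenated spike times, ms) and ``d<d>/trial_index``.
    Spike times are stored at 0.1 ms resolution.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _SCHEMA_VERSION
        f.attrs["t_start_ms"] = data.t_start_ms
        f.attrs["t_stop_ms"] = data.t_stop_ms
        f.create_dataset("diameters_deg", data=data.diameters)
        for ui, u in enumerate(data.units):
            g = f.require_group(f"penetrations/{u.penetration}/units/{u.unit_id}")
            g.attrs["channel"] = u.channel
            g.attrs["depth_um"] = u.depth_um
            g.attrs["layer"] = u.layer
            g.attrs["order"] = ui
            for di in range(data.diameters.size):
                trials = data.spikes[ui][di]
                times = np.concatenate(trials) if trials else np.empty(0)
                idx = np.repeat(np.arange(len(trials)), [len(t) for t in trials])
                gd = g.create_group(f"d{di}")
                # 0.1 ms resolution as integer ticks keeps the round trip lossless
                gd.create_dataset("times", data=np.round(times / TIME_RESOLUTION_MS).astype(np.int64))
                gd.create_dataset("trial_index", data=idx.astype(np.int32))
                gd.attrs["n_trials"] = len(trials)


def load_session(path) -> TrialSpikeData:
    """Load a session from the HDF5 container (or the CSV count-table dialect).

    All container invariants are validated; violations raise
    :class:`SchemaError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        raise SchemaError(
            "CSV files hold count tables, not spike times; use load_count_table")
    units: list[tuple[int, UnitRecord, list[list[np.ndarray]]]] = []
    with h5py.File(path, "r") as f:
        if "diameters_deg" not in f:
            raise SchemaError("missing dataset 'diameters_deg'")
        diameters = np.asarray(f["diameters_deg"])
        t_start = float(f.attrs.get("t_start_ms", BASELINE_WINDOW_MS[0]))
        t_stop = float(f.attrs.get("t_stop_ms", 500.0))
        if t_start > BASELINE_WINDOW_MS[0]:
            raise SchemaError("session lacks the [-400, 0) ms baseline segment")
        for pkey, pgrp in f["penetrations"].items():
            for uid, g in pgrp["units"].items():
                layer = str(g.attrs["layer"])
                rec = UnitRecord(unit_id=uid, penetration=int(pkey),
                                 channel=int(g.attrs["channel"]),
                                 depth_um=float(g.attrs["depth_um"]), layer=layer)
                per_unit: list[list[np.ndarray]] = []
                for di in range(diameters.size):
                    gd = g[f"d{di}"]
                    times = np.asarray(gd["times"]) * TIME_RESOLUTION_MS
                    idx = np.asarray(gd["trial_index"])
                    n_tr = int(gd.attrs["n_trials"])
                    per_unit.append([times[idx == t] for t in range(n_tr)])
                units.append((int(g.attrs.get("order", len(units))), rec, per_unit))
    units.sort(key=lambda x: x[0])
    return TrialSpikeData(units=[u[1] for u in units], diameters=diameters,
                          spikes=[u[2] for u in units],
                          t_start_ms=t_start, t_stop_ms=t_stop)


# ---------------------------------------------------------------------------
# flat CSV count table

CSV_COLUMNS = ["penetration", "channel", "layer", "diameter_deg", "trial",
               "count_stim", "count_base"]


def save_count_table(stim: SpikeCountTable, base: SpikeCountTable,
                     units: list[UnitRecord], path) -> None:
    """Write the flat CSV count table (one row per unit x diameter x trial)."""
    rows = []
    for ui, u in enumerate(units):
        for di, d in enumerate(stim.diameters):
            for ti in range(stim.counts.shape[2]):
                rows.append((u.penetration, u.channel, u.layer, float(d), ti,
                             int(stim.counts[ui, di, ti]), int(base.counts[ui, di, ti])))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def load_count_table(path) -> tuple[SpikeCountTable, SpikeCountTable, list[UnitRecord]]:
    """Read the flat CSV dialect back into stimulus/baseline count tables."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"count table missing column(s): {missing}")
    bad = set(df["layer"].unique()) - set(LAYER_VOCAB)
    if bad:
        raise SchemaError(f"unknown layer label(s) {sorted(bad)}; expected one of {LAYER_VOCAB}")
    df = df.sort_values(["penetration", "channel", "diameter_deg", "trial"])
    units = []
    keys = df[["penetration", "channel", "layer"]].drop_duplicates().to_records(index=False)
    diameters = np.sort(df["diameter_deg"].unique())
    n_trials = int(df["trial"].max()) + 1
    stim = np.zeros((len(keys), diameters.size, n_trials), dtype=np.int64)
    base = np.zeros_like(stim)
    for ui, (pen, ch, layer) in enumerate(keys):
        units.append(UnitRecord(unit_id=f"p{pen}c{ch}", penetration=int(pen),
                                channel=int(ch), depth_um=np.nan, layer=str(layer)))
        sub = df[(df.penetration == pen) & (df.channel == ch)]
        for di, d in enumerate(diameters):
            s = sub[sub.diameter_deg == d]
            stim[ui, di, s["trial"].to_numpy()] = s["count_stim"].to_numpy()
            base[ui, di, s["trial"].to_numpy()] = s["count_base"].to_numpy()
    uid = [u.unit_id for u in units]
    return (SpikeCountTable(stim, STIM_WINDOW_MS, "stim", uid, diameters),
            SpikeCountTable(base, BASELINE_WINDOW_MS, "baseline", uid, diameters),
            units)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
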