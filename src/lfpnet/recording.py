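"""Data model and on-disk I/O for multi-channel extracellular recordings.

A :class:`Recording` is a channels x samples voltage matrix (microvolts) with a
sampling rate and a time axis expressed in seconds relative to the drug
injection (t = 0; negative times are pre-drug baseline).  The accompanying
:class:`ElectrodeMap` assigns every channel to an animal, a fine-grained
anatomical structure label, and one of ten broader functional regions.

On disk a recording is a directory containing

* ``data.bin`` -- flat little-endian float32, channel-major (row per channel),
* ``meta.json`` -- fs, t0, channel ids, units, shape,
* optionally ``electrodes.tsv`` -- the electrode map (fixed header).

Vendor acquisition formats (Neuralynx NCS, OpenEphys) are deliberately not
parsed; conversion to this layout is the caller's responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: Fixed vocabulary of functional regions (cognitive-limbic then sensorimotor).
REGIONS = (
    "OlfC", "OFC", "PFC", "vStr", "SepA", "IntTh",
    "SenC", "dStr", "TemAA", "SenTh",
)

EMAP_COLUMNS = (
    "channel_id", "animal_id", "anatomical_label", "region",
    "ap_mm", "ml_mm", "dv_mm", "row", "col",
)


@dataclass
class Recording:
    """Multi-channel voltage time series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    fs
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample in seconds relative to injection.
    channel_ids
        One id string per row of ``data``.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_ids)} channel_ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, channel_id: str) -> np.ndarray:
        return self.data[self.channel_ids.index(str(channel_id))]


@dataclass(frozen=True)
class EpochSpec:
    """Half-open time interval [t_start, t_end) relative to injection."""

    t_start: float
    t_end: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(
                f"t_start ({self.t_start}) must be < t_end ({self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ElectrodeMap:
    """Per-channel anatomical metadata backed by a DataFrame.

    Columns: channel_id, animal_id, anatomical_label, region, ap_mm, ml_mm,
    dv_mm, row, col.  ``region`` must come from :data:`REGIONS`; coordinates
    may be NaN; (row, col) is the position on the 250-um-pitch array.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).copy()
        missing = [c for c in ("channel_id", "animal_id", "anatomical_label", "region")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"electrode map missing columns: {missing}")
        for c in ("ap_mm", "ml_mm", "dv_mm", "row", "col"):
            if c not in df.columns:
                df[c] = np.nan
        df["channel_id"] = df["channel_id"].astype(str)
        if df["channel_id"].duplicated().any():
            dup = df.loc[df["channel_id"].duplicated(), "channel_id"].tolist()
            raise ValueError(f"duplicate channel_ids in electrode map: {dup}")
        bad = sorted(set(df["region"]) - set(REGIONS))
        if bad:
            raise ValueError(
                f"unknown region(s) {bad}; must be one of {list(REGIONS)}"
            )
        self.table = df.loc[:, list(EMAP_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def channel_ids(self) -> list[str]:
        return self.table["channel_id"].tolist()

    def region_of(self, channel_id: str) -> str:
        return self._lookup(channel_id, "region")

    def structure_of(self, channel_id: str) -> str:
        return self._lookup(channel_id, "anatomical_label")

    def animal_of(self, channel_id: str) -> str:
        return str(self._lookup(channel_id, "animal_id"))

    def position_of(self, channel_id: str) -> tuple[float, float]:
        row = self.table.set_index("channel_id").loc[str(channel_id)]
        return float(row["row"]), float(row["col"])

    def _lookup(self, channel_id: str, col: str):
        sel = self.table.loc[self.table["channel_id"] == str(channel_id), col]
        if sel.empty:
            raise KeyError(f"channel {channel_id!r} not in electrode map")
        return sel.iloc[0]

    def structures(self) -> dict[str, list[str]]:
        """Map anatomical structure label -> channel ids (table order)."""
        out: dict[str, list[str]] = {}
        for _, r in self.table.iterrows():
            out.setdefault(r["anatomical_label"], []).append(r["channel_id"])
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ElectrodeMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"channel_id": str,
                                                      "animal_id": str}))


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` to directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(rec.data, dtype="<f4")
    data.tofile(path / "data.bin")
    meta = {
        "format": "lfpnet-recording-v1",
        "fs": float(rec.fs),
        "t0": float(rec.t0),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_ids": rec.channel_ids,
        "units": "uV",
        "dtype": "<f4",
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Load a recording directory written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json under {path}")
    meta = json.loads(meta_path.read_text())
    for key in ("fs", "t0", "n_channels", "n_samples", "channel_ids"):
        if key not in meta:
            raise ValueError(f"meta.json missing field {key!r}")
    if meta["fs"] <= 0:
        raise ValueError(f"invalid metadata: fs={meta['fs']} (must be > 0)")
    raw = np.fromfile(path / "data.bin", dtype=meta.get("dtype", "<f4"))
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"invalid metadata: n_channels*n_samples={n_ch * n_s} "
            f"but data.bin holds {raw.size} samples"
        )
    data = raw.reshape(n_ch, n_s)
    if np.isnan(data).any():
        bad = int(np.isnan(data).sum())
        raise ValueError(f"recording contains {bad} NaN samples; refusing to load")
    return Recording(data=data, fs=float(meta["fs"]), t0=float(meta["t0"]),
                     channel_ids=list(meta["channel_ids"]))


# ---------------------------------------------------------------------------
# Epoch selection / resampling
# ---------------------------------------------------------------------------

def select_epoch(rec: Recording, spec: EpochSpec) -> Recording:
    """Extract the half-open sample interval covering ``spec``.

    The epoch must lie inside the recorded span; out-of-range requests raise
    rather than clip silently.
    """
    i0 = int(round((spec.t_start - rec.t0) * rec.fs))
    n = int(round(spec.duration * rec.fs))
    if i0 < 0 or i0 + n > rec.n_samples:
        raise ValueError(
            f"epoch [{spec.t_start}, {spec.t_end}) s outside recording span "
            f"[{rec.t0}, {rec.t_end}) s"
        )
    return Recording(
        data=rec.data[:, i0:i0 + n],
        fs=rec.fs,
        t0=rec.t0 + i0 / rec.fs,
        channel_ids=list(rec.channel_ids),
    )


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased decimation to ``target_fs`` (<= fs, rational ratio).

    Polyphase filtering (Kaiser window) provides > 40 dB stopband attenuation
    above the new Nyquist; output length is floor(n * target_fs / fs).
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"cannot upsample: target_fs={target_fs} > fs={rec.fs}"
        )
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(np.asarray(rec.data, dtype=float), up, down, axis=1)
    n_out = int(np.floor(rec.n_samples * target_fs / rec.fs))
    return Recording(data=out[:, :n_out], fs=float(target_fs), t0=rec.t0,
                     channel_ids=list(rec.channel_ids))


def lowpass(rec: Recording, cutoff_hz: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth low-pass (used by the connectivity control)."""
    if not 0 < cutoff_hz < rec.fs / 2:
        raise ValueError(f"cutoff must be in (0, fs/2), got {cutoff_hz}")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, np.asarray(rec.data, dtype=float), axis=1)
    return replace(rec, data=data)


# ---------------------------------------------------------------------------
# Region census
# ---------------------------------------------------------------------------

def group_regions(
    emap: ElectrodeMap,
    min_recordings: int = 6,
    min_animals: int = 3,
) -> dict[str, list[str]]:
    """Map region -> channel ids, dropping under-sampled regions.

    A region is retained only with at least ``min_recordings`` channels from
    at least ``min_animals`` distinct animals (defaults follow the inclusion
    rule of the analysis: six recordings from three animals).  Excluded
    regions are logged, not raised.
    """
    kept: dict[str, list[str]] = {}
    df = emap.table
    for region in REGIONS:
        sub = df[df["region"] == region]
        if sub.empty:
            continue
        n_rec = len(sub)
        n_animals = sub["animal_id"].nunique()
        if n_rec >= min_recordings and n_animals >= min_animals:
            kept[region] = sub["channel_id"].tolist()
        else:
            logger.info(
                "region %s excluded: %d recordings from %d animals "
                "(need >=%d from >=%d)",
                region, n_rec, n_animals, min_recordings, min_animals,
            )
    if not kept:
        logger.warning("no region satisfied the inclusion rule")
    return kept
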