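"""Aperiodic power-spectrum parameterization of bipolar LFP signals.

The pipeline: derive bipolar (differential) series from electrode pairs
within a structure, estimate Welch spectrograms, take the median spectrum
over an analysis epoch, iteratively separate periodic humps (oscillations,
mains) from the aperiodic background, and fit the background with the
power law

    y = 10^A / f^B

in log-log space over 1-300 Hz.  A is the offset -- a uniform shift of
log-power across frequencies, a proxy for overall population activity -- and
B is the aperiodic exponent (spectral slope), commonly read as an index of
excitation-inhibition balance.

Fits are performed on log-spaced resampled bins so that every frequency
decade carries equal leverage; on a noiseless power law the fit is exact.
The aperiodic stage uses 8-s Hann windows by default: with 0.125-Hz
resolution the 1-Hz lower fit bound sits far enough from DC that kernel
smoothing of steep (B up to 4) spectra is negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import signal

from .recording import ElectrodeMap, EpochSpec, Recording, select_epoch

logger = logging.getLogger(__name__)

DEFAULT_FIT_RANGE = (1.0, 300.0)
MAINS_HZ = 50.0          # European mains; harmonics are always masked
MAINS_HALF_WIDTH = 2.0


@dataclass
class BipolarSeries:
    """Differential series channel_i - channel_j from one structure."""
    channel_i: str
    channel_j: str
    structure: str
    region: str
    data: np.ndarray
    fs: float
    t0: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.channel_i, self.channel_j)


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray
    source: str = ""
    n_windows: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly ascending")


@dataclass
class Spectrogram:
    times: np.ndarray        # window centers, s relative to injection
    frequencies: np.ndarray
    power: np.ndarray        # (n_windows, n_freqs), uV^2/Hz
    source: str = ""


@dataclass
class AperiodicFit:
    offset: float            # A, log10(uV^2/Hz)
    exponent: float          # B, dimensionless
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE
    r2_loglog: float = np.nan
    excluded_bands: list[tuple[float, float]] = field(default_factory=list)

    def evaluate(self, freqs: np.ndarray) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        return 10.0 ** self.offset / freqs ** self.exponent


@dataclass
class SpectralChange:
    structure: str
    region: str
    delta_offset: float      # median over pairs of (A_post - A_base)
    delta_exponent: float
    fits_baseline: list[AperiodicFit]
    fits_post: list[AperiodicFit]
    pairs: list[tuple[str, str]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_deltas(self) -> tuple[np.ndarray, np.ndarray]:
        da = np.array([p.offset - b.offset
                       for b, p in zip(self.fits_baseline, self.fits_post)])
        db = np.array([p.exponent - b.exponent
                       for b, p in zip(self.fits_baseline, self.fits_post)])
        return da, db


# ---------------------------------------------------------------------------
# Bipolar derivation
# ---------------------------------------------------------------------------

def bipolar_pairs(
    rec: Recording,
    emap: ElectrodeMap,
    mode: str = "all_within_structure",
    channels: list[str] | None = None,
) -> list[BipolarSeries]:
    """Differential series for electrode pairs within each structure.

    ``mode="all_within_structure"`` forms all C(n, 2) same-structure pairs;
    ``mode="neighbors"`` keeps only pairs adjacent on the array (Chebyshev
    distance 1 in (row, col)).  Any signal common to both electrodes cancels
    exactly.  Structures with fewer than two channels are skipped with a log
    entry.
    """
    if mode not in ("all_within_structure", "neighbors"):
        raise ValueError(f"unknown mode {mode!r}")
    allowed = set(channels) if channels is not None else set(rec.channel_ids)
    out: list[BipolarSeries] = []
    for structure, chans in emap.structures().items():
        chans = [c for c in chans if c in allowed]
        if len(chans) < 2:
            logger.info("structure %s skipped: <2 channels", structure)
            continue
        region = emap.region_of(chans[0])
        for ci, cj in combinations(chans, 2):
            if mode == "neighbors":
                ri, coli = emap.position_of(ci)
                rj, colj = emap.position_of(cj)
                if np.isnan([ri, rj, coli, colj]).any():
                    continue
                if max(abs(ri - rj), abs(coli - colj)) != 1:
                    continue
            out.append(BipolarSeries(
                channel_i=ci, channel_j=cj, structure=structure, region=region,
                data=rec.channel(ci) - rec.channel(cj),
                fs=rec.fs, t0=rec.t0,
            ))
    return out


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------

def compute_spectrogram(
    series: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    t0: float = 0.0,
    source: str = "",
) -> Spectrogram:
    """Hann-tapered one-sided PSD per window, density scaling (uV^2/Hz)."""
    series = np.asarray(series, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg < 64:
        raise ValueError("window_s * fs must be >= 64 samples")
    if series.size < nperseg:
        raise ValueError(
            f"series ({series.size} samples) shorter than one window ({nperseg})"
        )
    noverlap = int(round(nperseg * overlap_frac))
    freqs, times, sxx = signal.spectrogram(
        series, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="density", mode="psd",
    )
    return Spectrogram(times=t0 + times, frequencies=freqs,
                       power=sxx.T, source=source)


def median_spectrum(sgram: Spectrogram, epoch: EpochSpec | None = None,
                    debias: bool = False) -> PowerSpectrum:
    """Elementwise median over windows whose centers fall in the epoch.

    For Gaussian signals each window's PSD bin is ~chi^2_2 distributed, so
    the across-window median sits at ln 2 ~ 0.693 of the underlying PSD.
    ``debias=True`` divides by ln 2, keeping the median's robustness to
    transients while restoring the absolute scale; parameter *changes*
    between epochs are unaffected either way.
    """
    if epoch is None:
        mask = np.ones(len(sgram.times), dtype=bool)
    else:
        mask = (sgram.times >= epoch.t_start) & (sgram.times < epoch.t_end)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"no spectrogram windows inside epoch "
            f"[{epoch.t_start}, {epoch.t_end})"
        )
    power = np.median(sgram.power[mask], axis=0)
    if debias:
        power = power / np.log(2.0)
    return PowerSpectrum(
        frequencies=sgram.frequencies,
        power=power,
        source=sgram.source,
        n_windows=n,
    )


# ---------------------------------------------------------------------------
# Power-law fitting and periodic separation
# ---------------------------------------------------------------------------

def _band_mask(freqs: np.ndarray, bands: list[tuple[float, float]]) -> np.ndarray:
    """Boolean mask, True where a frequency falls inside any band."""
    mask = np.zeros_like(freqs, dtype=bool)
    for lo, hi in bands:
        mask |= (freqs >= lo) & (freqs <= hi)
    return mask


def mains_bands(fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                mains_hz: float = MAINS_HZ,
                half_width: float = MAINS_HALF_WIDTH) -> list[tuple[float, float]]:
    """Mains frequency and harmonics inside the fit range."""
    bands = []
    f = mains_hz
    while f - half_width <= fit_range[1]:
        if f + half_width >= fit_range[0]:
            bands.append((f - half_width, f + half_width))
        f += mains_hz
    return bands


def fit_powerlaw(
    spec: PowerSpectrum,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    exclude_bands: list[tuple[float, float]] | None = None,
    n_logbins: int = 100,
) -> AperiodicFit:
    """Least-squares fit of log10(power) on log10(f): A = intercept, B = -slope.

    The spectrum is resampled onto ``n_logbins`` log-spaced frequencies by
    linear interpolation in log-log coordinates (excluded bands are bridged),
    giving each decade equal leverage in the regression.
    """
    lo, hi = fit_range
    freqs, power = spec.frequencies, spec.power
    in_range = (freqs >= lo) & (freqs <= hi)
    if in_range.sum() < 10:
        raise ValueError("need >= 10 spectral bins inside the fit range")
    bad = in_range & (power <= 0)
    if bad.any():
        raise ValueError(
            f"non-positive power at {freqs[bad][:10].tolist()} Hz in fit range"
        )
    keep = in_range
    if exclude_bands:
        keep = keep & ~_band_mask(freqs, list(exclude_bands))
    if keep.sum() < 10:
        raise ValueError("fewer than 10 usable bins after band exclusion")

    logf = np.log10(freqs[keep])
    logp = np.log10(power[keep])
    grid = np.linspace(np.log10(lo), np.log10(hi), n_logbins)
    grid = np.clip(grid, logf[0], logf[-1])
    logp_grid = np.interp(grid, logf, logp)

    slope, intercept = np.polyfit(grid, logp_grid, 1)
    resid = logp_grid - (slope * grid + intercept)
    ss_tot = np.sum((logp_grid - logp_grid.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        offset=float(intercept), exponent=float(-slope),
        fit_range=(lo, hi), r2_loglog=float(r2),
        excluded_bands=list(exclude_bands or []),
    )


def separate_aperiodic(
    spec: PowerSpectrum,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    peak_threshold_sd: float = 2.5,
    max_iters: int = 5,
    mask_mains: bool = True,
) -> tuple[PowerSpectrum, list[tuple[float, float]]]:
    """Iteratively mask periodic humps riding on the 1/f background.

    Each pass fits the power law to the unmasked bins, computes log-power
    residuals, and flags contiguous runs of bins whose residual exceeds
    ``peak_threshold_sd`` standard deviations above the fit; flagged bands
    are masked and the fit repeated until stable or ``max_iters``.  Mains
    harmonics are masked unconditionally.  Returns the masked (aperiodic)
    spectrum restricted to the fit range plus the list of excluded bands.
    """
    lo, hi = fit_range
    freqs, power = spec.frequencies, spec.power
    in_range = (freqs >= lo) & (freqs <= hi)
    bands: list[tuple[float, float]] = mains_bands(fit_range) if mask_mains else []

    for _ in range(max_iters):
        fit = fit_powerlaw(spec, fit_range, exclude_bands=bands)
        usable = in_range & ~_band_mask(freqs, bands)
        resid = np.log10(power[usable]) - np.log10(fit.evaluate(freqs[usable]))
        sd = resid.std()
        if sd == 0:
            break
        flagged = resid > peak_threshold_sd * sd
        if not flagged.any():
            break
        f_use = freqs[usable]
        df = np.median(np.diff(freqs)) if len(freqs) > 1 else 1.0
        new_bands = _contiguous_bands(f_use, flagged, gap=1.5 * df)
        bands = _merge_bands(bands + new_bands)

    masked_frac = _band_mask(freqs[in_range], bands).mean() if in_range.any() else 0.0
    if masked_frac > 0.5:
        logger.warning(
            "more than 50%% of fit-range bins masked as periodic "
            "(%.0f%%); aperiodic fit may be unreliable", 100 * masked_frac,
        )
    keep = in_range & ~_band_mask(freqs, bands)
    aperiodic = PowerSpectrum(frequencies=freqs[keep], power=power[keep],
                              source=spec.source, n_windows=spec.n_windows)
    return aperiodic, bands


def _contiguous_bands(freqs: np.ndarray, flagged: np.ndarray,
                      gap: float) -> list[tuple[float, float]]:
    bands = []
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return bands
    start = prev = idx[0]
    for i in idx[1:]:
        if freqs[i] - freqs[prev] > gap:
            bands.append((freqs[start], freqs[prev]))
            start = i
        prev = i
    bands.append((freqs[start], freqs[prev]))
    # widen point-bands slightly so the offending bin is actually covered
    half = gap / 3.0
    return [(lo - half, hi + half) for lo, hi in bands]


def _merge_bands(bands: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not bands:
        return []
    bands = sorted(bands)
    merged = [bands[0]]
    for lo, hi in bands[1:]:
        plo, phi = merged[-1]
        if lo <= phi:
            merged[-1] = (plo, max(phi, hi))
        else:
            merged.append((lo, hi))
    return merged


def fit_aperiodic(
    spec: PowerSpectrum,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    peak_threshold_sd: float = 2.5,
    max_iters: int = 5,
    mask_mains: bool = True,
) -> AperiodicFit:
    """Convenience: periodic separation followed by the power-law fit."""
    aperiodic, bands = separate_aperiodic(
        spec, fit_range, peak_threshold_sd, max_iters, mask_mains,
    )
    fit = fit_powerlaw(aperiodic, fit_range)
    fit.excluded_bands = bands
    return fit


# ---------------------------------------------------------------------------
# Structure-level contrast
# ---------------------------------------------------------------------------

def structure_spectral_change(
    rec: Recording,
    emap: ElectrodeMap,
    baseline_epoch: EpochSpec,
    post_epoch: EpochSpec,
    mode: str = "all_within_structure",
    channels: list[str] | None = None,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    window_s: float = 8.0,
    overlap_frac: float = 0.5,
    peak_threshold_sd: float = 2.5,
    max_iters: int = 5,
    mask_mains: bool = True,
) -> list[SpectralChange]:
    """Per-structure offset/exponent change between two epochs.

    For every bipolar pair: median Welch spectrum per epoch, periodic
    separation, power-law fit; the structure-level change is the median over
    pairs of the per-pair parameter deltas.
    """
    pairs = bipolar_pairs(rec, emap, mode=mode, channels=channels)
    by_structure: dict[str, list[BipolarSeries]] = {}
    for bp in pairs:
        by_structure.setdefault(bp.structure, []).append(bp)

    changes: list[SpectralChange] = []
    for structure, bps in by_structure.items():
        fits_base, fits_post, pair_ids = [], [], []
        for bp in bps:
            fits = []
            for epoch in (baseline_epoch, post_epoch):
                sub = select_epoch(
                    Recording(data=bp.data[None, :], fs=bp.fs, t0=bp.t0,
                              channel_ids=[f"{bp.channel_i}-{bp.channel_j}"]),
                    epoch,
                )
                sgram = compute_spectrogram(
                    sub.data[0], sub.fs, window_s=window_s,
                    overlap_frac=overlap_frac, t0=sub.t0,
                    source=f"{bp.channel_i}-{bp.channel_j}",
                )
                spec = median_spectrum(sgram, debias=True)
                fits.append(fit_aperiodic(
                    spec, fit_range, peak_threshold_sd, max_iters, mask_mains,
                ))
            fits_base.append(fits[0])
            fits_post.append(fits[1])
            pair_ids.append(bp.pair)
        da = np.median([p.offset - b.offset
                        for b, p in zip(fits_base, fits_post)])
        db = np.median([p.exponent - b.exponent
                        for b, p in zip(fits_base, fits_post)])
        changes.append(SpectralChange(
            structure=structure, region=bps[0].region,
            delta_offset=float(da), delta_exponent=float(db),
            fits_baseline=fits_base, fits_post=fits_post, pairs=pair_ids,
        ))
    return changes
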