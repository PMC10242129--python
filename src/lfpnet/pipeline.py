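"""End-to-end orchestration: recording -> spectral + connectivity -> stats.

A :class:`PipelineConfig` holds every analysis choice (epochs per stage, fit
range, MI window, downsampling target, alpha, mode flags); defaults follow
the standard protocol -- spectral epochs -32..-2 / 30..60 min around the
injection, connectivity epochs -20..-5 / 45..60 min with 2-s windows on
1-kHz monopolar data, fit range 1-300 Hz, alpha 0.05, no multiple-testing
correction (Benjamini-Hochberg available behind a flag).

The statistical unit is the electrode pair pooled within a region.  Pairs
recorded in one animal are not independent samples, so pooled per-region
p-values are anticonservative to a degree that depends on electrode overlap
between pairs; the report carries this caveat, and electrode-disjoint
("neighbors") pairing is available to remove the overlap.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import spectral as spec
from . import stats as st
from .recording import (ElectrodeMap, EpochSpec, Recording, downsample,
                        group_regions, read_recording)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # epochs, s relative to injection (stage-specific protocol defaults)
    spectral_baseline: tuple[float, float] = (-1920.0, -120.0)   # -32..-2 min
    spectral_post: tuple[float, float] = (1800.0, 3600.0)        # 30..60 min
    conn_baseline: tuple[float, float] = (-1200.0, -300.0)       # -20..-5 min
    conn_post: tuple[float, float] = (2700.0, 3600.0)            # 45..60 min
    fit_range: tuple[float, float] = (1.0, 300.0)
    window_s: float = 2.0            # MI window (2 s -> 450 per 15 min)
    spectral_window_s: float = 8.0   # Welch window for the aperiodic stage
    target_fs: float = 1000.0
    bipolar_mode: str = "all_within_structure"
    peak_threshold_sd: float = 2.5
    max_iters: int = 5
    mask_mains: bool = True
    mi_units: str = "bits"
    bias_correct: bool = True
    mi_floor: float = conn.MI_FLOOR_BITS
    alpha: float = 0.05
    min_recordings: int = 6
    min_animals: int = 3
    bh_correct: bool = False
    run_baseline_control: bool = False
    seed: int = 0

    def with_updates(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spectral_baseline", "spectral_post",
                    "conn_baseline", "conn_post", "fit_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineReport:
    spectral_table: pd.DataFrame       # per region: dA, dB, p-values, flags
    spectral_changes: list[spec.SpectralChange]
    pair_table: pd.DataFrame           # per electrode pair MI summary
    region_matrix: pd.DataFrame        # region x region mean ratio
    fit_table: pd.DataFrame            # within/between post-vs-baseline fits
    contrast_table: pd.DataFrame       # global ratio contrasts
    summary: conn.ConnectivitySummary
    control_table: pd.DataFrame | None
    log_lines: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spectral_table.to_csv(out / "spectral_changes.tsv", sep="\t",
                                   index=False, float_format="%.6g")
        self.pair_table.to_csv(out / "pair_connectivity.tsv", sep="\t",
                               index=False, float_format="%.6g")
        self.region_matrix.to_csv(out / "region_matrix.tsv", sep="\t",
                                  float_format="%.6g")
        self.fit_table.to_csv(out / "connectivity_fits.tsv", sep="\t",
                              index=False, float_format="%.6g")
        self.contrast_table.to_csv(out / "connectivity_contrasts.tsv",
                                   sep="\t", index=False, float_format="%.6g")
        if self.control_table is not None:
            self.control_table.to_csv(out / "baseline_control.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        (out / "run.log").write_text("\n".join(self.log_lines) + "\n")
        return out


def _sig_mark(p: float, alpha: float) -> str:
    return "*" if p <= alpha else ""


def run_pipeline(
    cfg: PipelineConfig,
    rec: Recording | str | Path,
    emap: ElectrodeMap | str | Path,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Execute the full analysis and (optionally) write the report bundle.

    Deterministic given identical inputs and config.
    """
    if not isinstance(rec, Recording):
        rec = read_recording(rec)
    if not isinstance(emap, ElectrodeMap):
        emap = ElectrodeMap.from_tsv(emap)

    log: list[str] = [f"config: {asdict(cfg)}"]
    regions = group_regions(emap, cfg.min_recordings, cfg.min_animals)
    kept_channels = [c for chans in regions.values() for c in chans]
    log.append(f"regions retained: {sorted(regions)} "
               f"({len(kept_channels)} channels)")
    log.append("statistical unit: electrode pairs pooled within region; "
               "pairs within one animal are not independent (pseudo-"
               "replication caveat)")

    # ----- spectral stage (bipolar pairs) -----
    changes = spec.structure_spectral_change(
        rec, emap,
        EpochSpec(*cfg.spectral_baseline, "baseline"),
        EpochSpec(*cfg.spectral_post, "post"),
        mode=cfg.bipolar_mode, channels=kept_channels,
        fit_range=cfg.fit_range, window_s=cfg.spectral_window_s,
        peak_threshold_sd=cfg.peak_threshold_sd, max_iters=cfg.max_iters,
        mask_mains=cfg.mask_mains,
    )
    region_rows = []
    by_region: dict[str, list[spec.SpectralChange]] = {}
    for ch in changes:
        by_region.setdefault(ch.region, []).append(ch)
    for region, chs in sorted(by_region.items()):
        da = np.concatenate([c.pair_deltas()[0] for c in chs])
        db = np.concatenate([c.pair_deltas()[1] for c in chs])
        a_base = np.concatenate([[f.offset for f in c.fits_baseline] for c in chs])
        a_post = np.concatenate([[f.offset for f in c.fits_post] for c in chs])
        b_base = np.concatenate([[f.exponent for f in c.fits_baseline] for c in chs])
        b_post = np.concatenate([[f.exponent for f in c.fits_post] for c in chs])
        t_a = st.paired_contrast(a_base, a_post, alpha=cfg.alpha)
        t_b = st.paired_contrast(b_base, b_post, alpha=cfg.alpha)
        region_rows.append({
            "region": region, "n_pairs": len(da),
            "A_base": np.median(a_base), "A_post": np.median(a_post),
            "dA": np.median(da), "p_dA": t_a.p_value,
            "sig_dA": _sig_mark(t_a.p_value, cfg.alpha),
            "B_base": np.median(b_base), "B_post": np.median(b_post),
            "dB": np.median(db), "p_dB": t_b.p_value,
            "sig_dB": _sig_mark(t_b.p_value, cfg.alpha),
        })
    # pooled-over-regions contrast (global offset / exponent change)
    if region_rows:
        da_all = np.concatenate([c.pair_deltas()[0] for c in changes])
        db_all = np.concatenate([c.pair_deltas()[1] for c in changes])
        t_a = st.paired_contrast(np.zeros_like(da_all), da_all, alpha=cfg.alpha)
        t_b = st.paired_contrast(np.zeros_like(db_all), db_all, alpha=cfg.alpha)
        region_rows.append({
            "region": "ALL", "n_pairs": len(da_all),
            "A_base": np.nan, "A_post": np.nan,
            "dA": np.median(da_all), "p_dA": t_a.p_value,
            "sig_dA": _sig_mark(t_a.p_value, cfg.alpha),
            "B_base": np.nan, "B_post": np.nan,
            "dB": np.median(db_all), "p_dB": t_b.p_value,
            "sig_dB": _sig_mark(t_b.p_value, cfg.alpha),
        })
    spectral_table = pd.DataFrame(region_rows)
    if cfg.bh_correct and len(spectral_table) > 1:
        body = spectral_table["region"] != "ALL"
        for col, sig in (("p_dA", "sig_dA"), ("p_dB", "sig_dB")):
            rej = st.benjamini_hochberg(spectral_table.loc[body, col].values,
                                        alpha=cfg.alpha)
            spectral_table.loc[body, sig] = np.where(rej, "*", "")
        log.append("Benjamini-Hochberg correction applied to region p-values")

    # ----- connectivity stage (monopolar pairs) -----
    rec_ds = downsample(rec, cfg.target_fs)
    log.append(f"connectivity on monopolar data at {rec_ds.fs} Hz")
    pairs = list(combinations(kept_channels, 2))
    pcs = conn.epoch_pair_connectivity(
        rec_ds, emap,
        EpochSpec(*cfg.conn_baseline, "baseline"),
        EpochSpec(*cfg.conn_post, "post"),
        window_s=cfg.window_s, pairs=pairs,
        bias_correct=cfg.bias_correct, units=cfg.mi_units,
        floor=cfg.mi_floor,
    )
    summary = conn.structure_summary(pcs, emap)

    pair_table = pd.DataFrame([{
        "chan_i": pc.pair[0], "chan_j": pc.pair[1],
        "structure_i": emap.structure_of(pc.pair[0]),
        "structure_j": emap.structure_of(pc.pair[1]),
        "region_i": emap.region_of(pc.pair[0]),
        "region_j": emap.region_of(pc.pair[1]),
        "mi_base": pc.mi_baseline, "mi_post": pc.mi_post,
        "ratio": pc.ratio, "within": pc.within_structure,
        "reliable": pc.reliable,
    } for pc in pcs])

    region_matrix = pd.DataFrame(summary.matrix.mean_ratio,
                                 index=summary.matrix.regions,
                                 columns=summary.matrix.regions)
    fit_rows = []
    for fit in (summary.fit_within, summary.fit_between):
        if fit is not None:
            fit_rows.append({"scope": fit.scope, "slope": fit.slope,
                             "intercept": fit.intercept,
                             "r_squared": fit.r_squared,
                             "n_pairs": fit.n_pairs})
    fit_table = pd.DataFrame(fit_rows)

    contrast_rows = []
    for scope in ("within", "between"):
        ratios = np.array([pc.ratio for pc in pcs
                           if pc.within_structure == (scope == "within")
                           and pc.reliable and np.isfinite(pc.ratio)])
        if ratios.size < 3:
            continue
        t = st.paired_contrast(np.zeros_like(ratios), np.log(ratios),
                               alpha=cfg.alpha)
        contrast_rows.append({
            "scope": scope, "n_pairs": ratios.size,
            "median_ratio": float(np.median(ratios)),
            "p_value": t.p_value,
            "sig": _sig_mark(t.p_value, cfg.alpha),
        })
    contrast_table = pd.DataFrame(contrast_rows)
    log.append(f"baseline within-vs-between mean MI difference: "
               f"{summary.within_between_diff_pct:.1f}%")

    control_table = None
    if cfg.run_baseline_control:
        ctrl = conn.baseline_control(
            rec_ds, EpochSpec(*cfg.conn_baseline, "baseline"), emap,
            window_s=cfg.window_s, pairs=pairs,
            bias_correct=cfg.bias_correct, units=cfg.mi_units,
            floor=cfg.mi_floor,
        )
        control_table = pd.DataFrame([{
            "chan_i": pc.pair[0], "chan_j": pc.pair[1],
            "ratio": pc.ratio, "reliable": pc.reliable,
        } for pc in ctrl])
        med = np.nanmedian(control_table["ratio"].values)
        log.append(f"baseline split-half control: median ratio {med:.3f}")

    report = PipelineReport(
        spectral_table=spectral_table, spectral_changes=changes,
        pair_table=pair_table, region_matrix=region_matrix,
        fit_table=fit_table, contrast_table=contrast_table,
        summary=summary, control_table=control_table, log_lines=log,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
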