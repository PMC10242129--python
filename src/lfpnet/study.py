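"""Scaled-down simulated drug studies with ground-truth recovery checks.

These scenarios run the full pipeline (generator -> recording -> spectral +
connectivity -> stats) at desk scale: 3 structures x 12 channels at 1 kHz,
150 s of baseline and 150 s of drug epoch, 120-s analysis windows on each
side of the injection.  Two stylized drug effects are provided:

* ``ketamine-like`` -- broadband power offset up (dA = +0.3), exponent
  unchanged, coupling scaled by 0.7 (connectivity down);
* ``lsd-like`` -- offset unchanged, exponent down (dB = -0.4, spectral
  flattening), coupling scaled by 0.8.

Bipolar pairing uses the "neighbors" mode on a pair-isolated array geometry,
so the six bipolar pairs per structure share no electrodes: the per-pair
(A, B) estimates entering the per-structure signed-rank test are then
independent and the test attains its exact size (2/64 ~ 3.1% at six pairs).
With all-within-structure pairs, shared electrodes correlate the pair
estimates and the pooled test becomes anticonservative -- the documented
pseudo-replication caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import PipelineConfig, PipelineReport, run_pipeline
from .sim import DrugEffect, SimConfig, simulate_experiment, study_config

#: Stylized drug effects: (delta offset, delta exponent, coupling scale).
DRUG_EFFECTS = {
    "ketamine-like": DrugEffect(delta_offset=0.3, delta_exponent=0.0,
                                coupling_scale=0.7),
    "lsd-like": DrugEffect(delta_offset=0.0, delta_exponent=-0.4,
                           coupling_scale=0.8),
    "null": DrugEffect(),
}

STUDY_DURATION_PRE = 150.0
STUDY_DURATION_POST = 150.0
STUDY_EPOCH_BASE = (-130.0, -10.0)
STUDY_EPOCH_POST = (20.0, 140.0)


def scaled_study_config(kind: str, seed: int, **overrides) -> SimConfig:
    """Generator config for one scaled-down drug study."""
    if kind not in DRUG_EFFECTS:
        raise ValueError(f"unknown study kind {kind!r}; "
                         f"choose from {sorted(DRUG_EFFECTS)}")
    kwargs = dict(
        drug_effect=DRUG_EFFECTS[kind],
        n_structures=3,
        channels_per_structure=12,
        fs=1000.0,
        duration_pre=STUDY_DURATION_PRE,
        duration_post=STUDY_DURATION_POST,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return study_config(**kwargs)


def scaled_pipeline_config() -> PipelineConfig:
    """Pipeline config matching the scaled epochs and single-animal data."""
    return PipelineConfig(
        spectral_baseline=STUDY_EPOCH_BASE,
        spectral_post=STUDY_EPOCH_POST,
        conn_baseline=STUDY_EPOCH_BASE,
        conn_post=STUDY_EPOCH_POST,
        bipolar_mode="neighbors",
        min_recordings=6,
        min_animals=1,
    )


@dataclass
class StudyResult:
    kind: str
    seed: int
    report: PipelineReport
    true_delta_offset: float
    true_delta_exponent: float
    coupling_scale: float

    # --- recovered quantities -------------------------------------------
    @property
    def recovered_delta_offset(self) -> float:
        """Median bipolar-pair offset change pooled over structures."""
        return float(self._all_row()["dA"])

    @property
    def recovered_delta_exponent(self) -> float:
        return float(self._all_row()["dB"])

    @property
    def within_ratio(self) -> float:
        row = self.report.contrast_table
        sel = row[row["scope"] == "within"]
        return float(sel["median_ratio"].iloc[0]) if len(sel) else np.nan

    @property
    def between_ratio(self) -> float:
        row = self.report.contrast_table
        sel = row[row["scope"] == "between"]
        return float(sel["median_ratio"].iloc[0]) if len(sel) else np.nan

    def _all_row(self):
        t = self.report.spectral_table
        return t[t["region"] == "ALL"].iloc[0]

    def _region_rows(self):
        t = self.report.spectral_table
        return t[t["region"] != "ALL"]

    # --- significance pattern -------------------------------------------
    def offset_sig_positive_everywhere(self) -> bool:
        r = self._region_rows()
        return bool(((r["sig_dA"] == "*") & (r["dA"] > 0)).all())

    def offset_sig_positive_nowhere(self) -> bool:
        r = self._region_rows()
        return not bool(((r["sig_dA"] == "*") & (r["dA"] > 0)).any())

    def exponent_sig_negative_everywhere(self) -> bool:
        r = self._region_rows()
        return bool(((r["sig_dB"] == "*") & (r["dB"] < 0)).all())

    def matches_expected_pattern(self) -> bool:
        """Qualitative pattern for the stylized drug (see module docstring)."""
        if self.kind == "ketamine-like":
            return (self.offset_sig_positive_everywhere()
                    and self.within_ratio < 1.0)
        if self.kind == "lsd-like":
            return (self.offset_sig_positive_nowhere()
                    and self.exponent_sig_negative_everywhere()
                    and self.within_ratio < 1.0)
        if self.kind == "null":
            r = self._region_rows()
            return not bool(((r["sig_dA"] == "*") | (r["sig_dB"] == "*")).any())
        raise ValueError(self.kind)


def run_drug_study(kind: str, seed: int,
                   cfg: PipelineConfig | None = None,
                   **sim_overrides) -> StudyResult:
    """Simulate one injection experiment and run the full analysis on it."""
    sim_cfg = scaled_study_config(kind, seed, **sim_overrides)
    rec, emap, truth = simulate_experiment(sim_cfg)
    report = run_pipeline(cfg or scaled_pipeline_config(), rec, emap)
    eff = sim_cfg.drug_effect
    return StudyResult(
        kind=kind, seed=seed, report=report,
        true_delta_offset=eff.delta_offset,
        true_delta_exponent=eff.delta_exponent,
        coupling_scale=eff.coupling_scale,
    )


def dissociation_success_rate(seeds: list[int] | np.ndarray) -> float:
    """Fraction of seeds where both stylized drugs show their pattern.

    For each seed, a ketamine-like and an LSD-like study are simulated and
    analyzed; success requires the ketamine-like run to show a significant
    offset increase in every structure with within-structure MI ratio < 1,
    and the LSD-like run to show a significant exponent decrease in every
    structure, no significant offset increase anywhere, and ratio < 1.
    """
    ok = 0
    for s in seeds:
        ket = run_drug_study("ketamine-like", int(s))
        lsd = run_drug_study("lsd-like", int(s) + 10_000)
        ok += int(ket.matches_expected_pattern()
                  and lsd.matches_expected_pattern())
    return ok / len(seeds)
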