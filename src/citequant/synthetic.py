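"""Synthetic paired-AML cohort generator with known ground truth.

Every downstream stage of the pipeline (normalization, bead calibration,
ADT-to-ABC bridging, target ranking, composition and survival analysis) is
exercised against cohorts produced here, for which the true per-cell antigen
numbers, capture artifacts, lineage compositions, and hazard structure are
all known.

The generative model, per patient and timepoint (diagnosis, relapse):

* Each antigen's true per-cell surface count follows a lognormal law:
  log10 ABC ~ Normal(mu_sa, sigma), with the sample-antigen mean mu_sa drawn
  uniformly over the configured log10 range (default 200..10,000 antigens
  per cell, the span observed for established myeloid targets).
* CITE-seq ADT counts are negative-binomial with mean
  true ABC x sample capture efficiency e_s x per-cell technical factor t_c
  (t_c lognormal, shared across all antibodies of a cell).  Isotype-control
  antibodies have no biological signal: their mean is a constant background
  times e_s x t_c.  An empty-droplet (ambient) matrix with antibody means
  proportional to e_s but independent of cell expression accompanies each
  sample, giving background correction a measurable target.
* The sample's antibody-library QC metrics are deterministic functions of
  e_s plus Gaussian noise, so they are informative artifact covariates.
* Flow cytometry is a separate aliquot: fresh cells drawn from the same
  lognormal truth, pushed through a batch-specific instrument response
  (log10 MFI linear in log10 ABC) with multiplicative lognormal noise.
  QuantiBRITE-style bead standards are generated from the same instrument
  response, so the fitted standard curve inverts it.
* Relapse lineage composition is the diagnosis Dirichlet composition
  perturbed in centered-log-ratio space by a patient-specific magnitude, so
  the true Aitchison distance equals that magnitude exactly.  Survival is
  exponential with log-hazard = baseline + hazard_coefficient x distance,
  administratively censored at a fixed horizon.

Flow and CITE-seq readouts are conditionally independent given the true
ABC law (they are separate aliquots of the same sample).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .composition import (
    LINEAGE_STATES,
    CompositionPair,
    CompositionVector,
    composition_from_labels,
)
from .flow import BeadStandard, FlowSample, StandardCurve, fit_standard_curve
from .preprocess import QC_METRIC_NAMES, AdtSample
from .survival import SurvivalRecord

__all__ = [
    "DEFAULT_PANEL",
    "DEFAULT_BRIDGE_ANTIGENS",
    "ISOTYPE_CONTROLS",
    "QUANTIBRITE_PE_PER_BEAD",
    "SyntheticConfig",
    "SyntheticSample",
    "SyntheticCohort",
    "generate_cohort",
    "generate_outcome_cohort",
    "generate_expression",
    "derive_seed",
]

DEFAULT_PANEL: tuple[str, ...] = (
    "CD33",
    "CLL-1",
    "CD123",
    "ADGRE2",
    "LAIR1",
    "ITGA4",
    "DEC-205",
    "CD244",
    "CD34",
    "CD38",
    "CD117",
    "CD99",
)
DEFAULT_BRIDGE_ANTIGENS: tuple[str, ...] = ("CD33", "CLL-1", "CD123", "ADGRE2")
ISOTYPE_CONTROLS: tuple[str, ...] = ("IgG1-iso", "IgG2a-iso", "IgG2b-iso")

#: A representative QuantiBRITE PE lot: PE molecules per bead for the four
#: bead populations (low, medium-low, medium-high, high).
QUANTIBRITE_PE_PER_BEAD: tuple[float, ...] = (474.0, 5359.0, 23843.0, 62336.0)

#: Batch-specific instrument response: log10 MFI = gain * log10 ABC + offset.
_INSTRUMENT_RESPONSE = {
    "diagnosis": (0.97, -0.30),
    "relapse": (1.03, -0.22),
}

_FMO_ABC_CUTOFF = 150.0  # background-binding level defining the FMO gate


class ConfigurationError(ValueError):
    pass


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 10
    n_cells_per_sample: int = 1000
    antigen_panel: tuple[str, ...] = DEFAULT_PANEL
    bridge_antigens: tuple[str, ...] = DEFAULT_BRIDGE_ANTIGENS
    n_isotype_controls: int = 3
    abc_log10_mean_range: tuple[float, float] = (np.log10(200.0), np.log10(10_000.0))
    abc_log10_sd: float = 0.25
    capture_efficiency_range: tuple[float, float] = (0.2, 1.0)
    qc_noise_sd: float = 0.05
    n_lineage_states: int = 9
    shift_magnitude_range: tuple[float, float] = (0.0, 3.0)
    hazard_coefficient: float = -0.6
    seed: int = 0
    # count-noise / background parameters
    nb_dispersion: float = 10.0
    technical_sd: float = 0.3
    flow_noise_sd: float = 0.10
    isotype_background_mean: float = 20.0
    ambient_background_mean: float = 20.0
    n_background_droplets: int = 500
    n_flow_cells: Optional[int] = None
    # survival parameters
    baseline_median_survival: float = 24.0  # months
    censor_horizon: float = 60.0  # months

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_cells_per_sample", "n_isotype_controls", "n_lineage_states"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("abc_log10_mean_range", "capture_efficiency_range", "shift_magnitude_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered (low <= high)")
        lo, hi = self.capture_efficiency_range
        if not (0 < lo and hi <= 1):
            raise ConfigurationError("capture efficiencies must lie in (0, 1]")
        if self.shift_magnitude_range[0] < 0:
            raise ConfigurationError("shift magnitudes must be nonnegative")
        if self.abc_log10_sd <= 0 or self.qc_noise_sd <= 0:
            raise ConfigurationError("abc_log10_sd and qc_noise_sd must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not set(self.bridge_antigens) <= set(self.antigen_panel):
            raise ConfigurationError("bridge antigens must be a subset of the panel")
        if len(self.bridge_antigens) < 4:
            raise ConfigurationError("need at least 4 designated bridge antigens")

    @property
    def isotype_names(self) -> tuple[str, ...]:
        return tuple(ISOTYPE_CONTROLS[i % 3] + ("" if i < 3 else f"-{i}")
                     for i in range(self.n_isotype_controls))

    @property
    def lineage_states(self) -> tuple[str, ...]:
        n = self.n_lineage_states
        if n <= len(LINEAGE_STATES):
            return LINEAGE_STATES[:n]
        extra = tuple(f"state-{i}" for i in range(len(LINEAGE_STATES), n))
        return LINEAGE_STATES + extra


@dataclass
class SyntheticSample:
    """One patient-timepoint sample with its ground truth."""

    sample_id: str
    patient_id: str
    timepoint: str  # "diagnosis" | "relapse"
    adt: AdtSample
    truth_abc: pd.DataFrame  # cells x antigens, linear scale
    lineage_labels: np.ndarray
    lineage_frequencies: np.ndarray  # generating composition (ground truth)
    flow: dict[str, FlowSample]
    capture_efficiency: float
    technical_factors: np.ndarray
    abc_log10_means: pd.Series  # mu_sa per antigen


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    samples: list[SyntheticSample]
    bead_standards: dict[str, BeadStandard]
    standard_curves: dict[str, StandardCurve]  # fitted (inverse-instrument) curves
    pairs: list[CompositionPair]
    survival: pd.DataFrame

    def sample(self, sample_id: str) -> SyntheticSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion size."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _qc_metrics(rng: np.random.Generator, efficiency: float, noise_sd: float) -> pd.Series:
    """Antibody-library QC metrics as noisy deterministic functions of the
    sample capture efficiency, so they carry artifact information."""
    e = efficiency

    def pct(base: float, slope: float) -> float:
        value = base + slope * e + rng.normal(0.0, 2.0 * noise_sd * abs(slope))
        return float(np.clip(value, 0.0, 100.0))

    def count(base: float) -> float:
        return float(base * (0.3 + 0.7 * e) * (1.0 + rng.normal(0.0, noise_sd)))

    values = {
        "total_reads": count(2.0e8),
        "mean_reads_per_cell": count(30_000.0),
        "pct_valid_barcodes": pct(80.0, 15.0),
        "antibody_sequencing_saturation": pct(30.0, 55.0),
        "pct_q30_barcode": pct(88.0, 8.0),
        "pct_q30_antibody_read": pct(84.0, 10.0),
        "pct_q30_umi": pct(86.0, 10.0),
        "pct_reads_with_barcode": pct(74.0, 20.0),
        "pct_reads_antibody_valid_umi_cell": pct(50.0, 40.0),
        "pct_reads_aggregate_barcodes": pct(6.0, -4.0),
        "pct_reads_unrecognized_antibody": pct(9.0, -6.0),
        "pct_reads_antibody_valid_umi_cell_in_cells": pct(40.0, 45.0),
        "median_umis_per_cell": count(3_000.0),
    }
    return pd.Series({name: values[name] for name in QC_METRIC_NAMES})


def _perturb_composition(
    rng: np.random.Generator, freqs: np.ndarray, magnitude: float
) -> tuple[np.ndarray, float]:
    """Perturb a composition in CLR space by a vector of the given norm, so
    the true Aitchison distance between input and output equals magnitude."""
    if magnitude == 0:
        return freqs.copy(), 0.0
    delta = rng.normal(size=freqs.size)
    delta -= delta.mean()
    norm = np.linalg.norm(delta)
    if norm == 0:  # pragma: no cover - measure-zero draw
        return freqs.copy(), 0.0
    delta *= magnitude / norm
    logf = np.log(freqs)
    z = (logf - logf.mean()) + delta
    out = np.exp(z - z.max())
    out /= out.sum()
    return out, magnitude


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort.  Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    states = config.lineage_states
    panel = list(config.antigen_panel)
    isotypes = list(config.isotype_names)
    n_cells = config.n_cells_per_sample
    n_flow = config.n_flow_cells or n_cells

    # Bead standards: exact instrument response per flow batch (one batch
    # per timepoint), so the fitted curve inverts the instrument exactly.
    bead_standards: dict[str, BeadStandard] = {}
    standard_curves: dict[str, StandardCurve] = {}
    for batch, (gain, offset) in _INSTRUMENT_RESPONSE.items():
        pe = np.asarray(QUANTIBRITE_PE_PER_BEAD)
        gmfi = 10.0 ** (gain * np.log10(pe) + offset)
        beads = BeadStandard(tuple(pe), tuple(gmfi))
        bead_standards[batch] = beads
        standard_curves[batch] = fit_standard_curve(beads)

    lo_mu, hi_mu = config.abc_log10_mean_range
    lo_e, hi_e = config.capture_efficiency_range
    alpha = np.full(config.n_lineage_states, 2.0)
    baseline_log_hazard = float(np.log(np.log(2.0) / config.baseline_median_survival))

    samples: list[SyntheticSample] = []
    pairs: list[CompositionPair] = []
    survival_rows = []

    for p in range(config.n_patients):
        patient_id = f"P{p + 1:02d}"
        diag_freqs = rng.dirichlet(alpha)
        magnitude = rng.uniform(*config.shift_magnitude_range)
        relapse_freqs, distance = _perturb_composition(rng, diag_freqs, magnitude)

        # survival: exponential hazard tied to the true compositional shift
        hazard = np.exp(baseline_log_hazard + config.hazard_coefficient * distance)
        raw_time = rng.exponential(1.0 / hazard)
        event = int(raw_time <= config.censor_horizon)
        os_time = float(min(raw_time, config.censor_horizon))
        sex = int(rng.integers(0, 2))
        time_to_relapse = float(os_time * rng.uniform(0.3, 0.9))
        record = SurvivalRecord(
            patient_id=patient_id,
            os_time=os_time,
            event=event,
            sex=sex,
            distance=distance,
            time_to_relapse=time_to_relapse,
        )
        survival_rows.append(
            {
                "patient_id": patient_id,
                "os_time": os_time,
                "event": event,
                "sex": sex,
                "true_distance": distance,
                "time_to_relapse": time_to_relapse,
            }
        )

        timepoint_labels: dict[str, np.ndarray] = {}
        for timepoint, freqs in (("diagnosis", diag_freqs), ("relapse", relapse_freqs)):
            sample_id = f"{patient_id}{'D' if timepoint == 'diagnosis' else 'R'}"
            efficiency = rng.uniform(lo_e, hi_e)
            mu = pd.Series(rng.uniform(lo_mu, hi_mu, size=len(panel)), index=panel)
            technical = rng.lognormal(0.0, config.technical_sd, size=n_cells)

            truth_log10 = rng.normal(
                mu.to_numpy()[None, :], config.abc_log10_sd, size=(n_cells, len(panel))
            )
            truth = 10.0 ** truth_log10
            barcodes = [f"{sample_id}-c{i:05d}" for i in range(n_cells)]
            truth_df = pd.DataFrame(truth, index=barcodes, columns=panel)

            adt_mean = truth * efficiency * technical[:, None]
            adt_counts = _nb_counts(rng, adt_mean, config.nb_dispersion)
            iso_mean = (
                config.isotype_background_mean * efficiency * technical[:, None]
            ) * np.ones((n_cells, len(isotypes)))
            iso_counts = _nb_counts(rng, iso_mean, config.nb_dispersion)
            counts = pd.DataFrame(
                np.hstack([adt_counts, iso_counts]),
                index=barcodes,
                columns=panel + isotypes,
            )

            ambient_mean = np.full(
                len(panel) + len(isotypes),
                config.ambient_background_mean * efficiency,
            )
            background = pd.DataFrame(
                _nb_counts(
                    rng,
                    np.tile(ambient_mean, (config.n_background_droplets, 1)),
                    config.nb_dispersion,
                ),
                columns=panel + isotypes,
            )

            cell_qc = pd.DataFrame(
                {
                    "total_counts": rng.lognormal(np.log(8000.0), 0.3, n_cells).clip(1500, None),
                    "detected_features": rng.lognormal(np.log(2500.0), 0.25, n_cells)
                    .clip(400, None)
                    .round(),
                    "mito_fraction": rng.uniform(0.01, 0.10, n_cells),
                },
                index=barcodes,
            )
            qc_metrics = _qc_metrics(rng, efficiency, config.qc_noise_sd)

            adt = AdtSample(
                sample_id=sample_id,
                counts=counts,
                isotype_controls=tuple(isotypes),
                cell_qc=cell_qc,
                qc_metrics=qc_metrics,
                background=background,
            )

            labels = rng.choice(states, size=n_cells, p=freqs)
            timepoint_labels[timepoint] = labels

            gain, offset = _INSTRUMENT_RESPONSE[timepoint]
            fmo_threshold = float(10.0 ** (gain * np.log10(_FMO_ABC_CUTOFF) + offset))
            flow: dict[str, FlowSample] = {}
            for antigen in config.bridge_antigens:
                flow_truth_log10 = rng.normal(mu[antigen], config.abc_log10_sd, size=n_flow)
                intensity = 10.0 ** (gain * flow_truth_log10 + offset)
                intensity *= np.exp(rng.normal(0.0, config.flow_noise_sd, size=n_flow))
                flow[antigen] = FlowSample(
                    sample_id=sample_id,
                    antigen=antigen,
                    intensities=intensity,
                    gates=np.array(["blast"] * n_flow),
                    fmo_threshold=fmo_threshold,
                )

            samples.append(
                SyntheticSample(
                    sample_id=sample_id,
                    patient_id=patient_id,
                    timepoint=timepoint,
                    adt=adt,
                    truth_abc=truth_df,
                    lineage_labels=labels,
                    lineage_frequencies=freqs.copy(),
                    flow=flow,
                    capture_efficiency=float(efficiency),
                    technical_factors=technical,
                    abc_log10_means=mu,
                )
            )

        pairs.append(
            CompositionPair(
                patient_id=patient_id,
                diagnosis=composition_from_labels(timepoint_labels["diagnosis"], states),
                relapse=composition_from_labels(timepoint_labels["relapse"], states),
                survival=record,
                diagnosis_labels=timepoint_labels["diagnosis"],
                relapse_labels=timepoint_labels["relapse"],
            )
        )

    survival = pd.DataFrame(survival_rows).set_index("patient_id")
    return SyntheticCohort(
        config=config,
        samples=samples,
        bead_standards=bead_standards,
        standard_curves=standard_curves,
        pairs=pairs,
        survival=survival,
    )


def generate_outcome_cohort(
    n_patients: int,
    hazard_coefficient: float,
    shift_magnitude_range: tuple[float, float] = (0.0, 3.0),
    seed: int = 0,
    baseline_median_survival: float = 24.0,
    censor_horizon: float = 60.0,
) -> pd.DataFrame:
    """Lightweight cohort (distance + survival only) for power and coverage
    simulations, using the same hazard model as the full generator."""
    rng = np.random.default_rng(seed)
    baseline_log_hazard = float(np.log(np.log(2.0) / baseline_median_survival))
    distance = rng.uniform(*shift_magnitude_range, size=n_patients)
    hazard = np.exp(baseline_log_hazard + hazard_coefficient * distance)
    raw = rng.exponential(1.0 / hazard)
    event = (raw <= censor_horizon).astype(int)
    os_time = np.minimum(raw, censor_horizon)
    sex = rng.integers(0, 2, size=n_patients)
    return pd.DataFrame(
        {
            "os_time": os_time,
            "event": event,
            "sex": sex,
            "distance": distance,
        },
        index=[f"P{i + 1:03d}" for i in range(n_patients)],
    )


def generate_expression(
    n_cells: int,
    n_genes: int = 200,
    seed: int = 0,
    gene_prefix: str = "G",
    cell_prefix: str = "c",
) -> pd.DataFrame:
    """Minimal log-normal expression table (cells x genes) for module-score
    gating.  Gene means are lognormal; per-cell values add lognormal noise.
    No attempt is made to model real transcriptome structure."""
    rng = np.random.default_rng(seed)
    gene_means = rng.lognormal(1.0, 1.0, size=n_genes)
    expr = gene_means[None, :] * rng.lognormal(0.0, 0.3, size=(n_cells, n_genes))
    return pd.DataFrame(
        expr,
        index=[f"{cell_prefix}{i:05d}" for i in range(n_cells)],
        columns=[f"{gene_prefix}{j:04d}" for j in range(n_genes)],
    )
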