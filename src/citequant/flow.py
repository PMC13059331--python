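"""Bead-calibrated quantification of flow cytometry.

Quantitative flow cytometry with PE-conjugated calibration beads (e.g. BD
QuantiBRITE) converts fluorescence intensity into antibodies bound per cell
(ABC).  Each bead lot carries four bead populations with a known number of PE
molecules per bead; running them alongside the stained sample yields a
log10-log10 standard curve mapping geometric mean fluorescence intensity
(gMFI) to PE molecules.  Because the antibodies are PE-conjugated at 1:1
stoichiometry, PE molecules per cell equal antibodies bound per cell.

This module fits the standard curve, converts per-cell intensities to ABC,
and computes the positivity/intensity summaries used downstream: geometric
means and FMO-gated percent positivity on the blast (CD45mid) population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BeadStandard",
    "StandardCurve",
    "FlowSample",
    "BeadCalibration",
    "fit_standard_curve",
    "fluorescence_to_abc",
    "abc_to_fluorescence",
    "geometric_mean",
    "fmo_threshold_from_events",
    "percent_positive",
    "read_bead_table",
    "read_flow_events",
    "summarize_flow_sample",
]

#: FMO gating percentile used when a threshold must be derived from raw
#: FMO-control events (standard practice: the top 0.1% of the FMO
#: distribution is treated as positive).
FMO_PERCENTILE = 99.9


class CalibrationError(ValueError):
    """Raised when a bead standard cannot define a valid curve."""


@dataclass(frozen=True)
class BeadStandard:
    """A bead lot: known PE molecules per bead and measured gMFI per population."""

    pe_per_bead: tuple[float, ...]
    gmfi: tuple[float, ...]

    def __post_init__(self) -> None:
        pe = np.asarray(self.pe_per_bead, dtype=float)
        mfi = np.asarray(self.gmfi, dtype=float)
        if pe.size != mfi.size:
            raise CalibrationError("pe_per_bead and gmfi must have equal length")
        if pe.size < 2:
            raise CalibrationError("need at least 2 bead populations to fit a curve")
        if np.any(pe <= 0) or np.any(mfi <= 0):
            raise CalibrationError("bead PE values and gMFI must be strictly positive")


@dataclass(frozen=True)
class StandardCurve:
    """log10 ABC = slope * log10 MFI + intercept."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    def abc(self, intensities: np.ndarray | float) -> np.ndarray | float:
        return fluorescence_to_abc(intensities, self)

    def inverse(self, abc: np.ndarray | float) -> np.ndarray | float:
        """Map ABC back to fluorescence intensity (used to simulate instruments)."""
        return abc_to_fluorescence(abc, self)


@dataclass
class FlowSample:
    """Per-cell flow events for one (sample, antigen) with gate labels.

    ``gates`` holds one label per event (e.g. ``"blast"`` for CD45mid,
    ``"lsc"`` for CD34+CD38-); ``fmo_threshold`` is the positivity cutoff
    derived from the fluorescence-minus-one control.
    """

    sample_id: str
    antigen: str
    intensities: np.ndarray
    gates: np.ndarray
    fmo_threshold: Optional[float] = None
    fmo_events: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.gates = np.asarray(self.gates)
        if self.intensities.shape != self.gates.shape:
            raise ValueError("intensities and gates must align")
        if np.any(self.intensities <= 0):
            raise ValueError("fluorescence intensities must be strictly positive")

    def gated(self, gate: str = "blast") -> np.ndarray:
        return self.intensities[self.gates == gate]


class BeadCalibration(BaseEstimator, RegressorMixin):
    """Standard-curve regressor: ordinary least squares on log10-log10 scale.

    ``fit`` regresses log10(PE per bead) on log10(gMFI) so that ``predict``
    maps fluorescence intensity directly to ABC.
    """

    def fit(self, gmfi: Sequence[float], pe_per_bead: Sequence[float]) -> "BeadCalibration":
        beads = BeadStandard(tuple(np.asarray(pe_per_bead, float)), tuple(np.asarray(gmfi, float)))
        res = stats.linregress(np.log10(beads.gmfi), np.log10(beads.pe_per_bead))
        if res.slope <= 0:
            raise CalibrationError(
                f"bead standard yields non-increasing curve (slope={res.slope:.3g})"
            )
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.curve_ = StandardCurve(self.slope_, self.intercept_, self.r_squared_)
        return self

    def predict(self, intensities: Sequence[float]) -> np.ndarray:
        check_is_fitted(self, "curve_")
        return np.asarray(fluorescence_to_abc(np.asarray(intensities, float), self.curve_))


def fit_standard_curve(beads: BeadStandard) -> StandardCurve:
    """OLS fit of log10(pe_per_bead) on log10(gmfi)."""
    return BeadCalibration().fit(beads.gmfi, beads.pe_per_bead).curve_


def fluorescence_to_abc(intensities, curve: StandardCurve):
    """ABC_i = 10^(slope * log10 I_i + intercept); monotone in intensity."""
    arr = np.asarray(intensities, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("intensities must be strictly positive")
    out = 10.0 ** (curve.slope * np.log10(arr) + curve.intercept)
    return out if arr.ndim else float(out)


def abc_to_fluorescence(abc, curve: StandardCurve):
    arr = np.asarray(abc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ABC values must be strictly positive")
    out = 10.0 ** ((np.log10(arr) - curve.intercept) / curve.slope)
    return out if arr.ndim else float(out)


def geometric_mean(values) -> float:
    """exp(mean(ln values)) over a nonempty strictly positive vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty vector is undefined")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def fmo_threshold_from_events(fmo_events, percentile: float = FMO_PERCENTILE) -> float:
    arr = np.asarray(fmo_events, dtype=float)
    if arr.size == 0:
        raise ValueError("empty FMO event vector")
    return float(np.percentile(arr, percentile))


def percent_positive(sample: FlowSample, gate: str = "blast") -> float:
    """Fraction of gated events with intensity above the FMO threshold."""
    threshold = sample.fmo_threshold
    if threshold is None:
        if sample.fmo_events is None:
            raise ValueError(
                f"{sample.sample_id}/{sample.antigen}: no FMO threshold and no FMO events"
            )
        threshold = fmo_threshold_from_events(sample.fmo_events)
    events = sample.gated(gate)
    if events.size == 0:
        raise ValueError(f"{sample.sample_id}/{sample.antigen}: empty gate {gate!r}")
    return float(np.mean(events > threshold))


def summarize_flow_sample(
    sample: FlowSample, curve: StandardCurve, gate: str = "blast"
) -> dict:
    """Per-sample quantification row: positivity plus geometric/arithmetic
    mean ABC among antigen-positive gated events."""
    pct = percent_positive(sample, gate=gate)
    threshold = sample.fmo_threshold
    if threshold is None:
        threshold = fmo_threshold_from_events(sample.fmo_events)
    events = sample.gated(gate)
    positive = events[events > threshold]
    if positive.size:
        gmfi_pos = geometric_mean(positive)
        abc_pos = np.asarray(fluorescence_to_abc(positive, curve))
        mean_abc = float(np.mean(abc_pos))
        geo_abc = geometric_mean(abc_pos)
    else:
        gmfi_pos = mean_abc = geo_abc = float("nan")
    all_abc = np.asarray(fluorescence_to_abc(events, curve))
    return {
        "sample_id": sample.sample_id,
        "antigen": sample.antigen,
        "population": gate,
        "pct_positive": pct,
        "gmfi_positive": gmfi_pos,
        "mean_abc_positive": mean_abc,
        "geomean_abc_positive": geo_abc,
        "mean_abc_all": float(np.mean(all_abc)),
    }


def read_bead_table(path) -> BeadStandard:
    """Read a bead table CSV with columns population, pe_per_bead, gmfi."""
    df = pd.read_csv(path)
    return BeadStandard(tuple(df["pe_per_bead"].astype(float)), tuple(df["gmfi"].astype(float)))


def read_flow_events(path) -> list[FlowSample]:
    """Read a flow event CSV (sample_id, antigen, fluorescence, gate
    [, fmo_threshold]) into one FlowSample per (sample, antigen)."""
    df = pd.read_csv(path)
    samples = []
    for (sid, antigen), grp in df.groupby(["sample_id", "antigen"], sort=True):
        thr = None
        if "fmo_threshold" in grp.columns and grp["fmo_threshold"].notna().any():
            thr = float(grp["fmo_threshold"].dropna().iloc[0])
        samples.append(
            FlowSample(
                sample_id=str(sid),
                antigen=str(antigen),
                intensities=grp["fluorescence"].to_numpy(float),
                gates=grp["gate"].to_numpy(),
                fmo_threshold=thr,
            )
        )
    return samples
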