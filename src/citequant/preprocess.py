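"""Cell QC filtering and ADT normalization for CITE-seq antibody counts.

Three transformations are provided, mirroring common CITE-seq practice:

* **CLR** — centered log-ratio within each cell across antibodies, the
  Seurat default for ADT data.  Used downstream for the CD34/CD38 gates.
* **DSB-style background correction** — per-antibody z-scoring of ln counts
  against a background distribution (empty droplets when available), then
  removal of a per-cell technical factor estimated from isotype-control
  antibodies.
* **Cell-profile quantile normalization** — every cell's antibody profile is
  mapped onto a common reference distribution (the mean of sorted profiles),
  preserving within-cell ranks.  This puts all cells of a sample on one
  scale before quantile mapping against flow cytometry.

Cell QC uses the standard RNA-side filters: cells with < 1,000 total counts,
< 200 detected features, or > 15% mitochondrial reads are removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "QC_METRIC_NAMES",
    "QC_MIN_TOTAL_COUNTS",
    "QC_MIN_DETECTED_FEATURES",
    "QC_MAX_MITO_FRACTION",
    "AdtSample",
    "qc_filter_cells",
    "CLRNormalizer",
    "DSBNormalizer",
    "ProfileQuantileNormalizer",
    "clr_normalize",
    "dsb_normalize",
    "quantile_normalize_cells",
]

# Antibody-library QC metrics reported by Cell Ranger for the ADT library;
# used as artifact covariates by the bridging model.
QC_METRIC_NAMES: tuple[str, ...] = (
    "total_reads",
    "mean_reads_per_cell",
    "pct_valid_barcodes",
    "antibody_sequencing_saturation",
    "pct_q30_barcode",
    "pct_q30_antibody_read",
    "pct_q30_umi",
    "pct_reads_with_barcode",
    "pct_reads_antibody_valid_umi_cell",
    "pct_reads_aggregate_barcodes",
    "pct_reads_unrecognized_antibody",
    "pct_reads_antibody_valid_umi_cell_in_cells",
    "median_umis_per_cell",
)

QC_MIN_TOTAL_COUNTS = 1_000
QC_MIN_DETECTED_FEATURES = 200
QC_MAX_MITO_FRACTION = 0.15


class NormalizationError(ValueError):
    pass


@dataclass
class AdtSample:
    """One sample's ADT count matrix (cells x antibodies) with metadata.

    ``counts`` rows are cells (index = barcodes), columns antibodies.
    ``isotype_controls`` names the non-targeting control antibodies.
    ``cell_qc`` optionally carries the RNA-side QC triple per cell
    (total_counts, detected_features, mito_fraction); ``qc_metrics`` the
    sample-level antibody-library QC metrics; ``background`` an optional
    empty-droplet count matrix on the same antibody panel.
    """

    sample_id: str
    counts: pd.DataFrame
    isotype_controls: tuple[str, ...] = ()
    cell_qc: Optional[pd.DataFrame] = None
    qc_metrics: Optional[pd.Series] = None
    background: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("ADT counts must be nonnegative")
        missing = set(self.isotype_controls) - set(self.counts.columns)
        if missing:
            raise ValueError(f"isotype controls not in panel: {sorted(missing)}")

    @property
    def antigens(self) -> list[str]:
        return [c for c in self.counts.columns if c not in self.isotype_controls]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


def qc_filter_cells(adt: AdtSample) -> AdtSample:
    """Remove cells failing the RNA-side QC filters.

    Removal conditions are strict (< 1,000 counts, < 200 features,
    > 15% mito), so a cell sitting exactly on a threshold is kept.
    Row order is preserved; the filter is idempotent.
    """
    if adt.cell_qc is None:
        warnings.warn(
            f"{adt.sample_id}: no per-cell RNA QC available; cell filter skipped",
            stacklevel=2,
        )
        logger.warning("%s: QC filter skipped (no cell_qc)", adt.sample_id)
        return adt
    qc = adt.cell_qc.loc[adt.counts.index]
    keep = (
        (qc["total_counts"] >= QC_MIN_TOTAL_COUNTS)
        & (qc["detected_features"] >= QC_MIN_DETECTED_FEATURES)
        & (qc["mito_fraction"] <= QC_MAX_MITO_FRACTION)
    )
    return replace(
        adt,
        counts=adt.counts.loc[keep.to_numpy()],
        cell_qc=qc.loc[keep.to_numpy()],
    )


class CLRNormalizer(BaseEstimator, TransformerMixin):
    """Centered log-ratio across antibodies within each cell.

    y_{c,a} = ln(x_{c,a} + 1) - mean_a' ln(x_{c,a'} + 1); each row sums to 0.
    Stateless: ``fit`` is a no-op kept for pipeline compatibility.
    """

    def fit(self, X, y=None) -> "CLRNormalizer":
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        frame = isinstance(X, pd.DataFrame)
        arr = np.log1p(np.asarray(X, dtype=float))
        out = arr - arr.mean(axis=1, keepdims=True)
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class DSBNormalizer(BaseEstimator, TransformerMixin):
    """Background z-scoring plus isotype-based technical-factor removal.

    Step 1: per antibody, z-score ln(x+1) against background mean/sd.  The
    background comes from an empty-droplet matrix when supplied; otherwise
    it is estimated in-sample from the lowest ``background_decile`` of cells
    per antibody (flagged in ``background_source_``, since the in-sample
    proxy absorbs part of the biological level).

    Step 2: per cell, the mean of the isotype-control z-scores estimates a
    technical factor (droplet-to-droplet capture differences) which is
    subtracted from every antibody value of that cell.
    """

    def __init__(self, isotype_controls: Sequence[str] = (), background_decile: float = 0.10):
        self.isotype_controls = isotype_controls
        self.background_decile = background_decile

    def fit(self, X: pd.DataFrame, y=None, background: Optional[pd.DataFrame] = None):
        if not list(self.isotype_controls):
            raise NormalizationError("DSB requires at least one isotype control")
        missing = set(self.isotype_controls) - set(X.columns)
        if missing:
            raise NormalizationError(f"isotype controls missing from matrix: {sorted(missing)}")
        if background is not None:
            bg = np.log1p(background[X.columns].to_numpy(float))
            self.background_mean_ = bg.mean(axis=0)
            self.background_sd_ = bg.std(axis=0, ddof=1)
            self.background_source_ = "empty_droplets"
        else:
            arr = np.log1p(X.to_numpy(float))
            n = arr.shape[0]
            k = max(2, int(np.ceil(self.background_decile * n)))
            low = np.sort(arr, axis=0)[:k]
            self.background_mean_ = low.mean(axis=0)
            self.background_sd_ = low.std(axis=0, ddof=1)
            self.background_source_ = "lowest_decile_cells"
        # guard degenerate backgrounds (constant counts); the threshold also
        # absorbs float rounding on exactly-constant columns
        self.background_sd_ = np.where(
            self.background_sd_ <= 1e-6, 1.0, self.background_sd_
        )
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "background_mean_")
        arr = np.log1p(X[list(self.feature_names_in_)].to_numpy(float))
        z = (arr - self.background_mean_) / self.background_sd_
        iso_idx = [list(self.feature_names_in_).index(c) for c in self.isotype_controls]
        technical = z[:, iso_idx].mean(axis=1, keepdims=True)
        out = z - technical
        return pd.DataFrame(out, index=X.index, columns=self.feature_names_in_)


class ProfileQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Quantile normalization with cells as the normalized profiles.

    The reference distribution is the mean of the sorted per-cell profiles;
    each cell's values are replaced by the reference values at their
    within-cell ranks.  Ties receive the average of the tied reference
    values.  With a single antibody the transform is the identity.
    """

    def fit(self, X, y=None) -> "ProfileQuantileNormalizer":
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] < 2:
            raise NormalizationError("quantile normalization needs >= 2 cells")
        self.reference_ = np.sort(arr, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        frame = isinstance(X, pd.DataFrame)
        arr = np.asarray(X, dtype=float)
        n, p = arr.shape
        if p == 1:
            return X
        out = np.empty_like(arr)
        ref = self.reference_
        for i in range(n):
            row = arr[i]
            order = np.argsort(row, kind="stable")
            mapped = np.empty(p)
            mapped[order] = ref
            # average reference values over ties
            uniq, inverse, counts = np.unique(row, return_inverse=True, return_counts=True)
            if np.any(counts > 1):
                sums = np.bincount(inverse, weights=mapped)
                mapped = (sums / counts)[inverse]
            out[i] = mapped
        if frame:
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


def clr_normalize(adt: AdtSample | pd.DataFrame) -> pd.DataFrame:
    counts = adt.counts if isinstance(adt, AdtSample) else adt
    return CLRNormalizer().fit_transform(counts)


def dsb_normalize(
    adt: AdtSample,
    background: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """DSB-style normalization of one sample; uses the sample's own
    empty-droplet matrix when none is passed explicitly."""
    if background is None:
        background = adt.background
    norm = DSBNormalizer(isotype_controls=adt.isotype_controls)
    norm.fit(adt.counts, background=background)
    return norm.transform(adt.counts)


def quantile_normalize_cells(matrix: pd.DataFrame | np.ndarray):
    return ProfileQuantileNormalizer().fit_transform(matrix)
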