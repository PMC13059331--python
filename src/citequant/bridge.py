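"""Cross-modality bridging: per-cell absolute antigen counts from CITE-seq.

Flow cytometry with calibration beads yields absolute antibodies-bound-per-
cell (ABC) distributions for a handful of bridge antigens per sample, but
the flow and CITE-seq aliquots contain different cells, so ABC and ADT
values cannot be paired cell-by-cell.  The bridge instead pairs the two
assays at the distribution level: empirical 5% quantiles of the normalized
ADT distribution are matched to the same quantiles of the log10 ABC
distribution, assuming rank alignment (the lowest ADT quantile corresponds
to the lowest ABC quantile).

A random-forest regression is then fit on all (sample, antigen, quantile)
observations, with the ADT quantile value plus the sample's 13 antibody-
library QC metrics as features and the log10 ABC quantile as target.  The
QC metrics let the model absorb sample-specific capture artifacts.  The
trained model is applied per cell — the cell's normalized ADT value stands
in for the quantile-value feature — to estimate log10 ABC for every antigen
in the panel, which is then unlogged.

Validation is leave-one-antigen-out: each bridge antigen is excluded from
training in turn, predicted per cell, and its sample-level mean compared
with the flow measurement.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

from .preprocess import QC_METRIC_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_QUANTILE_GRID",
    "UNDERSATURATED_ANTIBODIES",
    "QuantileMap",
    "AbcBridgeRegressor",
    "build_quantile_map",
    "build_training_table",
    "train_model",
    "predict_cell_abc",
    "leave_one_antigen_out",
    "save_model",
    "load_model",
]

#: Empirical quantile levels 0.05..0.95 (19 points); the extreme order
#: statistics (0 and 1) are excluded as too noisy.
DEFAULT_QUANTILE_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.05, 0.951, 0.05), 2)
)

#: Antibodies found undersaturated at the staining concentration used; their
#: estimates carry a caution flag but are not suppressed.
UNDERSATURATED_ANTIBODIES: frozenset[str] = frozenset(
    {"CD13", "CD45", "CD47", "CD99", "HLA-DR"}
)

FEATURE_ADT = "adt_quantile_value"
TARGET = "abc_log10_quantile"
MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class QuantileMap:
    """Paired empirical quantiles of normalized ADT and log10 ABC for one
    (sample, antigen)."""

    sample_id: str
    antigen: str
    levels: tuple[float, ...]
    adt_quantiles: tuple[float, ...]
    abc_log10_quantiles: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.size == 0 or np.any(np.diff(lv) <= 0):
            raise ValueError("quantile grid must be strictly increasing")
        if not (len(self.levels) == len(self.adt_quantiles) == len(self.abc_log10_quantiles)):
            raise ValueError("grid and quantile vectors must have equal length")
        for name in ("adt_quantiles", "abc_log10_quantiles"):
            if np.any(np.diff(np.asarray(getattr(self, name))) < -1e-12):
                raise ValueError(f"{name} must be non-decreasing along the grid")


def build_quantile_map(
    abc_values: Sequence[float],
    adt_values: Sequence[float],
    grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
    sample_id: str = "",
    antigen: str = "",
) -> QuantileMap:
    """Empirical quantiles (linear interpolation between order statistics)
    of the flow ABC distribution (log10 taken internally) and the normalized
    ADT distribution at the given grid levels."""
    abc = np.asarray(abc_values, dtype=float)
    adt = np.asarray(adt_values, dtype=float)
    if abc.size == 0 or adt.size == 0:
        raise ValueError("ABC and ADT vectors must be nonempty")
    if np.any(abc <= 0):
        raise ValueError("ABC values must be strictly positive (log10 is taken)")
    grid_arr = np.asarray(grid, dtype=float)
    if min(abc.size, adt.size) < grid_arr.size:
        warnings.warn(
            f"{sample_id}/{antigen}: fewer observations than grid points; "
            "quantiles defined by interpolation",
            stacklevel=2,
        )
    abc_q = np.quantile(np.log10(abc), grid_arr, method="linear")
    adt_q = np.quantile(adt, grid_arr, method="linear")
    return QuantileMap(
        sample_id=sample_id,
        antigen=antigen,
        levels=tuple(grid_arr),
        adt_quantiles=tuple(adt_q),
        abc_log10_quantiles=tuple(abc_q),
    )


def build_training_table(
    maps: Sequence[QuantileMap],
    qc: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """One row per (sample, antigen, grid level): the ADT quantile value and
    the sample's QC metrics as features, the log10 ABC quantile as target."""
    rows = []
    for qm in maps:
        if qm.sample_id not in qc:
            raise KeyError(f"no QC metrics for sample {qm.sample_id!r}")
        metrics = qc[qm.sample_id]
        missing = set(QC_METRIC_NAMES) - set(metrics.index)
        if missing:
            raise KeyError(f"sample {qm.sample_id!r} missing QC metrics: {sorted(missing)}")
        for level, adt_q, abc_q in zip(qm.levels, qm.adt_quantiles, qm.abc_log10_quantiles):
            row = {
                "sample_id": qm.sample_id,
                "antigen": qm.antigen,
                "level": level,
                FEATURE_ADT: adt_q,
                TARGET: abc_q,
            }
            for name in QC_METRIC_NAMES:
                row[name] = float(metrics[name])
            rows.append(row)
    return pd.DataFrame(rows)


class AbcBridgeRegressor(BaseEstimator, RegressorMixin):
    """Random-forest regression of log10 ABC quantiles on ADT quantiles and
    antibody QC metrics.

    Hyperparameters follow randomForest regression defaults: 500 trees,
    floor(p/3) candidate features per split, unlimited depth.  Cross-
    validation RMSE is estimated by 10-fold x 10-repeat resampling before
    the final fit on all rows; set ``cv_repeats=0`` to skip it.
    Deterministic under a fixed ``random_state``.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: int | str = "third",
        cv_folds: int = 10,
        cv_repeats: int = 10,
        random_state: Optional[int] = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.random_state = random_state

    def _make_forest(self, n_features: int) -> RandomForestRegressor:
        mtry = (
            max(1, n_features // 3)
            if self.max_features == "third"
            else self.max_features
        )
        return RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=mtry,
            random_state=self.random_state,
            n_jobs=1,
        )

    def fit(self, X: pd.DataFrame, y: Sequence[float]) -> "AbcBridgeRegressor":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        self.feature_names_ = list(X.columns)
        self.target_min_ = float(np.min(y))
        self.target_max_ = float(np.max(y))
        if np.ptp(y) == 0:
            warnings.warn("constant training target; model will predict the constant",
                          stacklevel=2)
        forest = self._make_forest(X.shape[1])
        if self.cv_repeats > 0 and len(y) >= self.cv_folds:
            cv = RepeatedKFold(
                n_splits=self.cv_folds,
                n_repeats=self.cv_repeats,
                random_state=self.random_state,
            )
            scores = -cross_val_score(
                self._make_forest(X.shape[1]),
                X.to_numpy(float),
                y,
                scoring="neg_root_mean_squared_error",
                cv=cv,
                n_jobs=1,
            )
            self.cv_rmse_mean_ = float(scores.mean())
            self.cv_rmse_sd_ = float(scores.std(ddof=1))
        else:
            self.cv_rmse_mean_ = float("nan")
            self.cv_rmse_sd_ = float("nan")
        forest.fit(X.to_numpy(float), y)
        self.forest_ = forest
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = pd.DataFrame(X)[self.feature_names_]
        return self.forest_.predict(X.to_numpy(float))


def train_model(
    table: pd.DataFrame,
    seed: Optional[int] = None,
    min_rows: int = 50,
    **kwargs,
) -> AbcBridgeRegressor:
    """Fit the bridge regressor on a training table (see
    :func:`build_training_table`)."""
    if len(table) < min_rows:
        raise ValueError(f"training table has {len(table)} rows; need >= {min_rows}")
    features = [FEATURE_ADT, *QC_METRIC_NAMES]
    model = AbcBridgeRegressor(random_state=seed, **kwargs)
    model.fit(table[features], table[TARGET].to_numpy(float))
    return model


def predict_cell_abc(
    model: AbcBridgeRegressor,
    normalized_adt: pd.DataFrame,
    qc: pd.Series,
    antigens: Optional[Sequence[str]] = None,
    clip_margin: float = 0.5,
) -> pd.DataFrame:
    """Per-cell antigen counts (linear scale) for every requested antigen.

    The cell's normalized ADT value substitutes for the quantile-value
    feature; the sample's QC metrics supply the remaining features.
    Predictions are clipped to the training target range +/- ``clip_margin``
    (log10) before unlogging, to prevent blow-ups outside the calibrated
    range; clipping events are logged.
    """
    antigens = list(antigens) if antigens is not None else list(normalized_adt.columns)
    missing = set(antigens) - set(normalized_adt.columns)
    if missing:
        raise KeyError(f"antigens missing from the normalized matrix: {sorted(missing)}")
    n_cells = normalized_adt.shape[0]
    lo = model.target_min_ - clip_margin
    hi = model.target_max_ + clip_margin
    out = {}
    n_clipped = 0
    for antigen in antigens:
        X = pd.DataFrame({FEATURE_ADT: normalized_adt[antigen].to_numpy(float)})
        for name in QC_METRIC_NAMES:
            X[name] = float(qc[name])
        pred = model.predict(X)
        n_clipped += int(np.sum((pred < lo) | (pred > hi)))
        out[antigen] = 10.0 ** np.clip(pred, lo, hi)
    if n_clipped:
        logger.info(
            "predict_cell_abc: clipped %d/%d predictions to [%.2f, %.2f] log10",
            n_clipped, n_cells * len(antigens), lo, hi,
        )
    return pd.DataFrame(out, index=normalized_adt.index)


def leave_one_antigen_out(
    maps: Sequence[QuantileMap],
    qc: Mapping[str, pd.Series],
    normalized_matrices: Mapping[str, pd.DataFrame],
    flow_mean_abc: Mapping[tuple[str, str], float],
    seed: Optional[int] = None,
    clip_margin: float = 0.5,
    cv_repeats: int = 0,
) -> pd.DataFrame:
    """Leave-one-antigen-out concordance validation.

    For each bridge antigen: train on the quantile maps of the other
    antigens, predict the excluded antigen per cell in every sample, and
    compare the sample-level mean predicted ABC against the flow-measured
    mean ABC.  Returns one row per excluded antigen with the Spearman
    correlation across samples and the median |log10 bias|; the per-sample
    table and per-iteration training antigens sit in ``attrs``.
    """
    bridge_antigens = sorted({qm.antigen for qm in maps})
    if len(bridge_antigens) < 2:
        raise ValueError("leave-one-antigen-out requires >= 2 bridge antigens")
    per_sample_rows = []
    report_rows = []
    training_antigens: dict[str, list[str]] = {}
    for excluded in bridge_antigens:
        kept = [qm for qm in maps if qm.antigen != excluded]
        table = build_training_table(kept, qc)
        assert excluded not in set(table["antigen"]), "excluded antigen leaked into training"
        training_antigens[excluded] = sorted(set(table["antigen"]))
        model = train_model(table, seed=seed, cv_repeats=cv_repeats)
        pred_means, flow_means = [], []
        for sample_id, matrix in normalized_matrices.items():
            if (sample_id, excluded) not in flow_mean_abc:
                continue
            est = predict_cell_abc(
                model, matrix, qc[sample_id], antigens=[excluded], clip_margin=clip_margin
            )
            pred_mean = float(est[excluded].mean())
            flow_mean = float(flow_mean_abc[(sample_id, excluded)])
            pred_means.append(pred_mean)
            flow_means.append(flow_mean)
            per_sample_rows.append(
                {
                    "excluded_antigen": excluded,
                    "sample_id": sample_id,
                    "mean_predicted_abc": pred_mean,
                    "mean_flow_abc": flow_mean,
                    "log10_bias": float(np.log10(pred_mean / flow_mean)),
                }
            )
        rho = stats.spearmanr(pred_means, flow_means).statistic
        bias = np.log10(np.asarray(pred_means) / np.asarray(flow_means))
        report_rows.append(
            {
                "excluded_antigen": excluded,
                "n_samples": len(pred_means),
                "spearman": float(rho),
                "median_abs_log10_bias": float(np.median(np.abs(bias))),
                "median_log10_bias": float(np.median(bias)),
            }
        )
    report = pd.DataFrame(report_rows)
    # plain containers only in attrs (DataFrames there break pandas display)
    report.attrs["per_sample"] = per_sample_rows
    report.attrs["training_antigens"] = training_antigens
    return report


def save_model(model: AbcBridgeRegressor, path) -> None:
    """Serialize a fitted model with its feature list, seed and a format
    version to a single file."""
    check_is_fitted(model, "forest_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": model.feature_names_,
        "random_state": model.random_state,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> AbcBridgeRegressor:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return payload["model"]
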