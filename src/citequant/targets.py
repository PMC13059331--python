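"""Target prioritization from per-cell antigen-count estimates.

Immunotherapeutic modalities require the target antigen both on a large
fraction of blasts and at sufficient density per cell (ADCs roughly
1,000-10,000 molecules, CAR-T substantially fewer).  The selection readouts
here follow that logic:

* per-antigen positivity and intensity summaries at a count threshold,
* pairwise co-expression fractions ("both antigens > threshold"),
* criterion-based ranking (default: >= 80% positivity and >= 1,000 antigens
  per cell, evaluated per sample/timepoint/population and aggregated as the
  fraction of samples passing),
* the LSC-enriched gate (positive stemness module score, CD34+ CD38- on
  CLR-normalized ADT).

The stemness module score follows the Seurat convention: mean expression of
the gene set minus the mean of expression-matched control genes drawn from
average-expression bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bridge import UNDERSATURATED_ANTIBODIES

__all__ = [
    "AntigenSummary",
    "LscGateParams",
    "positivity_and_intensity",
    "co_expression_fraction",
    "rank_targets",
    "module_score",
    "lsc_gate",
]

DEFAULT_POSITIVITY_MIN = 0.8
DEFAULT_COUNT_MIN = 1000.0


@dataclass(frozen=True)
class AntigenSummary:
    """Positivity/intensity summary for one (sample, antigen, population)."""

    sample_id: str
    antigen: str
    population: str  # "blast" | "lsc"
    threshold: float
    pct_positive: float
    mean_positive: float  # nan when no positive cells
    median_positive: float
    n_cells: int
    timepoint: str = ""
    caution: bool = False


@dataclass(frozen=True)
class LscGateParams:
    """Strict thresholds for the LSC-enriched gate."""

    module_score_min: float = 0.0
    cd34_clr_min: float = 1.0
    cd38_clr_max: float = 1.0


def positivity_and_intensity(
    estimates: pd.DataFrame,
    antigen: str,
    threshold: float = DEFAULT_COUNT_MIN,
    sample_id: str = "",
    population: str = "blast",
    timepoint: str = "",
) -> AntigenSummary:
    """Fraction of cells with estimated count strictly above the threshold,
    plus mean/median count among those positive cells."""
    if antigen not in estimates.columns:
        raise KeyError(f"antigen {antigen!r} not in estimates")
    if threshold <= 0 and threshold != 0:
        raise ValueError("threshold must be nonnegative")
    counts = estimates[antigen].to_numpy(float)
    if counts.size == 0:
        raise ValueError(f"{sample_id}/{antigen}: empty cell population")
    positive = counts > threshold
    pct = float(positive.mean())
    if positive.any():
        mean_pos = float(counts[positive].mean())
        median_pos = float(np.median(counts[positive]))
    else:
        mean_pos = median_pos = float("nan")
    return AntigenSummary(
        sample_id=sample_id,
        antigen=antigen,
        population=population,
        threshold=float(threshold),
        pct_positive=pct,
        mean_positive=mean_pos,
        median_positive=median_pos,
        n_cells=int(counts.size),
        timepoint=timepoint,
        caution=antigen in UNDERSATURATED_ANTIBODIES,
    )


def co_expression_fraction(
    estimates: pd.DataFrame,
    antigen_a: str,
    antigen_b: str,
    threshold: float = DEFAULT_COUNT_MIN,
) -> float:
    """Fraction of cells with both antigens strictly above the threshold;
    symmetric in the antigen pair."""
    for antigen in (antigen_a, antigen_b):
        if antigen not in estimates.columns:
            raise KeyError(f"antigen {antigen!r} not in estimates")
    a = estimates[antigen_a].to_numpy(float)
    b = estimates[antigen_b].to_numpy(float)
    return float(np.mean((a > threshold) & (b > threshold)))


def rank_targets(
    summaries: Sequence[AntigenSummary],
    positivity_min: float = DEFAULT_POSITIVITY_MIN,
    count_min: float = DEFAULT_COUNT_MIN,
) -> pd.DataFrame:
    """Rank antigens by pooled median count among positive cells.

    Each summary (one per sample/timepoint/population) passes the selection
    criterion when pct_positive >= positivity_min AND median count among
    positive cells >= count_min.  Antigens are aggregated as the fraction of
    summaries passing and sorted by the median of per-sample median counts,
    descending; ties break alphabetically.  Caution flags (undersaturated
    antibodies) are propagated.  A free ``annotation`` column is left for
    external notes (e.g. healthy-tissue screening, which is outside this
    package's scope).
    """
    if not summaries:
        raise ValueError("no summaries to rank")
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "antigen": [s.antigen for s in summaries],
            "population": [s.population for s in summaries],
            "timepoint": [s.timepoint for s in summaries],
            "pct_positive": [s.pct_positive for s in summaries],
            "median_positive": [s.median_positive for s in summaries],
            "caution": [s.caution for s in summaries],
        }
    )
    df["passes"] = (df["pct_positive"] >= positivity_min) & (
        df["median_positive"].fillna(0.0) >= count_min
    )
    ranked = (
        df.groupby("antigen")
        .agg(
            n_samples=("sample_id", "size"),
            criterion_fraction=("passes", "mean"),
            median_count=("median_positive", "median"),
            median_pct_positive=("pct_positive", "median"),
            caution=("caution", "any"),
        )
        .reset_index()
        .sort_values(
            ["median_count", "antigen"], ascending=[False, True], kind="stable"
        )
        .reset_index(drop=True)
    )
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked["annotation"] = ""
    ranked.attrs["per_sample"] = df.to_dict("records")
    return ranked


def module_score(
    expression: pd.DataFrame,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: Optional[int] = None,
) -> pd.Series:
    """Expression-bin-matched module score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins by pooled average
    expression (ties to the lower bin).  For every gene-set gene, ``n_ctrl``
    control genes are sampled (seeded) from its bin; the score is the mean
    expression of the gene set minus the mean of the pooled control genes.
    Gene-set genes absent from the matrix are dropped with a warning.
    """
    if expression.shape[1] < n_bins:
        raise ValueError(
            f"need >= {n_bins} genes to form {n_bins} expression bins; "
            f"got {expression.shape[1]}"
        )
    present = [g for g in gene_set if g in expression.columns]
    dropped = sorted(set(gene_set) - set(present))
    if dropped:
        warnings.warn(f"module_score: dropping genes absent from matrix: {dropped}",
                      stacklevel=2)
    if not present:
        raise ValueError("gene set is empty after intersecting with the matrix")
    rng = np.random.default_rng(seed)
    pooled_mean = expression.mean(axis=0)
    # equal-frequency bins on average expression; average ranks put tied
    # genes in the same (lower) bin
    ranks = pooled_mean.rank(method="average")
    bins = np.minimum(
        ((ranks - 1) / len(ranks) * n_bins).astype(int), n_bins - 1
    )
    controls: list[str] = []
    genes = np.asarray(expression.columns)
    in_set = np.isin(genes, present)
    for g in present:
        same_bin = (bins == bins[g]).to_numpy()
        candidates = genes[same_bin & ~in_set]
        if candidates.size == 0:  # bin holds only gene-set genes
            candidates = genes[same_bin]
        take = min(n_ctrl, candidates.size)
        controls.extend(rng.choice(candidates, size=take, replace=False))
    score = expression[present].mean(axis=1) - expression[list(controls)].mean(axis=1)
    score.name = "module_score"
    return score


def lsc_gate(
    scores: Sequence[float],
    cd34_clr: Sequence[float],
    cd38_clr: Sequence[float],
    params: LscGateParams = LscGateParams(),
) -> np.ndarray:
    """Boolean LSC-enriched mask: module score > 0, CD34 CLR > 1 and
    CD38 CLR < 1 (all strict)."""
    s = np.asarray(scores, dtype=float)
    cd34 = np.asarray(cd34_clr, dtype=float)
    cd38 = np.asarray(cd38_clr, dtype=float)
    if not (s.shape == cd34.shape == cd38.shape):
        raise ValueError("score and CLR vectors must have equal length")
    return (
        (s > params.module_score_min)
        & (cd34 > params.cd34_clr_min)
        & (cd38 < params.cd38_clr_max)
    )
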