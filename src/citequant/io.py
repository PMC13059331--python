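"""Disk formats: Matrix Market ADT matrices, flow/bead/QC CSV tables.

The on-disk layout per sample mirrors the Cell Ranger convention: a sparse
``matrix.mtx`` with features as rows and cells as columns, plus
``barcodes.tsv`` and ``features.tsv`` (the latter carrying a ``feature_type``
column that flags isotype controls).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import AdtSample

__all__ = [
    "write_adt_sample",
    "read_adt_sample",
    "read_adt_csv",
    "write_flow_csv",
    "write_bead_csv",
    "write_json",
]

ISOTYPE_TYPE = "Isotype Control"
ANTIBODY_TYPE = "Antibody Capture"


def write_adt_sample(adt: AdtSample, directory) -> list[Path]:
    """Write one sample as matrix.mtx + barcodes.tsv + features.tsv, with
    sidecar CSVs for per-cell QC, library QC metrics and background."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    matrix = sparse.csr_matrix(adt.counts.to_numpy().T)  # features x cells
    mtx_path = directory / "matrix.mtx"
    spio.mmwrite(str(mtx_path), matrix, field="integer")
    written.append(mtx_path)

    barcodes = directory / "barcodes.tsv"
    pd.Series(adt.counts.index).to_csv(barcodes, sep="\t", index=False, header=False)
    written.append(barcodes)

    features = directory / "features.tsv"
    feat = pd.DataFrame(
        {
            "name": adt.counts.columns,
            "feature_type": [
                ISOTYPE_TYPE if c in adt.isotype_controls else ANTIBODY_TYPE
                for c in adt.counts.columns
            ],
        }
    )
    feat.to_csv(features, sep="\t", index=False, header=False)
    written.append(features)

    if adt.cell_qc is not None:
        path = directory / "cell_qc.csv"
        adt.cell_qc.to_csv(path, index_label="barcode")
        written.append(path)
    if adt.qc_metrics is not None:
        path = directory / "qc_metrics.csv"
        adt.qc_metrics.rename("value").to_csv(path, index_label="metric")
        written.append(path)
    if adt.background is not None:
        path = directory / "background.csv"
        adt.background.to_csv(path, index=False)
        written.append(path)
    return written


def read_adt_sample(directory, sample_id: Optional[str] = None) -> AdtSample:
    """Read a sample written by :func:`write_adt_sample`."""
    directory = Path(directory)
    matrix = spio.mmread(str(directory / "matrix.mtx")).toarray().T  # cells x features
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    feat = pd.read_csv(directory / "features.tsv", sep="\t", header=None,
                       names=["name", "feature_type"])
    counts = pd.DataFrame(
        np.asarray(matrix), index=barcodes.to_list(), columns=feat["name"].to_list()
    )
    isotypes = tuple(feat.loc[feat["feature_type"] == ISOTYPE_TYPE, "name"])
    cell_qc = qc_metrics = background = None
    if (directory / "cell_qc.csv").exists():
        cell_qc = pd.read_csv(directory / "cell_qc.csv", index_col="barcode")
    if (directory / "qc_metrics.csv").exists():
        qc_metrics = pd.read_csv(directory / "qc_metrics.csv", index_col="metric")["value"]
    if (directory / "background.csv").exists():
        background = pd.read_csv(directory / "background.csv")
    return AdtSample(
        sample_id=sample_id or directory.name,
        counts=counts,
        isotype_controls=isotypes,
        cell_qc=cell_qc,
        qc_metrics=qc_metrics,
        background=background,
    )


def read_adt_csv(path, sample_id: str, isotype_controls: tuple[str, ...] = ()) -> AdtSample:
    """Read a dense cells-x-antibodies count CSV (first column = barcode)."""
    counts = pd.read_csv(path, index_col=0)
    return AdtSample(sample_id=sample_id, counts=counts, isotype_controls=isotype_controls)


def write_flow_csv(flow_samples, path) -> Path:
    """Write per-event flow CSV (sample_id, antigen, fluorescence, gate,
    fmo_threshold) for a collection of FlowSample objects."""
    frames = []
    for fs in flow_samples:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": fs.sample_id,
                    "antigen": fs.antigen,
                    "fluorescence": fs.intensities,
                    "gate": fs.gates,
                    "fmo_threshold": fs.fmo_threshold,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def write_bead_csv(beads, path) -> Path:
    pd.DataFrame(
        {
            "population": [f"bead{i + 1}" for i in range(len(beads.pe_per_bead))],
            "pe_per_bead": beads.pe_per_bead,
            "gmfi": beads.gmfi,
        }
    ).to_csv(path, index=False)
    return Path(path)


def write_json(obj, path) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return Path(path)
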