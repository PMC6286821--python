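"""Reading/writing beta matrices and sample sheets, coverage-based QC, and
k-nearest-neighbour imputation.

QC follows the standard array-processing recipe: probe coverage is the
fraction of samples with detection p-value below ``detection_alpha``; probes
with coverage < 0.99 are removed first, then sample coverage is recomputed
over the surviving probes and samples with coverage < 0.95 are removed.
Remaining missing values are imputed from the k nearest probes (k = 5 by
default), with Euclidean distance over pairwise-complete samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import DatasetError, MethylationDataset

__all__ = [
    "QcThresholds",
    "read_beta_table",
    "write_dataset",
    "qc_filter",
    "knn_impute",
]


@dataclass(frozen=True)
class QcThresholds:
    """Coverage-filter levels; strictly-below-threshold items are removed."""

    detection_alpha: float = 0.05
    probe_coverage_min: float = 0.99
    sample_coverage_min: float = 0.95

    def __post_init__(self):
        for name in ("detection_alpha", "probe_coverage_min", "sample_coverage_min"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0,1]")


def _read_matrix(path) -> pd.DataFrame:
    """TSV matrix, first column = probe ID; GEO series-matrix '!' header
    lines are skipped."""
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0)
    df.index.name = "probe_id"
    return df


def read_beta_table(
    path, sample_sheet_path, detection_p_path=None, name: Optional[str] = None
) -> MethylationDataset:
    """Read a TSV beta matrix plus CSV sample sheet into a dataset.

    Sample IDs in the sheet (column ``sample_id`` or the first column) must
    match the matrix columns exactly; mismatches fail hard naming offenders.
    """
    beta = _read_matrix(path).astype(float)
    sheet = pd.read_csv(sample_sheet_path)
    id_col = "sample_id" if "sample_id" in sheet.columns else sheet.columns[0]
    sheet = sheet.set_index(id_col)
    sheet.index = sheet.index.astype(str)
    beta.columns = beta.columns.astype(str)

    missing = [s for s in beta.columns if s not in sheet.index]
    extra = [s for s in sheet.index if s not in beta.columns]
    if missing or extra:
        raise DatasetError(
            f"sample sheet mismatch; absent from sheet: {missing}; "
            f"absent from matrix: {extra}"
        )
    sheet = sheet.loc[list(beta.columns)]

    detection_p = None
    if detection_p_path is not None:
        detection_p = _read_matrix(detection_p_path).astype(float)
        detection_p.columns = detection_p.columns.astype(str)
        detection_p = detection_p.loc[beta.index, beta.columns]

    return MethylationDataset(
        beta=beta,
        annotations=sheet,
        detection_p=detection_p,
        name=name or Path(str(path)).stem,
    )


def write_dataset(dataset: MethylationDataset, outdir, prefix: str = "dataset") -> dict:
    """Write beta TSV, sample-sheet CSV and (if present) detection-p TSV.

    Returns a dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    beta_path = outdir / f"{prefix}_beta.tsv"
    dataset.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    paths["beta"] = beta_path
    sheet_path = outdir / f"{prefix}_samples.csv"
    dataset.annotations.to_csv(sheet_path, index_label="sample_id")
    paths["sample_sheet"] = sheet_path
    if dataset.detection_p is not None:
        det_path = outdir / f"{prefix}_detection_p.tsv"
        dataset.detection_p.to_csv(det_path, sep="\t", index_label="probe_id")
        paths["detection_p"] = det_path
    return paths


def qc_filter(
    dataset: MethylationDataset, thresholds: QcThresholds = QcThresholds()
) -> MethylationDataset:
    """Coverage filter: probes first, then samples over surviving probes.

    Coverage of a probe = fraction of samples with detection p <
    ``detection_alpha``; probes with coverage < ``probe_coverage_min`` are
    dropped, then sample coverage is recomputed on the surviving probes and
    samples below ``sample_coverage_min`` are dropped. Comparisons are
    strict, so items exactly at the threshold are kept. Order of surviving
    probes and samples is preserved.
    """
    if dataset.detection_p is None:
        raise ValueError("qc_filter requires a detection p-value matrix")
    det = dataset.detection_p.to_numpy(dtype=float)
    good = det < thresholds.detection_alpha

    probe_cov = good.mean(axis=1)
    keep_probes = probe_cov >= thresholds.probe_coverage_min
    if not keep_probes.any():
        raise DatasetError("QC removed every probe; check detection p-values")

    sample_cov = good[keep_probes].mean(axis=0)
    keep_samples = sample_cov >= thresholds.sample_coverage_min
    if not keep_samples.any():
        raise DatasetError("QC removed every sample; check detection p-values")

    probes = dataset.probe_ids[keep_probes]
    samples = dataset.sample_ids[keep_samples]
    return MethylationDataset(
        beta=dataset.beta.loc[probes, samples],
        annotations=dataset.annotations.loc[samples],
        detection_p=dataset.detection_p.loc[probes, samples],
        name=dataset.name,
    )


def knn_impute(
    dataset: MethylationDataset, k: int = 5, max_missing_fraction: float = 0.5
) -> MethylationDataset:
    """Impute missing betas from the k nearest probes.

    Neighbour distance is Euclidean over the samples where both probes are
    observed (pairwise-complete); each missing cell becomes the mean of the k
    nearest probes' observed values at that sample. Observed values are
    never altered.
    """
    X = dataset.beta.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return dataset
    if k < 1:
        raise ValueError("k must be >= 1")

    row_missing_frac = miss.mean(axis=1)
    if (row_missing_frac >= 1.0).any():
        bad = dataset.probe_ids[row_missing_frac >= 1.0].tolist()
        raise DatasetError(f"probes with all values missing: {bad[:5]}")
    if (row_missing_frac > max_missing_fraction).any():
        bad = dataset.probe_ids[row_missing_frac > max_missing_fraction].tolist()
        raise DatasetError(
            f"probes exceed the missing-fraction cap {max_missing_fraction}: {bad[:5]}"
        )

    rows_to_fill = np.flatnonzero(miss.any(axis=1))
    obs = ~miss
    X0 = np.where(miss, 0.0, X)
    filled = X.copy()
    for i in rows_to_fill:
        both = obs & obs[i]  # co-observed mask vs every probe
        diff = X0 - X0[i]
        d2 = np.where(both, diff, 0.0) ** 2
        dist = np.sqrt(d2.sum(axis=1))
        dist[i] = np.inf
        dist[~both.any(axis=1)] = np.inf  # no co-observed samples
        for j in np.flatnonzero(miss[i]):
            cand = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if cand.size == 0:
                raise DatasetError(
                    f"no observed neighbours for probe {dataset.probe_ids[i]} "
                    f"at sample {dataset.sample_ids[j]}"
                )
            nearest = cand[np.argsort(dist[cand], kind="mergesort")[:k]]
            filled[i, j] = X[nearest, j].mean()

    beta = pd.DataFrame(filled, index=dataset.probe_ids, columns=dataset.sample_ids)
    return MethylationDataset(
        beta=beta,
        annotations=dataset.annotations,
        detection_p=dataset.detection_p,
        name=dataset.name,
    )
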