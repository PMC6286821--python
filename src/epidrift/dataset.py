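"""Core in-memory container for methylation array data.

A :class:`MethylationDataset` couples a probes-by-samples beta-value matrix
(values in [0, 1], NaN allowed pre-imputation) with a per-sample annotation
table (age in years, sex, batch, tissue, and optionally known cell-type
fractions) and, optionally, a detection p-value matrix of identical shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: prefix used for true/estimated cell-fraction columns in annotation tables
FRACTION_PREFIX = "frac_"

BETA_RANGE_TOL = 1e-6


class DatasetError(ValueError):
    """Raised when a dataset violates its structural contract."""


@dataclass
class MethylationDataset:
    """Beta matrix (probes x samples) plus aligned per-sample annotations.

    Parameters
    ----------
    beta
        DataFrame indexed by probe ID with one column per sample. Values must
        lie in [0, 1] (tolerance 1e-6); NaN marks missing values.
    annotations
        DataFrame indexed by sample ID, aligned 1:1 with ``beta.columns``.
        Conventional columns: ``age`` (years), ``sex``, ``batch``, ``tissue``,
        and ``frac_<cell_type>`` columns holding cell fractions.
    detection_p
        Optional matrix of detection p-values with the same index/columns as
        ``beta``.
    name
        Free-text label used in reports.
    """

    beta: pd.DataFrame
    annotations: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.beta.index.has_duplicates:
            dupes = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate probe IDs: {dupes[:5]}")
        if self.beta.columns.has_duplicates:
            dupes = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate sample IDs: {dupes[:5]}")
        if list(self.beta.columns) != list(self.annotations.index):
            missing = [s for s in self.beta.columns if s not in self.annotations.index]
            extra = [s for s in self.annotations.index if s not in self.beta.columns]
            raise DatasetError(
                "sample sheet does not align with beta matrix columns; "
                f"missing from sheet: {missing[:5]}; extra in sheet: {extra[:5]}"
            )
        values = self.beta.to_numpy(dtype=float)
        finite = values[np.isfinite(values)]
        if finite.size and (
            finite.min() < -BETA_RANGE_TOL or finite.max() > 1 + BETA_RANGE_TOL
        ):
            raise DatasetError(
                f"beta values outside [0,1]: range [{finite.min()}, {finite.max()}]"
            )
        if "age" in self.annotations.columns:
            ages = pd.to_numeric(self.annotations["age"], errors="raise")
            if (ages <= 0).any():
                raise DatasetError("ages must be positive (years)")
        if self.detection_p is not None:
            if self.detection_p.shape != self.beta.shape:
                raise DatasetError("detection_p shape differs from beta matrix")
            if list(self.detection_p.index) != list(self.beta.index) or list(
                self.detection_p.columns
            ) != list(self.beta.columns):
                raise DatasetError("detection_p index/columns differ from beta matrix")

    # ------------------------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    @property
    def ages(self) -> pd.Series:
        return pd.to_numeric(self.annotations["age"])

    def fraction_columns(self) -> list[str]:
        """Names of cell-fraction annotation columns (``frac_*``)."""
        return [c for c in self.annotations.columns if c.startswith(FRACTION_PREFIX)]

    # ------------------------------------------------------------------
    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationDataset":
        """Return the dataset restricted to ``sample_ids`` (order preserved)."""
        ids = list(sample_ids)
        det = self.detection_p[ids] if self.detection_p is not None else None
        return MethylationDataset(
            beta=self.beta[ids],
            annotations=self.annotations.loc[ids],
            detection_p=det,
            name=self.name,
        )

    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        ids = list(probe_ids)
        det = self.detection_p.loc[ids] if self.detection_p is not None else None
        return MethylationDataset(
            beta=self.beta.loc[ids],
            annotations=self.annotations,
            detection_p=det,
            name=self.name,
        )

    def with_annotations(self, extra: pd.DataFrame) -> "MethylationDataset":
        """Return a copy with extra annotation columns joined on sample ID."""
        ann = self.annotations.join(extra, how="left")
        return replace(self, annotations=ann)
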