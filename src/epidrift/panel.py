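"""Pan-tissue analysis of a fixed CpG panel (e.g. an epigenetic-clock panel).

Given age-regression tables from several cell/tissue types, each panel CpG
gets a signed significance value sign(t) * (-log10 p) per dataset, an aDMP
flag (genome-wide FDR q < 0.05 by default), a sharing count (number of
datasets flagged) and the cumulative proportion of the panel shared in at
least k datasets — the machinery behind "most clock CpGs are pan-tissue
aDMPs" summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .admp import AdmpTable

__all__ = ["PanelSummary", "panel_sharing"]


@dataclass
class PanelSummary:
    """Per-CpG, per-dataset panel statistics and sharing summaries.

    Attributes
    ----------
    signed_significance
        CpG x dataset frame of sign(t) * (-log10 p); NaN = not assessed.
    admp_flag
        CpG x dataset nullable-boolean frame (NA = CpG absent from that
        dataset's array).
    direction
        "hyper"/"hypo" per (CpG, dataset), NA where not assessed.
    sharing_count
        Number of datasets in which the CpG is flagged.
    cumulative_proportion
        For each k in 1..n_datasets, the fraction of panel CpGs (assessed in
        >= 1 dataset) with sharing count >= k; non-increasing in k.
    missing_per_dataset
        CpGs absent per dataset (recorded, not silently dropped).
    """

    signed_significance: pd.DataFrame
    admp_flag: pd.DataFrame
    direction: pd.DataFrame
    sharing_count: pd.Series
    cumulative_proportion: pd.Series
    missing_per_dataset: dict
    alpha: float

    @property
    def n_datasets(self) -> int:
        return self.signed_significance.shape[1]

    def specific_cpgs(self) -> set[str]:
        """CpGs flagged in exactly one dataset (the 'tissue-specific' bucket)."""
        return set(self.sharing_count.index[self.sharing_count == 1])

    def to_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "alpha": self.alpha,
            "cumulative_proportion": {
                int(k): float(v) for k, v in self.cumulative_proportion.items()
            },
            "n_specific": len(self.specific_cpgs()),
            "n_panel": len(self.sharing_count),
        }


def panel_sharing(
    panel: Sequence[str],
    tables: Sequence[tuple[str, AdmpTable]],
    alpha: float = 0.05,
    strict: bool = False,
) -> PanelSummary:
    """Compute sharing statistics for a CpG panel across datasets.

    aDMP flags use each table's genome-wide q-values (q < ``alpha``), not an
    FDR recomputed within the panel: the per-dataset analyses the flags
    summarise were genome-wide. CpGs absent from a dataset's array are
    recorded as not assessed; with ``strict=True`` they instead count as not
    significant.
    """
    panel = list(dict.fromkeys(panel))  # de-dup, keep order
    if not panel:
        raise ValueError("empty CpG panel")
    if not tables:
        raise ValueError("need at least one aDMP table")

    labels = [label for label, _ in tables]
    if len(set(labels)) != len(labels):
        raise ValueError("dataset labels must be unique")

    signed = pd.DataFrame(index=pd.Index(panel, name="cpg"), columns=labels, dtype=float)
    flags = pd.DataFrame(index=signed.index, columns=labels, dtype="boolean")
    direction = pd.DataFrame(index=signed.index, columns=labels, dtype=object)
    missing = {}
    for label, table in tables:
        if "q" not in table.table.columns:
            raise ValueError(f"table {label!r} lacks q-values; run adjust_pvalues")
        present = [c for c in panel if c in table.table.index]
        missing[label] = sorted(set(panel) - set(present))
        sub = table.table.loc[present]
        with np.errstate(divide="ignore"):
            logp = -np.log10(np.maximum(sub["p"].to_numpy(), 1e-300))
        signed.loc[present, label] = np.sign(sub["t"].to_numpy()) * logp
        flags.loc[present, label] = (sub["q"].to_numpy() < alpha) & (
            ~sub["degenerate"].to_numpy(dtype=bool)
        )
        direction.loc[present, label] = np.where(
            sub["t"].to_numpy() > 0, "hyper", "hypo"
        )

    assessed_any = flags.notna().any(axis=1)
    if not assessed_any.any():
        raise ValueError("no panel CpG is assessed in any dataset")
    flags = flags[assessed_any]
    signed = signed[assessed_any]
    direction = direction[assessed_any]

    filled = flags.fillna(False).astype(bool) if strict else flags
    sharing = filled.fillna(False).astype(bool).sum(axis=1)

    n_datasets = len(labels)
    n_panel = len(sharing)
    cumulative = pd.Series(
        {k: float((sharing >= k).sum()) / n_panel for k in range(1, n_datasets + 1)},
        name="cumulative_proportion",
    )
    return PanelSummary(
        signed_significance=signed,
        admp_flag=flags,
        direction=direction,
        sharing_count=sharing,
        cumulative_proportion=cumulative,
        missing_per_dataset=missing,
        alpha=alpha,
    )
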