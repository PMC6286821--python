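"""Cross-dataset sharing of aDMP sets.

Overlap significance uses the upper-tail hypergeometric test (pairwise, and
a nested construction for triple overlaps); directional concordance
cross-tabulates t-statistic signs between a discovery and a validation
dataset and applies a one-tailed Fisher exact test; cross-validation
fractions quantify how many discovery aDMPs survive a criterion in a second
dataset; and mean-DNAm profiles expose the beta-scale selection bias of
effect-size thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .admp import AdmpTable, SelectionCriterion, select_admps
from .dataset import MethylationDataset

__all__ = [
    "OverlapResult",
    "ConcordanceResult",
    "hypergeometric_overlap",
    "nested_overlap",
    "tstat_concordance",
    "cross_validation_fractions",
    "estimate_shared_fraction",
    "mean_dnam_profile",
]


def hypergeometric_overlap(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value of the overlap of two probe sets.

    P(X >= |A∩B|) with X ~ Hypergeometric(universe_size, |B| successes,
    |A| draws).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set size exceeds universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))


@dataclass
class OverlapResult:
    """Venn-region counts and hypergeometric p-values for three sets."""

    universe_size: int
    labels: tuple[str, str, str]
    region_counts: dict  # exclusive Venn regions keyed by frozenset of labels
    pairwise_p: dict  # {(labelA, labelB): p of the full pairwise overlap}
    triple_count: int
    triple_p: float

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "labels": list(self.labels),
            "regions": {"&".join(sorted(k)): v for k, v in self.region_counts.items()},
            "pairwise_p": {"&".join(k): v for k, v in self.pairwise_p.items()},
            "triple_count": self.triple_count,
            "triple_p": self.triple_p,
        }


def nested_overlap(
    sets: Sequence[Iterable], universe_size: int, labels: Sequence[str] = ("A", "B", "C")
) -> OverlapResult:
    """Three-set overlap with pairwise and nested triple hypergeometric tests.

    Reports the seven exclusive Venn-region counts. Pairwise p-values test
    each full pairwise intersection. The triple p-value is nested: it
    conditions on the observed A∩B and asks how surprising the triple
    overlap is, P(X >= |A∩B∩C|) with X ~ Hypergeometric(universe_size,
    |C| successes, |A∩B| draws).
    """
    if len(sets) != 3:
        raise ValueError("nested_overlap expects exactly three sets")
    A, B, C = (set(s) for s in sets)
    la, lb, lc = labels
    for s in (A, B, C):
        if len(s) > universe_size:
            raise ValueError("set size exceeds universe")

    abc = A & B & C
    regions = {
        frozenset([la]): len(A - B - C),
        frozenset([lb]): len(B - A - C),
        frozenset([lc]): len(C - A - B),
        frozenset([la, lb]): len((A & B) - C),
        frozenset([la, lc]): len((A & C) - B),
        frozenset([lb, lc]): len((B & C) - A),
        frozenset([la, lb, lc]): len(abc),
    }
    pairwise_p = {
        (la, lb): hypergeometric_overlap(A, B, universe_size),
        (la, lc): hypergeometric_overlap(A, C, universe_size),
        (lb, lc): hypergeometric_overlap(B, C, universe_size),
    }
    ab = len(A & B)
    triple_p = float(stats.hypergeom.sf(len(abc) - 1, universe_size, len(C), ab))
    return OverlapResult(
        universe_size=universe_size,
        labels=tuple(labels),
        region_counts=regions,
        pairwise_p=pairwise_p,
        triple_count=len(abc),
        triple_p=triple_p,
    )


@dataclass
class ConcordanceResult:
    """Sign agreement of age t-statistics between two datasets.

    Quadrant counts cover discovery aDMPs reaching the validation p
    threshold, cross-tabulated by sign(t) in each dataset; discovery aDMPs
    failing validation are counted separately.
    """

    quadrant_counts: dict  # {("+","+"): n, ("+","-"): n, ...}
    n_not_validated: int
    fisher_p: float
    n_discovery: int
    discovery_criterion: str
    validation_alpha: float

    @property
    def n_agree(self) -> int:
        return self.quadrant_counts[("+", "+")] + self.quadrant_counts[("-", "-")]

    @property
    def n_validated(self) -> int:
        return sum(self.quadrant_counts.values())

    def to_dict(self) -> dict:
        return {
            "quadrants": {"".join(k): v for k, v in self.quadrant_counts.items()},
            "n_not_validated": self.n_not_validated,
            "fisher_p": self.fisher_p,
            "n_discovery": self.n_discovery,
            "discovery_criterion": self.discovery_criterion,
            "validation_alpha": self.validation_alpha,
        }


def tstat_concordance(
    discovery: AdmpTable,
    validation: AdmpTable,
    discovery_criterion: SelectionCriterion = SelectionCriterion.fdr(0.05),
    validation_alpha: float = 0.05,
) -> ConcordanceResult:
    """Directional concordance of aDMPs between two datasets.

    Discovery aDMPs present in both probe universes and reaching
    ``validation_alpha`` in the validation dataset are cross-tabulated by
    the signs of their two t-statistics; a one-tailed Fisher exact test
    assesses enrichment of sign agreement. Probes with t exactly 0 are
    excluded from the sign table.
    """
    admps = select_admps(discovery, discovery_criterion)
    shared = set(discovery.probe_ids) & set(validation.probe_ids)
    admps = admps & shared
    if not admps:
        raise ValueError("empty discovery aDMP set on the shared universe")
    probes = sorted(admps)
    td = discovery.table.loc[probes, "t"].to_numpy()
    tv = validation.table.loc[probes, "t"].to_numpy()
    pv = validation.table.loc[probes, "p"].to_numpy()

    validated = (pv < validation_alpha) & (td != 0) & (tv != 0)
    n_not = int(len(probes) - validated.sum())
    sd = np.sign(td[validated])
    sv = np.sign(tv[validated])
    counts = {
        ("+", "+"): int(((sd > 0) & (sv > 0)).sum()),
        ("+", "-"): int(((sd > 0) & (sv < 0)).sum()),
        ("-", "+"): int(((sd < 0) & (sv > 0)).sum()),
        ("-", "-"): int(((sd < 0) & (sv < 0)).sum()),
    }
    table = [
        [counts[("+", "+")], counts[("+", "-")]],
        [counts[("-", "+")], counts[("-", "-")]],
    ]
    _, fisher_p = stats.fisher_exact(table, alternative="greater")
    return ConcordanceResult(
        quadrant_counts=counts,
        n_not_validated=n_not,
        fisher_p=float(fisher_p),
        n_discovery=len(probes),
        discovery_criterion=discovery_criterion.label,
        validation_alpha=validation_alpha,
    )


def cross_validation_fractions(
    discovery: AdmpTable,
    validation: AdmpTable,
    discovery_criterion: SelectionCriterion,
    validation_criteria: Sequence[SelectionCriterion],
) -> pd.DataFrame:
    """Fraction of discovery aDMPs satisfying each criterion in validation.

    The discovery set is intersected with the validation probe universe;
    for each validation criterion the count and fraction of those probes
    that pass it in the validation table are returned.
    """
    admps = select_admps(discovery, discovery_criterion)
    shared = admps & set(validation.probe_ids)
    rows = []
    for crit in validation_criteria:
        passed = select_admps(validation, crit) & shared
        frac = len(passed) / len(shared) if shared else float("nan")
        rows.append(
            {
                "validation_criterion": crit.label,
                "n_discovery": len(shared),
                "n_validated": len(passed),
                "fraction": frac,
            }
        )
    return pd.DataFrame(rows).set_index("validation_criterion")


def estimate_shared_fraction(
    discovery: AdmpTable,
    validation: AdmpTable,
    n_cell_types: int,
    discovery_criterion: SelectionCriterion = SelectionCriterion.fdr(0.05),
    validation_criterion: SelectionCriterion = SelectionCriterion.fdr(0.05),
    require_sign_agreement: bool = True,
) -> tuple[float, float]:
    """Estimate the shared fraction of drift from a validated fraction.

    Model: an age-affected probe is shared across all C cell types with
    probability s, otherwise specific to one of the C uniformly at random.
    At high power the fraction v of discovery aDMPs that validate in a
    second cell type satisfies v = s / (s + (1-s)/C), inverted here as
    s = v / (C - (C-1) v).

    Returns (shared_fraction_estimate, validated_fraction).
    """
    if n_cell_types < 2:
        raise ValueError("need at least two cell types")
    admps = select_admps(discovery, discovery_criterion)
    shared_universe = admps & set(validation.probe_ids)
    if not shared_universe:
        raise ValueError("no discovery aDMPs on the shared universe")
    validated = select_admps(validation, validation_criterion) & shared_universe
    if require_sign_agreement:
        probes = sorted(validated)
        td = np.sign(discovery.table.loc[probes, "t"].to_numpy())
        tv = np.sign(validation.table.loc[probes, "t"].to_numpy())
        validated = {p for p, a, b in zip(probes, td, tv) if a == b and a != 0}
    v = len(validated) / len(shared_universe)
    C = n_cell_types
    s = v / (C - (C - 1) * v)
    return float(np.clip(s, 0.0, 1.0)), float(v)


def mean_dnam_profile(
    dataset: MethylationDataset, probe_sets: Mapping[str, Iterable]
) -> tuple[dict[str, pd.Series], pd.DataFrame]:
    """Per-probe mean beta profiles of labelled probe sets.

    Returns (per-set Series of per-probe means, summary frame with deciles
    and the fraction of means below 0.1 / above 0.9 — the tails depleted by
    beta-scale effect-size selection). Unknown probes are dropped with a
    warning.
    """
    means_all = dataset.beta.mean(axis=1)
    per_set: dict[str, pd.Series] = {}
    rows = []
    for label, probes in probe_sets.items():
        probes = set(probes)
        known = probes & set(dataset.probe_ids)
        if len(known) < len(probes):
            import warnings

            warnings.warn(
                f"{len(probes) - len(known)} unknown probes dropped from "
                f"set {label!r}",
                stacklevel=2,
            )
        m = means_all.loc[sorted(known)]
        per_set[label] = m
        deciles = (
            m.quantile(np.arange(0.1, 1.0, 0.1)).to_numpy()
            if len(m)
            else np.full(9, np.nan)
        )
        rows.append(
            {
                "set": label,
                "n": len(m),
                "mean": m.mean() if len(m) else float("nan"),
                "frac_low": float((m < 0.1).mean()) if len(m) else float("nan"),
                "frac_high": float((m > 0.9).mean()) if len(m) else float("nan"),
                "frac_extreme": float(((m < 0.1) | (m > 0.9)).mean())
                if len(m)
                else float("nan"),
                **{f"d{int(q*100)}": v for q, v in zip(np.arange(0.1, 1.0, 0.1), deciles)},
            }
        )
    return per_set, pd.DataFrame(rows).set_index("set")
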