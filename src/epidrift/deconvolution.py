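"""Reference-based cell-type deconvolution.

``build_reference`` derives cell-type marker CpGs from sorted (purified)
profiles: a moderated two-group t-test (empirical-Bayes variance shrinkage
with a method-of-moments prior) plus a minimum group-mean methylation
difference, the recipe used to build e.g. neuron/non-neuron brain
references (Bonferroni 0.05 and delta-beta >= 0.70 by default).

``estimate_cell_fractions`` projects bulk samples onto the reference by
non-negative least squares renormalised to sum one — a simple constrained
projection whose estimated fractions are intended as covariates in age
models, not a re-implementation of robust-partial-correlation deconvolvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import MethylationDataset

__all__ = ["ReferenceMatrix", "FractionEstimate", "build_reference",
           "estimate_cell_fractions", "moderated_ttest"]


@dataclass
class ReferenceMatrix:
    """Marker-CpG mean betas per cell type, with per-marker provenance."""

    profiles: pd.DataFrame  # markers x cell types, mean beta
    provenance: pd.DataFrame  # per marker: t, p, bonf_p, delta_beta

    @property
    def marker_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    def to_csv(self, path) -> None:
        self.profiles.to_csv(path, index_label="probe_id")

    @classmethod
    def from_profiles(cls, profiles: pd.DataFrame) -> "ReferenceMatrix":
        """Wrap externally supplied pure profiles (no filter provenance)."""
        prov = pd.DataFrame(index=profiles.index)
        return cls(profiles=profiles, provenance=prov)


@dataclass
class FractionEstimate:
    """Per-sample cell-type weights (non-negative, sum to one)."""

    fractions: pd.DataFrame  # samples x cell types
    residual_norm: pd.Series  # per-sample fit residual

    def to_csv(self, path) -> None:
        out = self.fractions.copy()
        out["residual_norm"] = self.residual_norm
        out.to_csv(path, index_label="sample_id")


def moderated_ttest(x: np.ndarray, y: np.ndarray, moderated: bool = True):
    """Two-group t-test per row with empirical-Bayes variance shrinkage.

    Pooled per-row variances ``s2`` (df d = n1+n2-2) are shrunk toward a
    prior ``s0^2`` with prior df ``d0`` estimated by method of moments: under
    the scaled-F marginal, CV^2(s2) = 2 (d + d0 - 2) / (d (d0 - 4)), which is
    solved for d0. The moderated statistic uses the posterior variance
    (d0 s0^2 + d s2)/(d0 + d) with d + d0 degrees of freedom. With
    ``moderated=False`` a plain Welch t-test is computed instead.

    Returns (t, p, df) arrays.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    if not moderated:
        t, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
        df = np.full(x.shape[0], n1 + n2 - 2, dtype=float)
        return t, p, df

    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d

    mean_s2 = s2.mean()
    if mean_s2 <= 0:
        cv2 = 0.0
    else:
        cv2 = s2.var(ddof=1) / mean_s2**2
    denom = cv2 * d - 2.0
    if denom > 0:
        d0 = (4.0 * cv2 * d + 2.0 * d - 4.0) / denom
        d0 = max(d0, 1.0)
        s02 = mean_s2 * (d0 - 2.0) / d0 if d0 > 2 else mean_s2
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d + d0
    else:  # variances essentially constant across rows: full shrinkage
        s2_post = np.full_like(s2, mean_s2)
        df_total = float(d + x.shape[0])

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    df = np.full(x.shape[0], df_total, dtype=float)
    return t, p, df


def build_reference(
    sorted_data: MethylationDataset,
    group_labels: pd.Series | dict,
    alpha_bonf: float = 0.05,
    delta_beta_min: float = 0.70,
    moderated: bool = True,
) -> ReferenceMatrix:
    """Derive a marker reference from sorted profiles.

    Probes become markers when the Bonferroni-adjusted moderated-t p-value
    is below ``alpha_bonf`` AND the absolute group-mean difference is at
    least ``delta_beta_min`` (inclusive). With two groups a single contrast
    is tested; with more, each cell type is contrasted against the rest.
    Reference entries are group means at the markers.
    """
    labels = pd.Series(group_labels)
    labels = labels.loc[dataset_samples(sorted_data)]
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups of sorted samples")
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with < 2 samples: {small}")

    X = sorted_data.beta.to_numpy(dtype=float)
    n_probes = X.shape[0]
    contrasts = (
        [(groups[0], groups[1])]
        if len(groups) == 2
        else [(g, None) for g in groups]
    )

    marker_mask = np.zeros(n_probes, dtype=bool)
    prov_rows = {}
    for g, other in contrasts:
        in_g = (labels == g).to_numpy()
        in_other = (labels == other).to_numpy() if other is not None else ~in_g
        t, p, _ = moderated_ttest(X[:, in_g], X[:, in_other], moderated=moderated)
        bonf = np.minimum(1.0, p * n_probes)
        delta = X[:, in_g].mean(axis=1) - X[:, in_other].mean(axis=1)
        sel = (bonf < alpha_bonf) & (np.abs(delta) >= delta_beta_min)
        marker_mask |= sel
        prov_rows[g] = pd.DataFrame(
            {"t": t, "p": p, "bonf_p": bonf, "delta_beta": delta},
            index=sorted_data.probe_ids,
        )

    if not marker_mask.any():
        raise ValueError(
            "no probe passed the marker filters; relax alpha_bonf or "
            "delta_beta_min"
        )
    markers = sorted_data.probe_ids[marker_mask]
    profiles = pd.DataFrame(
        {g: X[np.asarray(marker_mask)][:, (labels == g).to_numpy()].mean(axis=1)
         for g in groups},
        index=markers,
    )
    first = contrasts[0][0]
    provenance = prov_rows[first].loc[markers]
    return ReferenceMatrix(profiles=profiles, provenance=provenance)


def dataset_samples(dataset: MethylationDataset) -> list[str]:
    return list(dataset.sample_ids)


def estimate_cell_fractions(
    dataset: MethylationDataset, reference: ReferenceMatrix
) -> FractionEstimate:
    """Estimate per-sample cell fractions by constrained projection.

    Solves non-negative least squares of observed marker betas on the
    reference profiles per sample, then renormalises weights to sum one.
    Markers absent from the dataset are dropped with a warning provided at
    least 80% remain.
    """
    ref = reference.profiles
    present = ref.index.intersection(dataset.probe_ids)
    if len(present) < len(ref.index):
        frac = len(present) / len(ref.index)
        if frac < 0.8:
            raise ValueError(
                f"only {frac:.0%} of reference markers present in the dataset"
            )
        import warnings

        warnings.warn(
            f"{len(ref.index) - len(present)} reference markers absent; "
            f"using {len(present)}",
            stacklevel=2,
        )
        ref = ref.loc[present]
    if len(ref) < len(ref.columns):
        raise ValueError("fewer markers than cell types")

    A = ref.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        corr = np.corrcoef(A.T)
        pairs = [
            (ref.columns[i], ref.columns[j])
            for i in range(A.shape[1])
            for j in range(i + 1, A.shape[1])
            if abs(corr[i, j]) > 1 - 1e-8
        ]
        raise ValueError(f"rank-deficient reference; collinear cell types: {pairs}")

    B = dataset.beta.loc[ref.index].to_numpy(dtype=float)
    n_samples = B.shape[1]
    W = np.zeros((n_samples, A.shape[1]))
    resid = np.zeros(n_samples)
    for s in range(n_samples):
        w, rnorm = optimize.nnls(A, B[:, s])
        total = w.sum()
        if total <= 0:
            raise ValueError(f"all-zero projection for sample {dataset.sample_ids[s]}")
        W[s] = w / total
        resid[s] = rnorm
    fractions = pd.DataFrame(W, index=dataset.sample_ids, columns=ref.columns)
    return FractionEstimate(
        fractions=fractions,
        residual_norm=pd.Series(resid, index=dataset.sample_ids, name="residual_norm"),
    )
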