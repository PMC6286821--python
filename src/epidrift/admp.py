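"""Age-DMP identification: per-probe linear models, multiple-testing
adjustment, selection criteria and Storey pi0 estimation.

For every probe the DNAm beta value is regressed on age plus optional
covariates by ordinary least squares; the age coefficient's t-statistic and
two-sided p-value follow a Student-t null with the residual degrees of
freedom. Probes can then be called aDMPs under a false-discovery-rate
threshold (Storey q-values), a family-wise Bonferroni threshold, an
effect-size threshold on the slope (beta units per year), or conjunctions of
those. The Storey pi0 estimate of the null fraction gives the genome-wide
drifting fraction 1 - pi0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MethylationDataset

__all__ = [
    "AdmpTable",
    "SelectionCriterion",
    "CriterionKind",
    "Pi0Estimate",
    "fit_admp",
    "adjust_pvalues",
    "select_admps",
    "estimate_pi0",
    "storey_pi0",
    "storey_qvalues",
]

DEFAULT_LAMBDAS = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))

_DEGENERATE_TOL = 1e-12


class CriterionKind(enum.Enum):
    FDR = "fdr"
    BONFERRONI = "bonferroni"
    EFFECT_SIZE = "effect_size"
    AND = "and"


@dataclass(frozen=True)
class SelectionCriterion:
    """Declarative aDMP-calling rule.

    ``FDR``/``BONFERRONI`` select probes with adjusted significance strictly
    below ``alpha``; ``EFFECT_SIZE`` selects |slope| strictly above ``tau``
    (beta units per year; the conventional threshold 0.002/yr is a 2% DNAm
    change per decade); ``AND`` intersects sub-criteria.
    """

    kind: CriterionKind
    alpha: float = 0.05
    tau: float = 0.002
    parts: tuple["SelectionCriterion", ...] = ()

    def __post_init__(self):
        if self.kind in (CriterionKind.FDR, CriterionKind.BONFERRONI):
            if not 0.0 < self.alpha <= 1.0:
                raise ValueError("alpha must lie in (0,1]")
        if self.kind is CriterionKind.EFFECT_SIZE and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kind is CriterionKind.AND and not self.parts:
            raise ValueError("AND criterion needs sub-criteria")

    @classmethod
    def fdr(cls, alpha: float = 0.05) -> "SelectionCriterion":
        return cls(CriterionKind.FDR, alpha=alpha)

    @classmethod
    def bonferroni(cls, alpha: float = 0.05) -> "SelectionCriterion":
        return cls(CriterionKind.BONFERRONI, alpha=alpha)

    @classmethod
    def effect_size(cls, tau: float = 0.002) -> "SelectionCriterion":
        return cls(CriterionKind.EFFECT_SIZE, tau=tau)

    @classmethod
    def all_of(cls, *parts: "SelectionCriterion") -> "SelectionCriterion":
        return cls(CriterionKind.AND, parts=tuple(parts))

    @property
    def label(self) -> str:
        if self.kind is CriterionKind.FDR:
            return f"fdr<{self.alpha:g}"
        if self.kind is CriterionKind.BONFERRONI:
            return f"bonf<{self.alpha:g}"
        if self.kind is CriterionKind.EFFECT_SIZE:
            return f"|slope|>{self.tau:g}"
        return " & ".join(p.label for p in self.parts)

    @classmethod
    def parse(cls, text: str) -> "SelectionCriterion":
        """Parse a CLI-style spec like ``fdr:0.05``, ``effect_size:0.002`` or
        ``bonferroni:0.05+effect_size:0.002``."""
        parts = []
        for token in text.split("+"):
            name, _, val = token.partition(":")
            name = name.strip().lower()
            if name == "fdr":
                parts.append(cls.fdr(float(val) if val else 0.05))
            elif name in ("bonferroni", "bonf"):
                parts.append(cls.bonferroni(float(val) if val else 0.05))
            elif name in ("effect_size", "effect-size", "es"):
                parts.append(cls.effect_size(float(val) if val else 0.002))
            else:
                raise ValueError(f"unknown criterion {token!r}")
        return parts[0] if len(parts) == 1 else cls.all_of(*parts)


@dataclass
class AdmpTable:
    """Per-probe age-regression results.

    ``table`` columns: slope (beta/yr), se, t, p, degenerate, and after
    :func:`adjust_pvalues` also bonf_p and q. ``n_probes`` is the multiple-
    testing denominator (degenerate probes included).
    """

    table: pd.DataFrame
    covariates: tuple[str, ...]
    n_samples: int
    pi0: Optional[float] = None

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def from_tsv(cls, path, covariates=(), n_samples=0) -> "AdmpTable":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(df, tuple(covariates), int(n_samples))


@dataclass(frozen=True)
class Pi0Estimate:
    """Storey estimate of the null-probe fraction."""

    pi0: float
    n_probes: int
    lambdas: tuple[float, ...]

    @property
    def null_count(self) -> int:
        return int(round(self.pi0 * self.n_probes))

    @property
    def admp_fraction(self) -> float:
        return 1.0 - self.pi0


# ----------------------------------------------------------------------
# model fitting
# ----------------------------------------------------------------------

def _design_matrix(
    dataset: MethylationDataset, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    ann = dataset.annotations
    if "age" not in ann.columns:
        raise ValueError("annotations lack an 'age' column")
    age = pd.to_numeric(ann["age"]).to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; the age slope is unidentifiable")
    cols = [np.ones_like(age), age]
    names = ["intercept", "age"]
    for cov in covariates:
        if cov not in ann.columns:
            raise ValueError(f"covariate {cov!r} missing from annotations")
        col = ann[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(str(name))
        else:
            cols.append(pd.to_numeric(col).to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        kept = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(names[j])
            else:
                kept = cand
        raise ValueError(f"collinear covariate columns: {bad}")
    return X, names


def fit_admp(
    dataset: MethylationDataset, covariates: Sequence[str] = ()
) -> AdmpTable:
    """Per-probe OLS of beta on age plus covariates.

    Categorical covariates are expanded to indicator contrasts dropping one
    level. Returns slope (beta units/yr), standard error, t and two-sided p
    for the age coefficient. Probes with (numerically) zero residual
    variance keep their fitted slope but get p = 1 and a degenerate flag.
    """
    X, names = _design_matrix(dataset, covariates)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few samples ({n}) for {p} model parameters")
    Y = dataset.beta.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(Y).any():
        raise ValueError("beta matrix contains missing values; impute first")

    XtX_inv = np.linalg.inv(X.T @ X)
    coefs = XtX_inv @ (X.T @ Y)  # p x probes
    resid = Y - X @ coefs
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    age_idx = names.index("age")
    var_scale = XtX_inv[age_idx, age_idx]
    se = np.sqrt(np.maximum(sigma2 * var_scale, 0.0))
    slope = coefs[age_idx]

    degenerate = sigma2 <= _DEGENERATE_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, 0.0, t)
    pvals = np.where(degenerate, 1.0, pvals)

    table = pd.DataFrame(
        {
            "slope": slope,
            "se": se,
            "t": t,
            "p": pvals,
            "degenerate": degenerate,
        },
        index=dataset.probe_ids,
    )
    return AdmpTable(table=table, covariates=tuple(covariates), n_samples=n)


# ----------------------------------------------------------------------
# multiple-testing adjustment
# ----------------------------------------------------------------------

def storey_pi0(pvalues: np.ndarray, lambdas: Sequence[float] = DEFAULT_LAMBDAS) -> float:
    """Storey estimate of the null fraction pi0.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is extrapolated to
    lambda -> 1 with a cubic least-squares smoother over the grid, then
    clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    n = p.size
    lam = np.asarray(lambdas, dtype=float)
    pi0_lam = np.array([(p > l).sum() / (n * (1.0 - l)) for l in lam])
    if len(lam) >= 4:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam.max()))
    else:
        pi0 = float(pi0_lam[-1])
    return float(np.clip(pi0, 0.0, 1.0))


def storey_qvalues(
    pvalues: np.ndarray,
    lambdas: Sequence[float] = DEFAULT_LAMBDAS,
    pi0: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """q-values via the Storey procedure: q_(i) = min_{j>=i} pi0 n p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    n = p.size
    if pi0 is None:
        pi0 = storey_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q, float(pi0)


def adjust_pvalues(
    table: AdmpTable, lambdas: Sequence[float] = DEFAULT_LAMBDAS
) -> AdmpTable:
    """Fill bonf_p (min(1, p*n)) and Storey q-value columns.

    Degenerate probes (p = 1) stay in the denominator n, matching per-dataset
    probe counts used for Bonferroni thresholds.
    """
    p = table.table["p"].to_numpy(dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values; refit before adjusting")
    n = p.size
    bonf = np.minimum(1.0, p * n)
    q, pi0 = storey_qvalues(p, lambdas)
    new = table.table.copy()
    new["bonf_p"] = bonf
    new["q"] = q
    return replace(table, table=new, pi0=pi0)


def estimate_pi0(
    table: AdmpTable | np.ndarray, lambdas: Sequence[float] = DEFAULT_LAMBDAS
) -> Pi0Estimate:
    """Estimate the fraction of probes not associated with age.

    ``1 - pi0`` is the genome-wide drifting (aDMP) fraction. A warning is
    emitted below 1000 probes, where the smoother is unstable.
    """
    if isinstance(table, AdmpTable):
        p = table.table["p"].to_numpy(dtype=float)
    else:
        p = np.asarray(table, dtype=float)
    if p.size < 1000:
        import warnings

        warnings.warn(
            f"pi0 estimated from only {p.size} p-values; expect instability",
            stacklevel=2,
        )
    pi0 = storey_pi0(p, lambdas)
    return Pi0Estimate(pi0=pi0, n_probes=p.size, lambdas=tuple(lambdas))


# ----------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------

def select_admps(table: AdmpTable, criterion: SelectionCriterion) -> set[str]:
    """Probe IDs passing ``criterion``. Degenerate probes are never selected.

    Thresholds are strict: FDR/Bonferroni use ``< alpha``, effect size uses
    ``|slope| > tau``.
    """
    df = table.table
    ok = ~df["degenerate"].to_numpy(dtype=bool)

    def mask(crit: SelectionCriterion) -> np.ndarray:
        if crit.kind is CriterionKind.FDR:
            if "q" not in df.columns:
                raise ValueError("q-values missing; run adjust_pvalues first")
            return df["q"].to_numpy() < crit.alpha
        if crit.kind is CriterionKind.BONFERRONI:
            if "bonf_p" not in df.columns:
                raise ValueError("bonf_p missing; run adjust_pvalues first")
            return df["bonf_p"].to_numpy() < crit.alpha
        if crit.kind is CriterionKind.EFFECT_SIZE:
            return np.abs(df["slope"].to_numpy()) > crit.tau
        sel = np.ones(len(df), dtype=bool)
        for part in crit.parts:
            sel &= mask(part)
        return sel

    selected = mask(criterion) & ok
    return set(df.index[selected])
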