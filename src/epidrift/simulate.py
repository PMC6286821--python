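"""Synthetic EWAS generator with known ground truth.

Emulates Illumina 450k/EPIC-scale beta-value data for ageing studies: bimodal
baseline methylomes over multiple cell types, a configurable fraction of
age-affected CpGs (aDMPs) with configurable cross-cell-type sharing, small
per-decade effect sizes, cell-type mixtures drawn from a Dirichlet, batch and
sex covariates, matched multi-tissue designs, and heteroscedastic bounded
noise.

The generative model
--------------------
For cell type ``c``, probe ``j`` and individual ``i`` with age ``a_i``::

    logit(m_cij) = logit(mu_cj) + b_cj * (a_i - mid) + batch_ij + sex_j * s_i
    x_ij         = sum_c w_ic * m_cij            (mixture)
    observed     ~ Beta(mean = x_ij, precision = noise_precision)

where ``mid`` is the midpoint of the age range, ``b_cj`` is zero unless probe
``j`` is age-affected in cell type ``c`` (slope magnitudes uniform on
``slope_range``, signs balanced), and the Beta noise has variance
``x(1-x)/(1+precision)`` so dispersion shrinks near the bounds — the
heteroscedasticity that drives effect-size selection bias on the beta scale.

Age effects live on the logit scale and are mapped back, so beta-scale effect
sizes are compressed near 0 and 1; with the default logit slopes of
0.005–0.02 per year the beta-scale effect at intermediate methylation is
roughly 1–5% DNAm per decade, the magnitude typical of epigenetic drift.

Every random draw comes from a named substream of one global seed, so output
is byte-reproducible and independent of iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataset import FRACTION_PREFIX, MethylationDataset

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_matched_tissues",
    "truth_sensitivity",
]

# Named substreams hanging off the global seed.  Labels are hashed (crc32)
# into the SeedSequence entropy so streams never collide across components.
_STREAMS = (
    "baseline",
    "markers",
    "admp",
    "slopes",
    "individuals",
    "fractions",
    "batch",
    "sex_effect",
    "noise",
    "missing",
    "detection",
)

_LOGIT_CLIP = 1e-4


def _rng(seed: int, stream: str, *keys) -> np.random.Generator:
    entropy = [int(seed), zlib.crc32(stream.encode())]
    entropy += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(entropy)


class SimulationError(ValueError):
    """Raised for degenerate or inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic EWAS.

    Defaults describe a desk-scale ageing EWAS: 20,000 probes, 300
    individuals aged 22–84 (the span of the purified blood cohorts this
    generator emulates), 30% of probes age-affected in at least one cell
    type, 70% of those shared across all cell types, logit-scale slopes of
    0.005–0.02 per year (≈1–5% DNAm per decade at intermediate methylation),
    and Beta noise with precision 150.
    """

    n_probes: int = 20_000
    n_individuals: int = 300
    cell_types: tuple[str, ...] = ("monocyte", "tcell")
    age_range: tuple[float, float] = (22.0, 84.0)
    admp_fraction: float = 0.30
    share_probability: float = 0.70
    slope_range: tuple[float, float] = (0.005, 0.02)  # logit units per year
    noise_precision: float = 150.0  # Beta precision; np.inf switches noise off
    dirichlet_alpha: float | tuple[float, ...] = 5.0
    batch_count: int = 2
    batch_sd: float = 0.10  # logit-scale SD of per-(probe,batch) offsets
    sex_effect_sd: float = 0.05  # logit-scale SD of per-probe sex offsets
    marker_fraction: float = 0.05  # probes with large cross-cell-type delta-beta
    baseline_divergence_sd: float = 0.30  # logit-scale cell-type baseline spread
    mixture_age_trend: float | tuple[float, ...] = 0.0
    matched: bool = False
    missing_rate: float = 0.0
    detection_fail_rate: float = 0.0
    ages: Optional[tuple[float, ...]] = None  # explicit ages override
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_probes <= 0:
            raise SimulationError("n_probes must be positive")
        if self.n_individuals <= 1:
            raise SimulationError("need at least two individuals")
        if not self.cell_types:
            raise SimulationError("at least one cell type required")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise SimulationError("cell type labels must be unique")
        lo, hi = self.age_range
        if not lo < hi:
            raise SimulationError(
                f"degenerate age_range {self.age_range}: a single age value "
                "leaves the age slope unidentifiable"
            )
        if not 0.0 <= self.admp_fraction <= 1.0:
            raise SimulationError("admp_fraction must lie in [0,1]")
        if not 0.0 <= self.share_probability <= 1.0:
            raise SimulationError("share_probability must lie in [0,1]")
        smin, smax = self.slope_range
        if not (0.0 < smin < smax):
            raise SimulationError("slope_range must satisfy 0 < min < max")
        if self.noise_precision <= 0:
            raise SimulationError("noise_precision must be positive")
        if self.batch_count < 1:
            raise SimulationError("batch_count must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must lie in [0,1)")
        if self.ages is not None:
            if len(self.ages) != self.n_individuals:
                raise SimulationError("explicit ages must match n_individuals")
            if len(set(self.ages)) < 2:
                raise SimulationError("explicit ages are constant")

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    @property
    def age_midpoint(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def alpha_vector(self) -> np.ndarray:
        a = self.dirichlet_alpha
        if np.isscalar(a):
            return np.full(self.n_cell_types, float(a))
        vec = np.asarray(a, dtype=float)
        if vec.shape != (self.n_cell_types,):
            raise SimulationError("dirichlet_alpha length must match cell_types")
        return vec

    def trend_vector(self) -> np.ndarray:
        t = self.mixture_age_trend
        if np.isscalar(t):
            vec = np.zeros(self.n_cell_types)
            vec[0] = float(t)
            return vec
        vec = np.asarray(t, dtype=float)
        if vec.shape != (self.n_cell_types,):
            raise SimulationError("mixture_age_trend length must match cell_types")
        return vec


@dataclass
class SyntheticTruth:
    """Ground truth underlying a simulated dataset.

    Attributes
    ----------
    is_admp
        probes x cell-types boolean frame: probe age-affected in that cell type.
    slope
        probes x cell-types logit-scale slopes per year (0 where unaffected).
    baseline
        probes x cell-types baseline mean betas ``mu_cj``.
    shared_set / specific_set
        Probes age-affected in all cell types vs in exactly one.
    cell_fractions
        samples x cell-types true mixture weights of the returned dataset.
    """

    is_admp: pd.DataFrame
    slope: pd.DataFrame
    baseline: pd.DataFrame
    shared_set: frozenset
    specific_set: frozenset
    cell_fractions: pd.DataFrame
    config: SimulationConfig

    def admp_set(self, cell_type: str) -> set[str]:
        """Probes truly age-affected in ``cell_type``."""
        if cell_type not in self.is_admp.columns:
            raise KeyError(f"unknown cell type {cell_type!r}")
        col = self.is_admp[cell_type]
        return set(col.index[col])

    def any_admp_set(self) -> set[str]:
        return set(self.is_admp.index[self.is_admp.any(axis=1)])

    def beta_scale_slope(self, cell_type: str) -> pd.Series:
        """Expected pure-cell slope on the observed beta scale.

        The logit link compresses effects near the bounds: at the age-range
        midpoint d(beta)/d(age) = b * mu * (1 - mu).
        """
        if cell_type not in self.slope.columns:
            raise KeyError(f"unknown cell type {cell_type!r}")
        mu = self.baseline[cell_type]
        return self.slope[cell_type] * mu * (1.0 - mu)


def truth_sensitivity(detected, truth: SyntheticTruth, cell_type: str) -> float:
    """Fraction of the true aDMPs of ``cell_type`` recovered by ``detected``.

    Returns NaN when the truth set is empty (sensitivity undefined).
    """
    true_set = truth.admp_set(cell_type)
    universe = set(truth.is_admp.index)
    detected = set(detected)
    if not detected <= universe:
        raise ValueError("detected probes outside the simulated probe universe")
    if not true_set:
        return float("nan")
    return len(detected & true_set) / len(true_set)


# ----------------------------------------------------------------------
# probe-level truth (shared across tissues/cohorts of one config)
# ----------------------------------------------------------------------

def _probe_truth(config: SimulationConfig):
    n, C = config.n_probes, config.n_cell_types
    probes = pd.Index([f"cg{j:07d}" for j in range(n)], name="probe_id")

    # baseline three-component mixture, shared across cell types ...
    rb = _rng(config.seed, "baseline")
    comp = rb.choice(3, size=n, p=(0.4, 0.2, 0.4))
    mu = np.empty(n)
    mu[comp == 0] = rb.beta(2.0, 40.0, size=(comp == 0).sum())  # unmethylated
    mu[comp == 1] = rb.beta(10.0, 10.0, size=(comp == 1).sum())  # intermediate
    mu[comp == 2] = rb.beta(40.0, 2.0, size=(comp == 2).sum())  # methylated
    mu = np.clip(mu, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    # genome-wide mild divergence of cell-type baselines (logit scale); the
    # mixture then transmits composition fluctuations into every probe, the
    # reason bulk EWAS must adjust for cell fractions
    if C >= 2 and config.baseline_divergence_sd > 0:
        div = rb.normal(0.0, config.baseline_divergence_sd, size=(n, C))
        mu_ct = expit(logit(mu)[:, None] + div)
        mu_ct = np.clip(mu_ct, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    else:
        mu_ct = np.tile(mu[:, None], (1, C))

    # ... except cell-type marker probes with large delta-beta between types
    if C >= 2 and config.marker_fraction > 0:
        rm = _rng(config.seed, "markers")
        n_markers = int(round(config.marker_fraction * n))
        marker_idx = rm.choice(n, size=n_markers, replace=False)
        lows = rm.uniform(0.03, 0.08, size=n_markers)
        highs = rm.uniform(0.88, 0.96, size=n_markers)
        high_mask = rm.integers(0, 2, size=(n_markers, C)).astype(bool)
        # guarantee at least one low and one high cell type per marker
        all_high = high_mask.all(axis=1)
        all_low = ~high_mask.any(axis=1)
        high_mask[all_high, 0] = False
        high_mask[all_low, 0] = True
        mu_ct[marker_idx, :] = np.where(
            high_mask, highs[:, None], lows[:, None]
        )

    # age-affected probes and their slopes
    ra = _rng(config.seed, "admp")
    rs = _rng(config.seed, "slopes")
    n_admp = int(round(config.admp_fraction * n))
    admp_idx = np.sort(ra.choice(n, size=n_admp, replace=False))
    shared_mask = ra.random(n_admp) < config.share_probability
    specific_ct = ra.integers(0, C, size=n_admp)

    mag = rs.uniform(*config.slope_range, size=n_admp)
    sign = np.where(rs.random(n_admp) < 0.5, -1.0, 1.0)
    b_admp = mag * sign

    slope = np.zeros((n, C))
    is_admp = np.zeros((n, C), dtype=bool)
    shared_rows = admp_idx[shared_mask]
    slope[shared_rows, :] = b_admp[shared_mask][:, None]
    is_admp[shared_rows, :] = True
    spec_rows = admp_idx[~shared_mask]
    spec_cols = specific_ct[~shared_mask]
    slope[spec_rows, spec_cols] = b_admp[~shared_mask]
    is_admp[spec_rows, spec_cols] = True

    shared_set = frozenset(probes[shared_rows])
    specific_set = frozenset(probes[spec_rows])

    # probe-level nuisance effects (logit scale)
    sex_eff = _rng(config.seed, "sex_effect").normal(0.0, config.sex_effect_sd, size=n)

    cols = list(config.cell_types)
    return (
        probes,
        pd.DataFrame(mu_ct, index=probes, columns=cols),
        pd.DataFrame(slope, index=probes, columns=cols),
        pd.DataFrame(is_admp, index=probes, columns=cols),
        shared_set,
        specific_set,
        sex_eff,
    )


def _individuals(config: SimulationConfig, cohort: int):
    ri = _rng(config.seed, "individuals", cohort)
    n = config.n_individuals
    sample_ids = pd.Index([f"C{cohort}S{i:05d}" for i in range(n)], name="sample_id")
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
    else:
        ages = ri.uniform(*config.age_range, size=n)
    sex = np.where(ri.random(n) < 0.5, "F", "M")
    batch = ri.integers(0, config.batch_count, size=n)
    return sample_ids, ages, sex, batch


def _mixture_weights(config: SimulationConfig, tissue: str, cohort: int,
                     cell_type: Optional[str], ages: np.ndarray) -> np.ndarray:
    n, C = config.n_individuals, config.n_cell_types
    if cell_type is not None:
        if cell_type not in config.cell_types:
            raise SimulationError(f"unknown cell type {cell_type!r}")
        w = np.zeros((n, C))
        w[:, config.cell_types.index(cell_type)] = 1.0
        return w
    rf = _rng(config.seed, "fractions", tissue, cohort)
    alpha = config.alpha_vector()
    trend = config.trend_vector()
    z = (ages - config.age_midpoint) / (0.5 * (config.age_range[1] - config.age_range[0]))
    alpha_i = alpha[None, :] * np.exp(trend[None, :] * z[:, None])
    g = rf.gamma(shape=alpha_i)  # normalised gammas == Dirichlet
    return g / g.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# public generators
# ----------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
    cell_type: Optional[str] = None,
    tissue: str = "mixed",
    cohort: int = 0,
) -> tuple[MethylationDataset, SyntheticTruth]:
    """Simulate one beta-valued dataset with known ground truth.

    Parameters
    ----------
    config
        Simulation parameters; validated before any draw.
    cell_type
        If given, the dataset is a purified profile of that cell type
        (one-hot mixture weights); otherwise samples are Dirichlet mixtures
        of all configured cell types.
    tissue
        Label stored in the annotations and used to key the mixture and
        noise substreams, so different tissues get independent draws.
    cohort
        Keys the individuals substream: datasets with the same cohort share
        individuals (matched design), different cohorts do not.

    Returns
    -------
    (dataset, truth)
        The observed mixed dataset and the full generative ground truth.
    """
    config.validate()
    (probes, baseline, slope, is_admp, shared_set, specific_set,
     sex_eff) = _probe_truth(config)
    sample_ids, ages, sex, batch = _individuals(config, cohort)
    w = _mixture_weights(config, tissue, cohort, cell_type, ages)

    batch_eff = _rng(config.seed, "batch", cohort).normal(
        0.0, config.batch_sd, size=(config.n_probes, config.batch_count)
    )
    sex01 = (sex == "M").astype(float)
    centred_age = ages - config.age_midpoint

    base_logit = logit(baseline.to_numpy())
    x = np.zeros((config.n_probes, config.n_individuals))
    for c in range(config.n_cell_types):
        lin = (
            base_logit[:, c][:, None]
            + slope.to_numpy()[:, c][:, None] * centred_age[None, :]
            + batch_eff[:, batch]
            + sex_eff[:, None] * sex01[None, :]
        )
        x += w[:, c][None, :] * expit(lin)

    if np.isfinite(config.noise_precision):
        rn = _rng(config.seed, "noise", tissue, cohort, cell_type or "")
        xc = np.clip(x, 1e-6, 1 - 1e-6)
        a = xc * config.noise_precision
        b = (1.0 - xc) * config.noise_precision
        x = rn.beta(a, b)
    x = np.clip(x, 0.0, 1.0)

    beta = pd.DataFrame(x, index=probes, columns=sample_ids)

    if config.missing_rate > 0:
        rmiss = _rng(config.seed, "missing", tissue, cohort, cell_type or "")
        mask = rmiss.random(beta.shape) < config.missing_rate
        beta = beta.mask(mask)

    detection_p = None
    if config.detection_fail_rate > 0:
        rdet = _rng(config.seed, "detection", tissue, cohort, cell_type or "")
        fails = rdet.random(beta.shape) < config.detection_fail_rate
        dp = np.zeros(beta.shape)
        dp[fails] = rdet.uniform(0.05, 1.0, size=int(fails.sum()))
        detection_p = pd.DataFrame(dp, index=probes, columns=sample_ids)

    ann = pd.DataFrame(
        {
            "age": ages,
            "sex": sex,
            "batch": np.char.add("b", batch.astype(str)),
            "tissue": tissue if cell_type is None else cell_type,
        },
        index=sample_ids,
    )
    fractions = pd.DataFrame(w, index=sample_ids, columns=list(config.cell_types))
    for ct in config.cell_types:
        ann[FRACTION_PREFIX + ct] = fractions[ct]

    dataset = MethylationDataset(
        beta=beta,
        annotations=ann,
        detection_p=detection_p,
        name=f"{tissue if cell_type is None else cell_type}-cohort{cohort}",
    )
    truth = SyntheticTruth(
        is_admp=is_admp,
        slope=slope,
        baseline=baseline,
        shared_set=shared_set,
        specific_set=specific_set,
        cell_fractions=fractions,
        config=config,
    )
    return dataset, truth


def simulate_matched_tissues(
    config: SimulationConfig, tissues: Sequence[str]
) -> tuple[list[MethylationDataset], list[SyntheticTruth]]:
    """Simulate one mixed dataset per tissue over the same cell types.

    With ``config.matched`` the tissues share individuals (identical sample
    IDs, ages, sex and batch — a matched multi-tissue design); otherwise each
    tissue gets an independent cohort. Probe-level truth (aDMP membership,
    slopes, baselines) is always common to all tissues.
    """
    datasets, truths = [], []
    for k, tissue in enumerate(tissues):
        cohort = 0 if config.matched else k
        ds, tr = simulate_dataset(config, tissue=tissue, cohort=cohort)
        datasets.append(ds)
        truths.append(tr)
    return datasets, truths
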