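"""End-to-end orchestration: simulate -> QC -> deconvolve -> call aDMPs ->
{overlap, concordance, validation fractions, power, panel}.

A run is driven by a YAML config with one flat namespace per stage; the
config is validated in full before any stage executes, persisted verbatim
next to the outputs, and every random draw descends from the single
top-level seed, so re-running an identical config reproduces identical
analysis outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import io_qc
from .admp import AdmpTable, SelectionCriterion, adjust_pvalues, estimate_pi0, fit_admp, select_admps
from .dataset import FRACTION_PREFIX, MethylationDataset
from .deconvolution import build_reference, estimate_cell_fractions
from .overlap import (
    cross_validation_fractions,
    hypergeometric_overlap,
    mean_dnam_profile,
    nested_overlap,
    tstat_concordance,
)
from .panel import panel_sharing
from .power import define_gold_standard, subsample_sensitivity
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

STAGES = (
    "simulate",
    "qc",
    "deconvolve",
    "admp",
    "overlap",
    "concordance",
    "validate_fractions",
    "power",
    "panel",
)


class ConfigError(ValueError):
    """Raised by pre-flight validation, naming the stage and parameter."""


@dataclass
class RunConfig:
    raw: dict
    seed: int

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        return cls(raw=raw, seed=int(raw.get("seed", 0)))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(raw=dict(raw), seed=int(raw.get("seed", 0)))

    def stage(self, name: str) -> Optional[dict]:
        return self.raw.get(name)

    # ------------------------------------------------------------------
    def validate(self) -> SimulationConfig:
        """Pre-flight validation of every stage; returns the sim config."""
        unknown = set(self.raw) - set(STAGES) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        sim_raw = self.raw.get("simulate")
        if sim_raw is None:
            raise ConfigError("stage 'simulate': section is required")
        sim_raw = dict(sim_raw)
        mixed_tissue = sim_raw.pop("mixed_tissue", "mixed")
        known_fields = set(SimulationConfig.__dataclass_fields__)
        bad = set(sim_raw) - known_fields
        if bad:
            raise ConfigError(f"stage 'simulate': unknown parameters {sorted(bad)}")
        for key in ("cell_types", "age_range", "slope_range", "ages"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        if isinstance(sim_raw.get("dirichlet_alpha"), list):
            sim_raw["dirichlet_alpha"] = tuple(sim_raw["dirichlet_alpha"])
        sim = SimulationConfig(seed=self.seed, **sim_raw)
        try:
            sim.validate()
        except ValueError as exc:
            raise ConfigError(f"stage 'simulate': {exc}") from exc

        for name, crit_keys in (
            ("overlap", ("criterion",)),
            ("concordance", ("discovery_criterion",)),
            ("power", ("criterion", "gold_criterion")),
        ):
            cfg = self.raw.get(name)
            if cfg:
                for key in crit_keys:
                    if key in cfg:
                        try:
                            SelectionCriterion.parse(str(cfg[key]))
                        except ValueError as exc:
                            raise ConfigError(f"stage '{name}': {key}: {exc}") from exc
        vf = self.raw.get("validate_fractions")
        if vf:
            for key in ["discovery_criterion"] :
                if key in vf:
                    SelectionCriterion.parse(str(vf[key]))
            for c in vf.get("validation_criteria", []):
                try:
                    SelectionCriterion.parse(str(c))
                except ValueError as exc:
                    raise ConfigError(
                        f"stage 'validate_fractions': {c!r}: {exc}"
                    ) from exc

        power = self.raw.get("power")
        if power:
            sizes = power.get("sizes", [])
            if not sizes:
                raise ConfigError("stage 'power': sizes must be non-empty")
            if max(sizes) > sim.n_individuals:
                raise ConfigError(
                    f"stage 'power': sizes {max(sizes)} exceeds "
                    f"n_individuals {sim.n_individuals}"
                )
            if int(power.get("runs", 10)) < 1:
                raise ConfigError("stage 'power': runs must be >= 1")
        panel = self.raw.get("panel")
        if panel:
            if int(panel.get("size", 100)) < 1:
                raise ConfigError("stage 'panel': size must be >= 1")
            if int(panel.get("size", 100)) > sim.n_probes:
                raise ConfigError("stage 'panel': size exceeds n_probes")
        qc = self.raw.get("qc")
        if qc:
            try:
                io_qc.QcThresholds(
                    detection_alpha=qc.get("detection_alpha", 0.05),
                    probe_coverage_min=qc.get("probe_coverage_min", 0.99),
                    sample_coverage_min=qc.get("sample_coverage_min", 0.95),
                )
            except ValueError as exc:
                raise ConfigError(f"stage 'qc': {exc}") from exc
        return sim

    @property
    def mixed_tissue(self) -> str:
        return self.raw.get("simulate", {}).get("mixed_tissue", "mixed")

    def params_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every configured stage in dependency order.

    Writes per-stage tabular outputs plus ``manifest.json`` (stage, outputs,
    parameter hash, seed, duration) under ``outdir``; returns the manifest.
    Any stage failure aborts with the stage name attached.
    """
    sim_config = config.validate()  # pre-flight: nothing runs if this fails
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.raw, fh, sort_keys=True)

    manifest: dict[str, Any] = {
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "stages": [],
    }

    def record(stage: str, outputs: list, t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": sorted(str(Path(o).relative_to(outdir)) for o in outputs),
                "duration_s": round(time.time() - t0, 3),
            }
        )

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # ---------------------------------------------------------- simulate
    t0 = time.time()
    try:
        datasets: dict[str, MethylationDataset] = {}
        truths = {}
        for ct in sim_config.cell_types:
            ds, tr = simulate_dataset(sim_config, cell_type=ct, cohort=0)
            datasets[ct] = ds
            truths[ct] = tr
        mixed_label = config.mixed_tissue
        ds, tr = simulate_dataset(sim_config, tissue=mixed_label, cohort=1)
        datasets[mixed_label] = ds
        truths[mixed_label] = tr
        outs = []
        simdir = outdir / "simulated"
        for label, ds in datasets.items():
            outs += list(io_qc.write_dataset(ds, simdir, prefix=label).values())
        truth_path = simdir / "truth_slopes.tsv"
        truths[mixed_label].slope.to_csv(truth_path, sep="\t", index_label="probe_id")
        outs.append(truth_path)
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)
    record("simulate", outs, t0)

    # ---------------------------------------------------------------- qc
    qc_cfg = config.stage("qc")
    if qc_cfg is not None:
        t0 = time.time()
        try:
            thresholds = io_qc.QcThresholds(
                detection_alpha=qc_cfg.get("detection_alpha", 0.05),
                probe_coverage_min=qc_cfg.get("probe_coverage_min", 0.99),
                sample_coverage_min=qc_cfg.get("sample_coverage_min", 0.95),
            )
            k = int(qc_cfg.get("knn_k", 5))
            outs = []
            for label in list(datasets):
                ds = datasets[label]
                if ds.detection_p is not None:
                    ds = io_qc.qc_filter(ds, thresholds)
                if ds.beta.isna().any().any():
                    ds = io_qc.knn_impute(ds, k=k)
                datasets[label] = ds
            report = {
                label: {"n_probes": d.n_probes, "n_samples": d.n_samples}
                for label, d in datasets.items()
            }
            path = outdir / "qc_report.json"
            _write_json(report, path)
            outs.append(path)
        except Exception as exc:  # noqa: BLE001
            fail("qc", exc)
        record("qc", outs, t0)

    # -------------------------------------------------------- deconvolve
    dec_cfg = config.stage("deconvolve")
    est_fraction_cols: list[str] = []
    if dec_cfg is not None and len(sim_config.cell_types) >= 2:
        t0 = time.time()
        try:
            purified = [datasets[ct] for ct in sim_config.cell_types]
            common = purified[0].probe_ids
            for d in purified[1:]:
                common = common.intersection(d.probe_ids)
            beta = pd.concat(
                [d.beta.loc[common] for d in purified], axis=1
            )
            # purified cohorts share individuals; disambiguate sample IDs
            beta.columns = [
                f"{ct}:{s}"
                for ct, d in zip(sim_config.cell_types, purified)
                for s in d.sample_ids
            ]
            labels = pd.Series(
                [
                    ct
                    for ct, d in zip(sim_config.cell_types, purified)
                    for _ in d.sample_ids
                ],
                index=beta.columns,
            )
            ann = pd.DataFrame({"group": labels}, index=beta.columns)
            sorted_ds = MethylationDataset(beta=beta, annotations=ann, name="sorted")
            reference = build_reference(
                sorted_ds,
                labels,
                alpha_bonf=float(dec_cfg.get("alpha_bonf", 0.05)),
                delta_beta_min=float(dec_cfg.get("delta_beta_min", 0.70)),
            )
            mixed = datasets[config.mixed_tissue]
            est = estimate_cell_fractions(mixed, reference)
            est_cols = est.fractions.add_prefix("est" + FRACTION_PREFIX)
            est_fraction_cols = list(est_cols.columns)
            datasets[config.mixed_tissue] = mixed.with_annotations(est_cols)

            true_frac = mixed.annotations[
                [FRACTION_PREFIX + ct for ct in reference.cell_types]
            ].to_numpy()
            rmse = float(
                np.sqrt(np.mean((est.fractions.to_numpy() - true_frac) ** 2))
            )
            ref_path = outdir / "reference.csv"
            reference.to_csv(ref_path)
            frac_path = outdir / "cell_fractions.csv"
            est.to_csv(frac_path)
            rep_path = outdir / "deconvolution_report.json"
            _write_json(
                {"n_markers": len(reference.marker_ids), "rmse_vs_truth": rmse},
                rep_path,
            )
            outs = [ref_path, frac_path, rep_path]
        except Exception as exc:  # noqa: BLE001
            fail("deconvolve", exc)
        record("deconvolve", outs, t0)

    # -------------------------------------------------------------- admp
    admp_cfg = config.stage("admp") or {}
    t0 = time.time()
    try:
        covariates = list(admp_cfg.get("covariates", ["sex", "batch"]))
        tables: dict[str, AdmpTable] = {}
        outs = []
        for label, ds in datasets.items():
            covs = list(covariates)
            if label == config.mixed_tissue:
                extra = est_fraction_cols or [
                    FRACTION_PREFIX + ct for ct in sim_config.cell_types
                ]
                covs += extra[:-1]  # fractions sum to one; drop last
            table = adjust_pvalues(fit_admp(ds, covs))
            tables[label] = table
            path = outdir / f"admp_{label}.tsv"
            table.to_tsv(path)
            outs.append(path)
        pi0_path = outdir / "pi0.json"
        _write_json(
            {
                label: {
                    "pi0": estimate_pi0(t).pi0,
                    "admp_fraction": estimate_pi0(t).admp_fraction,
                }
                for label, t in tables.items()
            },
            pi0_path,
        )
        outs.append(pi0_path)
    except Exception as exc:  # noqa: BLE001
        fail("admp", exc)
    record("admp", outs, t0)

    labels_order = list(tables)

    # ------------------------------------------------------------ overlap
    ov_cfg = config.stage("overlap")
    if ov_cfg is not None:
        t0 = time.time()
        try:
            crit = SelectionCriterion.parse(str(ov_cfg.get("criterion", "fdr:0.05")))
            universe = set(tables[labels_order[0]].probe_ids)
            for label in labels_order[1:]:
                universe &= set(tables[label].probe_ids)
            sets = {
                label: select_admps(tables[label], crit) & universe
                for label in labels_order
            }
            if len(labels_order) >= 3:
                first3 = labels_order[:3]
                result = nested_overlap(
                    [sets[l] for l in first3], len(universe), labels=tuple(first3)
                ).to_dict()
            else:
                a, b = labels_order[:2]
                result = {
                    "universe_size": len(universe),
                    "labels": [a, b],
                    "overlap": len(sets[a] & sets[b]),
                    "p": hypergeometric_overlap(sets[a], sets[b], len(universe)),
                }
            result["set_sizes"] = {l: len(s) for l, s in sets.items()}
            path = outdir / "overlap.json"
            _write_json(result, path)
            outs = [path]
        except Exception as exc:  # noqa: BLE001
            fail("overlap", exc)
        record("overlap", outs, t0)

    # -------------------------------------------------------- concordance
    cc_cfg = config.stage("concordance")
    if cc_cfg is not None:
        t0 = time.time()
        try:
            crit = SelectionCriterion.parse(
                str(cc_cfg.get("discovery_criterion", "fdr:0.05"))
            )
            alpha = float(cc_cfg.get("validation_alpha", 0.05))
            a, b = labels_order[:2]
            result = tstat_concordance(
                tables[a], tables[b], discovery_criterion=crit, validation_alpha=alpha
            ).to_dict()
            result["discovery"], result["validation"] = a, b
            path = outdir / "concordance.json"
            _write_json(result, path)
            outs = [path]
        except Exception as exc:  # noqa: BLE001
            fail("concordance", exc)
        record("concordance", outs, t0)

    # ------------------------------------------------- validate_fractions
    vf_cfg = config.stage("validate_fractions")
    if vf_cfg is not None:
        t0 = time.time()
        try:
            disc = SelectionCriterion.parse(
                str(vf_cfg.get("discovery_criterion", "effect_size:0.002"))
            )
            crits = [
                SelectionCriterion.parse(str(c))
                for c in vf_cfg.get(
                    "validation_criteria",
                    ["effect_size:0.002", "bonferroni:0.05", "fdr:0.05"],
                )
            ]
            a, b = labels_order[0], labels_order[-1]
            df = cross_validation_fractions(tables[a], tables[b], disc, crits)
            path = outdir / "validation_fractions.tsv"
            df.to_csv(path, sep="\t")
            # beta-profile of the selected sets (selection-bias diagnostic)
            ds = datasets[a]
            profile_sets = {
                disc.label: select_admps(tables[a], disc),
            }
            _, summary = mean_dnam_profile(ds, profile_sets)
            prof_path = outdir / "mean_dnam_profiles.tsv"
            summary.to_csv(prof_path, sep="\t")
            outs = [path, prof_path]
        except Exception as exc:  # noqa: BLE001
            fail("validate_fractions", exc)
        record("validate_fractions", outs, t0)

    # -------------------------------------------------------------- power
    pw_cfg = config.stage("power")
    if pw_cfg is not None:
        t0 = time.time()
        try:
            gold_crit = SelectionCriterion.parse(
                str(pw_cfg.get("gold_criterion", "bonferroni:0.05"))
            )
            run_crit = SelectionCriterion.parse(
                str(pw_cfg.get("criterion", "bonferroni:0.05"))
            )
            label = labels_order[0]
            ds = datasets[label]
            gold = define_gold_standard(ds, list(covariates), gold_crit)
            curve = subsample_sensitivity(
                ds,
                list(covariates),
                gold,
                run_crit,
                sizes=[int(s) for s in pw_cfg["sizes"]],
                runs=int(pw_cfg.get("runs", 10)),
                seed=config.seed,
            )
            curve.gold_criterion = gold_crit.label
            tsv_path = outdir / "power_curve.tsv"
            curve.to_tsv(tsv_path)
            json_path = outdir / "power_summary.json"
            _write_json(curve.to_dict() | {"gold_size": len(gold)}, json_path)
            outs = [tsv_path, json_path]
        except Exception as exc:  # noqa: BLE001
            fail("power", exc)
        record("power", outs, t0)

    # -------------------------------------------------------------- panel
    pn_cfg = config.stage("panel")
    if pn_cfg is not None:
        t0 = time.time()
        try:
            size = int(pn_cfg.get("size", 100))
            rng = np.random.default_rng([config.seed, zlib.crc32(b"panel")])
            probe_universe = np.asarray(tables[labels_order[0]].probe_ids)
            panel_cpgs = sorted(
                rng.choice(probe_universe, size=size, replace=False).tolist()
            )
            summary = panel_sharing(
                panel_cpgs,
                [(l, tables[l]) for l in labels_order],
                alpha=float(pn_cfg.get("alpha", 0.05)),
            )
            tsv_path = outdir / "panel_sharing.tsv"
            out = summary.signed_significance.copy()
            out["sharing_count"] = summary.sharing_count
            out.to_csv(tsv_path, sep="\t")
            json_path = outdir / "panel_summary.json"
            _write_json(summary.to_dict(), json_path)
            outs = [tsv_path, json_path]
        except Exception as exc:  # noqa: BLE001
            fail("panel", exc)
        record("panel", outs, t0)

    _write_json(manifest, outdir / "manifest.json")
    return manifest
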