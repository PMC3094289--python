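"""End-to-end experiment driver: generate → (render → trace) → measure → report.

A :class:`RunManifest` pins every input (configs, seed, stage toggles), is
recorded verbatim in the output directory, and identical manifests produce
byte-identical summary CSVs.  The fast path (``skip_render=True``) runs
morphometry on ground-truth trees; the imaging path renders each arbor to
a synthetic stack and re-traces it first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .consensus import build_consensus, classify_branches, classify_entry
from .genotypes import GENOTYPE_ORDER, load_all_genotype_configs
from .io import read_genotype_config, write_swc, write_varicosity_csv
from .morphometry import (
    MorphometryParams,
    cohort_reference_width,
    filter_and_normalize,
    metrics_frame,
    summarize_arbor,
)
from .render import render_stack
from .stats import cohort_table, cohort_table_frame, ks_test, proportion_test, rank_sum_test
from .synthgen import calibrate_config, sample_cohort
from .templates import load_wildtype_template, write_template
from .trace import trace_stack
from .types import RenderParams

__all__ = ["RunManifest", "run_experiment"]

log = logging.getLogger("pscarbor.pipeline")

#: comparisons mirroring the published statistics: LOF heterozygotes against
#: wildtype, driver-based RNAi genotypes against the driver-alone control
_COMPARISONS = [
    ("plexa_lof_het", "wildtype"),
    ("plexb_lof_het", "wildtype"),
    ("plexa_rnai", "driver_control"),
    ("plexa_rnai_lof", "driver_control"),
    ("plexb_rnai", "driver_control"),
    ("plexb_rnai_lof", "driver_control"),
    ("double_rnai", "driver_control"),
]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce one experiment run."""

    seed: int = 0
    out_dir: str = "results/run"
    config_dir: Optional[str] = None  # None -> packaged genotype configs
    genotypes: Optional[list[str]] = None  # None -> all packaged, table order
    skip_render: bool = True
    write_swc: bool = False
    write_tiff: bool = False
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_configs(manifest: RunManifest) -> dict:
    if manifest.config_dir is None:
        configs = load_all_genotype_configs()
    else:
        cfg_dir = Path(manifest.config_dir)
        configs = {}
        for name in GENOTYPE_ORDER:
            path = cfg_dir / f"{name}.cfg"
            if path.exists():
                configs[name] = read_genotype_config(path)
    if manifest.genotypes:
        configs = {k: configs[k] for k in manifest.genotypes}
    if not configs:
        raise FileNotFoundError("no genotype configs resolvable for the manifest")
    return configs


def run_experiment(manifest: RunManifest) -> Path:
    """Execute the pipeline per the manifest; returns the output directory.

    Outputs: ``manifest.json``, ``summary.csv`` (one row per genotype),
    ``metrics.csv`` (one row per neuron), ``tests.json`` (pairwise test
    battery), ``consensus_template.tsv`` (wildtype cohort consensus), a
    run log, and optionally per-arbor SWC/TIFF files.
    """
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (out / "manifest.json").write_text(manifest.to_json())
        template = load_wildtype_template()
        configs = _load_configs(manifest)
        log.info("run: seed=%d genotypes=%s skip_render=%s",
                 manifest.seed, list(configs), manifest.skip_render)

        ss = np.random.SeedSequence(manifest.seed)
        children = ss.spawn(len(configs))
        cohorts_metrics = {}
        all_rows = []
        wildtype_cohort = None
        per_genotype_counts = {}
        for (name, cfg), child in zip(configs.items(), children):
            cal = calibrate_config(cfg, template)
            log.info("calibrated %s: lambda=%.3f scale=%.3f rho=%.4f",
                     name, cal.variable_branch_rate, cal.length_scale,
                     cal.varicosity_density)
            rng = np.random.default_rng(child)
            cohort = sample_cohort(cal, template, rng)
            if manifest.write_swc or manifest.write_tiff:
                gdir = out / "arbors" / name
                gdir.mkdir(parents=True, exist_ok=True)
                for i, arbor in enumerate(cohort):
                    if manifest.write_swc:
                        write_swc(arbor, gdir / f"{name}_{i:03d}.swc")
                        write_varicosity_csv(arbor, gdir / f"{name}_{i:03d}_varicosities.csv")
            if not manifest.skip_render:
                rparams = RenderParams()
                traced = []
                for i, arbor in enumerate(cohort):
                    stack = render_stack(arbor, rparams, rng)
                    if manifest.write_tiff:
                        from .io import write_tiff
                        write_tiff(stack, out / "arbors" / name / f"{name}_{i:03d}.tif")
                    traced.append(trace_stack(stack))
                cohort_for_metrics = traced
            else:
                cohort_for_metrics = cohort
            ref = cohort_reference_width(cohort_for_metrics)
            filtered = [filter_and_normalize(a, reference_width=ref)
                        for a in cohort_for_metrics]
            classified = [classify_branches(a, template) for a in filtered]
            metrics = []
            for a in classified:
                m = summarize_arbor(a)
                m.n_skeletal = a.flags["n_skeletal"]
                m.n_variable = a.flags["n_variable"]
                m.n_missing_skeletal = a.flags["n_missing_skeletal"]
                m.n_routing_errors = a.flags["n_routing_errors"]
                m.guidance_error = classify_entry(a)
                m.genotype = name
                metrics.append(m)
            cohorts_metrics[name] = metrics
            all_rows.extend(metrics)
            per_genotype_counts[name] = [m.branch_count for m in metrics]
            if name == "wildtype":
                wildtype_cohort = filtered
            log.info("%s: n=%d mean branches %.2f mean length %.1f",
                     name, len(metrics),
                     float(np.mean([m.branch_count for m in metrics])),
                     float(np.mean([m.total_length for m in metrics])))

        metrics_frame(all_rows).to_csv(out / "metrics.csv", index=False,
                                       float_format="%.4f")
        summaries = cohort_table(cohorts_metrics)
        cohort_table_frame(summaries).to_csv(out / "summary.csv", index=False,
                                             float_format="%.4f")

        if wildtype_cohort is not None:
            consensus = build_consensus(wildtype_cohort)
            write_template(consensus, out / "consensus_template.tsv")
            log.info("wildtype consensus skeleton: %d branches", len(consensus))

        tests = _test_battery(cohorts_metrics)
        (out / "tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True))
        log.info("done: %d genotypes", len(cohorts_metrics))
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def _test_battery(cohorts_metrics: dict) -> dict:
    """The published comparison set on the simulated cohorts."""
    tests = {}
    for a, b in _COMPARISONS:
        if a not in cohorts_metrics or b not in cohorts_metrics:
            continue
        ma, mb = cohorts_metrics[a], cohorts_metrics[b]
        entry = {}
        for field, label in [("branch_count", "branches"),
                             ("varicosity_count", "varicosities")]:
            res = rank_sum_test([getattr(m, field) for m in ma],
                                [getattr(m, field) for m in mb])
            entry[label] = {"U": res.statistic, "p": res.p_value, "method": res.method}
        ks = ks_test([m.total_length for m in ma], [m.total_length for m in mb])
        entry["total_length_distribution"] = {"D": ks.statistic, "p": ks.p_value}
        chi = proportion_test(sum(m.guidance_error for m in ma), len(ma),
                              sum(m.guidance_error for m in mb), len(mb))
        entry["guidance_errors"] = {"chi2": chi.statistic, "p": chi.p_value,
                                    "degenerate": chi.degenerate}
        tests[f"{a}_vs_{b}"] = entry
    return tests
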