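#!/usr/bin/env python
"""Cohort statistics: tests, distribution shifts, and histograms.

Loads the per-neuron metrics produced by 02_morphometry_table.py (runs it
if missing), applies the nonparametric battery between knockdowns and
their controls, computes the 100-μm arbor-size histograms for the three
key genotypes, and writes everything under results/stats/.
"""

import json
import subprocess
import sys
from pathlib import Path

import pandas as pd

from pscarbor.stats import (
    ks_test,
    length_histogram,
    percent_change,
    proportion_test,
    rank_sum_test,
)
from pscarbor.types import ArborMetrics

METRICS = Path("results/table1/metrics.csv")
OUT = Path("results/stats")

COMPARISONS = [
    ("plexa_rnai", "driver_control"),
    ("plexb_rnai", "driver_control"),
    ("plexa_lof_het", "wildtype"),
    ("plexb_lof_het", "wildtype"),
    ("double_rnai", "driver_control"),
]


def load_metrics() -> dict[str, list[ArborMetrics]]:
    if not METRICS.exists():
        subprocess.run([sys.executable, "analysis/02_morphometry_table.py"],
                       check=True)
    df = pd.read_csv(METRICS)
    cohorts: dict[str, list[ArborMetrics]] = {}
    for _, r in df.iterrows():
        cohorts.setdefault(r["genotype"], []).append(ArborMetrics(
            branch_count=int(r["branch_count"]),
            total_length=float(r["total_length_um"]),
            varicosity_count=int(r["varicosity_count"]),
            varicosities_per_branch=float(r["varicosities_per_branch"]),
            guidance_error=bool(r["guidance_error"]),
            genotype=str(r["genotype"]),
        ))
    return cohorts


def main() -> None:
    cohorts = load_metrics()
    OUT.mkdir(parents=True, exist_ok=True)
    tests = {}
    for a, b in COMPARISONS:
        ma, mb = cohorts[a], cohorts[b]
        branches = rank_sum_test([m.branch_count for m in ma],
                                 [m.branch_count for m in mb])
        varis = rank_sum_test([m.varicosity_count for m in ma],
                              [m.varicosity_count for m in mb])
        sizes = ks_test([m.total_length for m in ma],
                        [m.total_length for m in mb])
        guid = proportion_test(sum(m.guidance_error for m in ma), len(ma),
                               sum(m.guidance_error for m in mb), len(mb))
        pct, rounded = percent_change(
            float(pd.Series([m.total_length for m in ma]).mean()),
            float(pd.Series([m.total_length for m in mb]).mean()),
        )
        tests[f"{a}_vs_{b}"] = {
            "branch_count_U_p": branches.p_value,
            "varicosity_U_p": varis.p_value,
            "total_length_KS_D": sizes.statistic,
            "total_length_KS_p": sizes.p_value,
            "guidance_chi2_p": guid.p_value,
            "arbor_size_change_pct": rounded,
        }
        print(f"{a} vs {b}: branches p={branches.p_value:.2g}, "
              f"varicosities p={varis.p_value:.2g}, size shift D={sizes.statistic:.2f} "
              f"(p={sizes.p_value:.2g}), arbor size {rounded:+d}%")
    (OUT / "tests.json").write_text(json.dumps(tests, indent=2))

    hist_rows = []
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = {"driver_control": "tab:blue", "plexa_rnai": "tab:orange",
              "plexb_rnai": "tab:green"}
    for name in ("driver_control", "plexa_rnai", "plexb_rnai"):
        edges, freqs = length_histogram(cohorts[name], 100.0)
        for e, f in zip(edges, freqs):
            hist_rows.append({"genotype": name, "bin_left_um": e, "frequency": f})
        ax.bar(edges + 33 * list(colors).index(name), freqs, width=30,
               color=colors[name], label=name, alpha=0.8)
    ax.set_xlabel("total arbor length (μm, 100 μm bins)")
    ax.set_ylabel("relative frequency")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "arbor_size_histograms.png", dpi=120)
    pd.DataFrame(hist_rows).to_csv(OUT / "arbor_size_histograms.csv",
                                   index=False, float_format="%.4f")
    print(f"wrote {OUT/'tests.json'}, {OUT/'arbor_size_histograms.csv'} "
          "and the histogram figure")


if __name__ == "__main__":
    main()
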