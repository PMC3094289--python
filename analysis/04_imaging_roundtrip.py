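#!/usr/bin/env python
"""Imaging-path validation: render cohorts to stacks, re-trace, compare.

Renders the wildtype and PlexA-knockdown cohorts to synthetic
epifluorescence stacks, re-traces them, and compares the traced cohort
means of branch count, total length and varicosity count with the
ground-truth cohort means (expected agreement: within ~10%).  Writes a
comparison table under results/imaging/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pscarbor.genotypes import load_genotype_config
from pscarbor.morphometry import filter_and_normalize, summarize_arbor
from pscarbor.render import render_stack
from pscarbor.synthgen import calibrate_config, sample_cohort
from pscarbor.templates import load_wildtype_template
from pscarbor.trace import trace_stack
from pscarbor.types import RenderParams

SEED = 11
OUT = Path("results/imaging")


def main() -> None:
    template = load_wildtype_template()
    rows = []
    for name in ("wildtype", "plexa_rnai"):
        cal = calibrate_config(load_genotype_config(name), template)
        rng = np.random.default_rng(SEED)
        cohort = sample_cohort(cal, template, rng)
        gt, traced = [], []
        for arbor in cohort:
            stack = render_stack(arbor, RenderParams(), rng)
            tree = trace_stack(stack)
            gt.append(summarize_arbor(
                filter_and_normalize(arbor, reference_width=180.0)))
            traced.append(summarize_arbor(
                filter_and_normalize(tree, reference_width=180.0)))
        for field in ("branch_count", "total_length", "varicosity_count"):
            g = float(np.mean([getattr(m, field) for m in gt]))
            t = float(np.mean([getattr(m, field) for m in traced]))
            rows.append({"genotype": name, "metric": field,
                         "ground_truth": g, "traced": t,
                         "relative_error": (t - g) / g})
            print(f"{name:12s} {field:16s} gt {g:8.1f} traced {t:8.1f} "
                  f"({100*(t-g)/g:+.1f}%)")
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "roundtrip.csv", index=False,
                              float_format="%.4f")


if __name__ == "__main__":
    main()
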