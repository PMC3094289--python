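#!/usr/bin/env python
"""Reproduce the cohort summary table on the ground-truth path.

Runs the full fast pipeline (generate -> filter/normalize -> classify ->
summarize) for all nine genotypes and writes the per-neuron metrics, the
mean ± SEM summary table, and the pairwise test battery under
results/table1/.  This is the synthetic twin of the study's headline
quantification table.
"""

from pscarbor.pipeline import RunManifest, run_experiment

SEED = 1


def main() -> None:
    out = run_experiment(RunManifest(seed=SEED, out_dir="results/table1",
                                     skip_render=True))
    print((out / "summary.csv").read_text())


if __name__ == "__main__":
    main()
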