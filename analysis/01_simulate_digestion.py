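#!/usr/bin/env python
"""Simulate the endoribonuclease digestion experiment.

Generates eight random 500-2000 nt references, records every UGG-motif
cleavage boundary as ground truth, and draws 5'-end-sequencing coverage
profiles from the Poisson + box-convolution read model.  Outputs land under
results/sim/ (refs.fa, coverage.tsv, truth.tsv) and feed 02_map_cleavage.py.
"""

from pathlib import Path

from cleavemap import SimulationConfig, core_io, simulate_experiment
from cleavemap.synthetic_data import write_truth_table

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 7


def main() -> None:
    config = SimulationConfig(seed=SEED)
    references, truth, profiles = simulate_experiment(config)

    OUT.mkdir(parents=True, exist_ok=True)
    core_io.write_fasta(references, OUT / "refs.fa")
    core_io.write_depth_table(profiles, OUT / "coverage.tsv")
    write_truth_table(truth, OUT / "truth.tsv")

    n_sites = sum(len(v) for v in truth.sites.values())
    print(f"simulated {len(references)} references (seed {SEED})")
    for ref in references:
        print(f"  {ref.id}: {len(ref)} nt, {len(truth.sites[ref.id])} true cleavage sites")
    print(f"total true sites: {n_sites}; outputs under {OUT}")


if __name__ == "__main__":
    main()
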