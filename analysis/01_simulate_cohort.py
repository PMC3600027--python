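"""Generate the synthetic study cohort.

Emulates the sequencing design the pipeline targets: ~2.5 kb-insert mate
pairs at 8-fold clone coverage for a tumor, its matched normal and two
healthy controls, with implanted deletions, insertions, inversions and
translocations (half germline), repeat-decoy clusters and ~1% chimeric
noise.  Writes the plain-text bundle under results/sim/.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from matepairsv.synthetic_data import (  # noqa: E402
    SimulationConfig,
    simulate_cohort,
    write_simulation,
)


def main():
    config = SimulationConfig(seed=1)
    genome, genes, truth, frames = simulate_cohort(config)
    outdir = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
    write_simulation(outdir, genome, genes, truth, frames)
    n_somatic = len(truth.somatic())
    print(f"genome: {len(genome.chromosomes)} chromosomes, "
          f"{genome.total_length / 1e6:.0f} Mb, {len(genes)} genes")
    print(f"implanted {len(truth.svs)} SVs ({n_somatic} somatic, "
          f"{len(truth.svs) - n_somatic} germline), "
          f"{len(truth.decoys)} decoy clusters")
    for sample, df in frames.items():
        print(f"  {sample}: {len(df)} mate pairs")
    print(f"bundle -> {os.path.abspath(outdir)}")


if __name__ == "__main__":
    main()
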