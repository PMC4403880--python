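#!/usr/bin/env python
"""Generate the synthetic study: toy genome, condition-specific ChIP/IgG
reads, NRI-scored receptor sites, and the 2x2x3 expression matrix.

Writes every input the downstream stages consume to results/synthetic_study/
and prints a short inventory.  All files are a pure function of the seed.
"""

from pathlib import Path

from relochip.synthetic_data import SimConfig, Simulation

OUT = Path("results/synthetic_study")
SEED = 7


def main() -> None:
    config = SimConfig(seed=SEED)
    sim = Simulation(config)
    paths = sim.write_files(OUT)
    truth = sim.truth()
    print(f"genome: {config.n_chroms} x {config.chrom_length / 1e6:.0f} Mb, "
          f"{len(sim.genes)} genes")
    print(f"planted peaks: {len(truth.baseline_peaks)} baseline (promoter-proximal), "
          f"{len(truth.hormone_peaks)} hormone ({len(truth.shared_peaks)} shared)")
    print(f"receptor sites: {len(truth.prbs)} (factor-bound: {sum(truth.prbs_bound)})")
    reg = truth.genes[truth.genes.regulated != "none"]
    print(f"regulated genes: {len(reg)} ({(reg.regulated == 'up').sum()} up, "
          f"{(reg.regulated == 'down').sum()} down), "
          f"{int(truth.genes.dependent.sum())} knockdown-dependent")
    print(f"wrote {len(paths)} files to {OUT}/")


if __name__ == "__main__":
    main()
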