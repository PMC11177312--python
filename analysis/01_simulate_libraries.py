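#!/usr/bin/env python
"""Simulate matched DUCG and AUCG hairpin-read libraries.

Generates one library per alphabet under the default study condition
(uniform 6N template, G/C-biased incorporation, 6x stalling, 3x
post-mismatch error boost, 0.1% sequencing error) and writes FASTQ plus
the ground-truth sidecar for each under results/libraries/.
"""

from pathlib import Path

from nerpe import AUCG, DUCG, ConstructSpec, CopyingModel
from nerpe.construct import simulate_library

N_READS = 20_000
OUT = Path(__file__).resolve().parent.parent / "results" / "libraries"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = ConstructSpec()
    for system, seed in ((DUCG, 100), (AUCG, 200)):
        model = CopyingModel(system=system, seed=seed)
        fq = OUT / f"{system.name}.fastq"
        truth = OUT / f"{system.name}_truth.tsv"
        truths, _ = simulate_library(model, spec, N_READS, fastq_path=fq, truth_path=truth)
        n_ext = sum(t.n_incorporated > 0 for t in truths)
        print(f"{system.name}: {N_READS} reads -> {fq.name}; "
              f"{n_ext} extended ({n_ext / N_READS:.1%}), "
              f"stalling factor set to {model.stalling_factor:.1f}")


if __name__ == "__main__":
    main()
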