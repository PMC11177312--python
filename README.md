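# nerpe

Analysis of nonenzymatic RNA template copying by deep sequencing and
kinetics, comparing the canonical **AUCG** alphabet with the
noncanonical **DUCG** alphabet in which 2,6-diaminopurine (D) replaces
adenine. D:U pairs form three hydrogen bonds, strengthening substrate
binding; this package quantifies the consequences for copying yield,
fidelity, substrate usage and mismatch stalling.

It is written for origins-of-life researchers running
hairpin-sequencing (NERPE-style) competition experiments and the
accompanying kinetic assays, and for anyone who needs a tested,
configurable simulator of such libraries with ground truth attached.

## What it computes

**Sequencing side.** Reads from a self-priming hairpin construct carry a
randomized 6-nt template and the product copied against it in the same
molecule. After decoding the reverse-transcription letter map (U→T,
D→A), the pipeline recovers (template, product) in copying order and
computes, per system:

- position-dependent frequencies of complementary / mismatched /
  unextended reads (each position normalized to 1);
- mismatch frequency *m* = mismatched / total incorporations over
  positions 1–4;
- the product-base distribution among fully complementary products, and
  the inferred distribution of the 16 bridged dinucleotides N*N from
  adjacent incorporated pairs;
- the position-dependent composition of all 12 template:product (T:P)
  mismatches;
- extension probability past a complementary vs a mismatched terminal
  pair and per-mismatch stalling factors
  S = P(ext | complementary) / P(ext | mismatch);
- the error frequency immediately after a mismatch, versus *m*;
- element-wise DUCG/AUCG frequency-ratio tables with D aligned to A.

**Kinetics side.** Pseudo-first-order fits F(t) = P·(1 − e^(−k·t));
Michaelis–Menten fits k_obs(c) = k_obs_max·c/(K_m + c) with specificity
k_obs_max/K_m; binding free-energy differences
ΔΔG° = R·T·ln(K_m,alt/K_m,ref); and rate-ratio stalling factors
S = k_matched/k_mismatched.

**Simulator.** A seeded generative model of the hairpin library
(template distribution, incorporation propensity matrix, extension /
stalling probabilities, post-mismatch error boost, sequencing errors)
that writes standard FASTQ plus a ground-truth TSV, used throughout the
tests for parameter-recovery validation. See `docs/methods.md` for the
model and every default.

## Worked example

```python
import numpy as np
from nerpe import DUCG, ConstructSpec, CopyingModel
from nerpe.construct import simulate_library
from nerpe.fidelity import build_report
from nerpe.reads import process_library

spec = ConstructSpec()                       # 12-nt handle, 6N template, 20-nt loop
model = CopyingModel(system=DUCG, seed=100)  # defaults: see docs/methods.md
simulate_library(model, spec, 20_000, fastq_path="DUCG.fastq")

reads, summary = process_library("DUCG.fastq", spec, DUCG)
report = build_report(reads, DUCG)
print(f"{summary.n_pass}/{summary.n_total} pass; m = {report.m:.4f}; "
      f"ext ratio = {report.extension['ratio']:.2f}")
```

prints

```
19995/20000 pass; m = 0.1391; ext ratio = 6.46
```

i.e. 5 of 20,000 simulated reads fail the anchor filter (substitution
errors in constant regions), the mismatch frequency over positions 1–4
is 0.139, and extension past a complementary terminal pair is 6.5× more
likely than past a mismatch — recovering the simulator's configured
stalling factor of 6.

The same pipeline is shell-runnable:

```
nerpe simulate --config config.yaml --out sim/
nerpe analyze  --fastq sim/reads.fastq --config config.yaml --out report/
nerpe compare  --a report_DUCG.json --b report_AUCG.json --out ratios/
nerpe kinetics fit-mm --in saturation.tsv
```

and the `analysis/` directory holds the numbered end-to-end drivers
(`01_simulate_libraries.py` … `04_kinetics.py`) that write their tables
under `results/`. On the kinetics side, fitting the saturation curves
defined by the measured parameter pairs — A\*A (k_obs_max = 27 h⁻¹,
K_m = 0.64 mM) and D\*D (20 h⁻¹, 0.033 mM) — gives specificities of 42
and 610 h⁻¹·mM⁻¹ at two significant figures, and the K_m ratio
corresponds to ΔΔG°₂₅ = −1.76 kcal/mol in favor of D:U binding.

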