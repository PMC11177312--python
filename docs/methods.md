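# Methods

## Scientific setting

Nonenzymatic RNA template copying — primer extension by chemically
activated nucleotides without enzymes — is the leading model for genetic
information transfer before the advent of ribozymes. The dominant
reactive substrate is the 5′–5′ imidazolium-bridged dinucleotide (N*N),
which binds the template through two base pairs. This package analyzes
such copying reactions in two four-letter alphabets: the canonical AUCG
system and a noncanonical DUCG system in which 2,6-diaminopurine (D)
replaces adenine. D pairs with U through three hydrogen bonds rather
than two, strengthening substrate binding; the analyses quantify what
this does to copying yield, fidelity, substrate usage, and stalling.

Two experimental readouts are covered:

1. **Deep sequencing of self-priming hairpin constructs.** A hairpin
   carries a randomized 6-nt template region (6N); after the copying
   reaction the product is ligated context within the same molecule, so
   one sequencing read contains both the template and the bases copied
   against it. Reverse transcription renders U as T and D as A, so the
   chemical alphabet must be declared to decode reads.
2. **Kinetics.** Pseudo-first-order rate constants k_obs from
   time courses, Michaelis–Menten saturation of k_obs with substrate
   concentration, and stalling factors defined as rate ratios.

## Read model and processing

A read is laid out 5′→3′ in cDNA space as

    handle5 (12 nt) + template region (6 nt) + loop (20 nt) + product (0–6 nt)

Copying proceeds from the template base adjacent to the primer, so the
template region appears in the read in reverse copying order: templating
position i (1-based, position 1 = first incorporated nucleotide) sits at
template-region index `template_len − i + 1`. The default constant
regions are invented sequences sharing no 6-mer with each other; the
construct is fully configurable so published sequences can be
substituted for real data.

Processing verifies both constant regions at fixed offsets within a
Hamming-distance budget (default 1 substitution each; no indel
alignment — the generator's error model is substitution-only, a
documented limitation for real data containing indels). The template
and product regions are decoded into the declared alphabet (`T→U`, and
`A→D` in DUCG mode), with `N` treated as ambiguity and never counted.
Per-base quality below Q20 in either analyzed region fails the read;
constant regions are exempt beyond anchor matching. A product region
longer than the template fails as a length anomaly. Reads failing any
filter are excluded from all statistics — no partial credit — matching
the all-or-none accounting implied by frequency tables normalized to 1.

## Generative model (synthetic libraries)

The simulator emulates the competition experiment at the level of its
observables, not its chemistry. For each read:

- template drawn i.i.d. from `template_dist` (default uniform — the 6N
  randomized region);
- product built left to right: extension occurs with probability
  `p_ext_initial` at step 1, thereafter `p_ext_after_match` or
  `p_ext_after_mismatch` according to the terminal pair's status;
- on extension, the incorporated base is sampled in proportion to the
  propensity row `W[t][·]` of the templating base; immediately after a
  mismatch, mismatch entries are multiplied by
  `post_mismatch_error_boost`;
- the read is emitted in cDNA letters with i.i.d. substitutions at
  `seq_error_rate` and constant Q40 qualities.

Default parameters (chosen once as the package's study conditions):

| parameter | default | rationale |
|---|---|---|
| `template_dist` | uniform | the 6N construct contains all four bases |
| `W[t][p]` | affinity(p) × 20 if complementary | match dominance κ=20 gives m ≈ 0.12, a realistic single-addition error rate; affinity (0.7, 0.7, 1.0, 1.3) for (D/A, U, C, G) reproduces the G/C incorporation bias of equimolar substrate mixes |
| `p_ext_initial` | 0.55 | roughly half of hairpins extend at least once in 24 h |
| `p_ext_after_match` | 0.60 | continued extension comparable to initiation |
| `p_ext_after_mismatch` | 0.10 | generator stalling factor 6, inside the observed 4–9× range |
| `post_mismatch_error_boost` | 3.0 | error frequency after a mismatch well above the overall m |
| `seq_error_rate` | 0.001 | typical Illumina substitution rate |
| `rt_error_rate` | 0.0 | the RT used incorporates T opposite D with high fidelity; the knob exists but no value is asserted |

What the generator does **not** emulate: bridged-intermediate formation
and hydrolysis equilibria, Mg²⁺-dependence (different reaction
conditions enter only as different parameter sets), paired-end reads and
their error correction (replaced by the quality/anchor filter), indels,
over-extension beyond the 6-nt template, and position-dependent
chemistry. Passing tests therefore demonstrate that the estimators
recover known generative parameters — not that real libraries satisfy
this model.

## Fidelity statistics

All statistics operate on passing reads only; read order never matters.

- **Position frequencies.** At position i a read is complementary or
  mismatched iff it incorporated ≥ i bases, unextended otherwise; the
  three frequencies sum to 1 at every position.
- **Mismatch frequency m** = mismatched / total incorporations over
  positions 1–4. The window is a parameter; 1–4 is the operational
  definition attached to the reported numbers.
- **Product-base distribution** conditions on *fully complementary*
  products, meaning every incorporated base is complementary — full
  6-nt extension is not required. Rows with no qualifying reads are
  undefined (NaN), never 0.
- **Inferred bridged dinucleotides.** Each adjacent incorporated pair
  (product[i], product[i+1]) within a fully complementary product
  contributes one count to species N1\*N2; overlapping pairs all count;
  raw counts are normalized to 1. An optional template-context
  normalization (divide by template dinucleotide availability, then
  renormalize) is provided but off by default.
- **Mismatch composition**: frequency of each of the 12 mismatch labels
  among incorporations at each position.
- **Stalling (sequencing version).** P(extension past position 1 |
  complementary) over P(extension | mismatched); per-mismatch stalling
  factors S(label) divide the complementary-side probability by each
  label's extension probability. Position 1 is the default conditioning
  (pooled-position mode available); labels never observed are absent,
  not zero.
- **Post-mismatch error**: among transitions (position i mismatched,
  i+1 incorporated), the fraction of i+1 mismatches, compared with m.
- **Cross-system ratios** align tables positionally by alphabet index,
  so D (DUCG) divides by A (AUCG). Zero denominators yield flagged NaN,
  never infinity.

## Kinetics

- Time courses follow F(t) = P·(1 − e^(−k·t)) with the plateau P fitted
  and bounded to (0, 1] (endpoints rarely reach 1). Initialization: P̂ =
  min(1, 1.05·max F), k from the slope of ln(P̂ − F) against t.
- Saturation curves follow k_obs(c) = k_obs_max·c/(K_m + c), unweighted
  least squares, initialized from the double-reciprocal linearization.
  A curve with no saturation signal (fitted K_m more than 10× beyond the
  measured range) returns with a warning flag rather than failing
  silently. Specificity k_obs_max/K_m is echoed at two significant
  figures where a headline number is wanted (606.06 → 610).
- ΔΔG° = R·T·ln(K_m,alt/K_m,ref) with R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹,
  evaluated at 298.15 K; negative when the alternative binds tighter.
- Stalling factor S = k_matched/k_mismatched for terminal-pair rate
  pairs. Units are h⁻¹ and mM throughout.

## Numerical and testing choices

- Randomness uses `numpy.random.default_rng` with explicit seeds; all
  outputs are byte-identical under a fixed seed (no timestamps in data
  files).
- The stochastic simulator is validated against an analytic two-state
  forward recursion over terminal-pair status, implemented independently
  in the test suite: with mismatch-given-incorporation probabilities q₀
  (unboosted) and q_b (boosted), the active complementary/mismatched
  masses propagate by the extension probabilities, giving exact marginal
  per-position frequencies. Empirical frequencies from 50,000 reads are
  required to match within 3 binomial standard errors at every position.
- Parameter-recovery checks (stalling ratio, per-mismatch S) run with
  `seq_error_rate = 0`: they verify the estimators, and substitution
  errors contaminate the mismatch conditioning set with misclassified
  complementary reads — a real effect of the assay that the recovery
  contract deliberately excludes.
- Normalized outputs are asserted to sum to 1 within 1e−9; undefined
  statistics raise typed errors (`UndefinedStatisticError`) or surface
  as NaN in tables, never as silent zeros.
- Problem sizes: 50,000 reads for oracle equivalence, 100,000 for
  stalling recovery, 200 replicates for noisy-fit error — sizes at which
  the 3-SE and 10% bands have comfortable statistical margin.

## Known limitations

- Anchor matching cannot rescue reads with indels in constant regions.
- Decoding is alphabet-blind within a system: an erroneous A in a DUCG
  read decodes as D, mirroring the unavoidable ambiguity of the real
  RT readout.
- Single-end reads only; the paired-read error correction of the
  original sequencing protocol is out of scope.
- The kinetic fits assume homoscedastic noise; replicate SDs are carried
  but not used as weights.
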