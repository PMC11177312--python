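"""Synthetic self-priming hairpin reads with a randomized 6-nt template.

Emulates the deep-sequencing readout of nonenzymatic template copying: a
hairpin construct carries a randomized template region (6N) and, after
the copying reaction and reverse transcription, the copied product sits
in the same read downstream of a constant loop/primer region. Read
layout, 5'→3' in cDNA space::

    handle5 + template_region + loop + product_region

Copying proceeds from the template base adjacent to the primer, so the
template region appears in the read as positions ``template_len..1`` of
copying order: templating position i sits at template-region index
``template_len - i + 1`` (1-based). Position 1 is the first incorporated
nucleotide throughout.

The generative model is position-wise: at each step the primer extends
with a probability depending on the status of the terminal pair
(initial / after a match / after a mismatch); on extension the
incorporated base is sampled from the propensity row of the templating
base, with mismatch entries multiplied by a boost immediately after a
mismatch. Substitution sequencing errors are applied i.i.d. in cDNA
space over the whole read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chemistry import ChemistrySystem, DUCG

__all__ = ["ConstructSpec", "CopyingModel", "TrueRecord", "simulate_read", "simulate_library"]

# Invented constant regions (the published construct sequences are
# configurable inputs, not defaults). Chosen to share no 6-mer.
DEFAULT_HANDLE5 = "ACGCTAGGTCAT"
DEFAULT_LOOP = "TTCGAAGCCGTACTGATCCA"

TRUTH_COLUMNS = ("read_id", "template", "product", "classifications", "n_incorporated")


@dataclass(frozen=True)
class ConstructSpec:
    """Hairpin read layout: constant anchors flanking the template region."""

    handle5: str = DEFAULT_HANDLE5
    template_len: int = 6
    loop: str = DEFAULT_LOOP

    def __post_init__(self) -> None:
        for name, seq in (("handle5", self.handle5), ("loop", self.loop)):
            if not seq or any(c not in "ACGT" for c in seq):
                raise ValueError(f"{name} must be a nonempty string over ACGT")
        if self.template_len < 1:
            raise ValueError("template_len must be >= 1")

    @property
    def min_read_length(self) -> int:
        return len(self.handle5) + self.template_len + len(self.loop)

    @property
    def loop_offset(self) -> int:
        return len(self.handle5) + self.template_len


def _default_propensity() -> np.ndarray:
    # W[t][p] = affinity(p) * (kappa if complementary else 1); kappa=20
    # gives a per-incorporation mismatch frequency near 0.12, and the
    # affinity vector biases products toward G and C as observed in
    # nonenzymatic copying with equimolar substrates.
    affinity = np.array([0.7, 0.7, 1.0, 1.3])  # A/D, U, C, G
    kappa = 20.0
    comp_idx = [1, 0, 3, 2]  # complement index in alphabet order
    w = np.tile(affinity, (4, 1))
    for t, p in enumerate(comp_idx):
        w[t, p] *= kappa
    return w


@dataclass
class CopyingModel:
    """Generative model of position-wise incorporation and stalling.

    Parameters
    ----------
    system
        Chemistry system whose alphabet orders all vectors/matrices.
    template_dist
        Probabilities of each alphabet base at a template position
        (i.i.d. across positions). Default uniform (the 6N construct).
    propensity
        4×4 positive matrix ``W[t][p]``: relative probability that, given
        incorporation opposite template base t, the incorporated base is
        p. Rows are normalized internally before sampling.
    p_ext_initial, p_ext_after_match, p_ext_after_mismatch
        Extension probabilities for the first incorporation and past a
        complementary / mismatched terminal pair. Their ratio
        ``p_ext_after_match / p_ext_after_mismatch`` is the generator's
        stalling factor.
    post_mismatch_error_boost
        Multiplier (>= 1) on mismatch propensities for the incorporation
        immediately following a mismatch.
    seq_error_rate
        Per-base substitution probability applied in cDNA space.
    rt_error_rate
        Substitution rate of reverse transcription opposite D; the RT
        used reads D as A with high fidelity, so the default is 0.
    """

    system: ChemistrySystem = DUCG
    template_dist: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    propensity: np.ndarray = field(default_factory=_default_propensity)
    p_ext_initial: float = 0.55
    p_ext_after_match: float = 0.60
    p_ext_after_mismatch: float = 0.10
    post_mismatch_error_boost: float = 3.0
    seq_error_rate: float = 0.001
    rt_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.template_dist = np.asarray(self.template_dist, dtype=float)
        self.propensity = np.asarray(self.propensity, dtype=float)
        if self.template_dist.shape != (4,):
            raise ValueError("template_dist must have 4 entries")
        if abs(self.template_dist.sum() - 1.0) > 1e-12:
            raise ValueError("template_dist must sum to 1")
        if np.any(self.template_dist < 0):
            raise ValueError("template_dist entries must be >= 0")
        if self.propensity.shape != (4, 4) or np.any(self.propensity <= 0):
            raise ValueError("propensity must be a strictly positive 4x4 matrix")
        for name in ("p_ext_initial", "p_ext_after_match", "p_ext_after_mismatch",
                     "seq_error_rate", "rt_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.post_mismatch_error_boost < 1.0:
            raise ValueError("post_mismatch_error_boost must be >= 1")

    @property
    def stalling_factor(self) -> float:
        """S_gen = p_ext_after_match / p_ext_after_mismatch."""
        if self.p_ext_after_mismatch == 0:
            return float("inf")
        return self.p_ext_after_match / self.p_ext_after_mismatch

    def replace(self, **kwargs) -> "CopyingModel":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class TrueRecord:
    """Ground truth for one simulated read, in copying order."""

    read_id: str
    template: str
    product: str
    classifications: Tuple[str, ...]
    n_incorporated: int


@dataclass(frozen=True)
class FastqRecord:
    read_id: str
    sequence: str
    qualities: str


_DNA = "ACGT"


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [c for c in _DNA if c != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def simulate_read(
    model: CopyingModel,
    spec: ConstructSpec,
    rng: np.random.Generator,
    read_id: str = "read",
    quality_char: str = "I",
) -> Tuple[TrueRecord, FastqRecord]:
    """Simulate one copying reaction and its sequencing read.

    The template is drawn i.i.d. from ``template_dist``; the product is
    built left to right with the stalling/boost rules of the model; the
    read is emitted in cDNA space with the template region reversed into
    read orientation and i.i.d. substitution errors applied.
    """
    system = model.system
    alphabet = system.alphabet
    comp_idx = [alphabet.index(system.complement[b]) for b in alphabet]

    tmpl_idx = rng.choice(4, size=spec.template_len, p=model.template_dist)
    template = "".join(alphabet[i] for i in tmpl_idx)

    product_idx: List[int] = []
    classifications: List[str] = []
    prev_mismatch: Optional[bool] = None  # None before first incorporation
    for i in range(spec.template_len):
        if prev_mismatch is None:
            p_ext = model.p_ext_initial
        elif prev_mismatch:
            p_ext = model.p_ext_after_mismatch
        else:
            p_ext = model.p_ext_after_match
        if rng.random() >= p_ext:
            break
        t = tmpl_idx[i]
        weights = model.propensity[t].copy()
        if prev_mismatch:
            boost_mask = np.ones(4) * model.post_mismatch_error_boost
            boost_mask[comp_idx[t]] = 1.0
            weights = weights * boost_mask
        p = weights / weights.sum()
        b = rng.choice(4, p=p)
        product_idx.append(b)
        is_mismatch = b != comp_idx[t]
        classifications.append(system.classify_pair(alphabet[t], alphabet[b]).label)
        prev_mismatch = is_mismatch

    product = "".join(alphabet[i] for i in product_idx)
    truth = TrueRecord(read_id, template, product, tuple(classifications), len(product_idx))

    seq = (
        spec.handle5
        + system.encode_for_sequencer(template[::-1])
        + spec.loop
        + system.encode_for_sequencer(product)
    )
    seq = _apply_substitutions(seq, model.seq_error_rate, rng)
    fastq = FastqRecord(read_id, seq, quality_char * len(seq))
    return truth, fastq


def simulate_library(
    model: CopyingModel,
    spec: ConstructSpec,
    n_reads: int,
    fastq_path: Optional[str | Path] = None,
    truth_path: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> Tuple[List[TrueRecord], List[FastqRecord]]:
    """Simulate ``n_reads`` reads; optionally write FASTQ and a truth TSV.

    Deterministic under a fixed seed (``model.seed`` unless overridden).
    The truth sidecar TSV has columns read_id, template, product,
    classifications (comma-joined T:P labels), n_incorporated.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    truths: List[TrueRecord] = []
    fastqs: List[FastqRecord] = []
    for i in range(n_reads):
        t, f = simulate_read(model, spec, rng, read_id=f"sim_{i:07d}")
        truths.append(t)
        fastqs.append(f)
    if fastq_path is not None:
        write_fastq(fastqs, fastq_path)
    if truth_path is not None:
        write_truth_tsv(truths, truth_path)
    return truths, fastqs


def write_fastq(records: Sequence[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


def write_truth_tsv(truths: Sequence[TrueRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.template}\t{t.product}\t"
                f"{','.join(t.classifications)}\t{t.n_incorporated}\n"
            )
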