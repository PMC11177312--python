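"""Recover (template, product) in copying order from hairpin reads.

Each read is matched against the construct's constant regions at fixed
offsets (Hamming distance, no indel alignment — the generator's error
model is substitution-only and the real protocol's constant regions make
offsets deterministic). The template region between the anchors is
reversed into copying order and decoded from cDNA letters into the
declared alphabet; everything after the loop is the product region.
Reads failing any filter are excluded from all statistics.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio import SeqIO

from .chemistry import ChemistrySystem, PairClass
from .construct import ConstructSpec

__all__ = ["FailReason", "ProcessedRead", "extract_regions", "classify_read",
           "process_library", "ProcessingSummary"]


class FailReason(str, Enum):
    ANCHOR_MISMATCH = "anchor_mismatch"
    LOW_QUALITY = "low_quality"
    AMBIGUOUS_BASE = "ambiguous_base"
    LENGTH_ANOMALY = "length_anomaly"


@dataclass
class ProcessedRead:
    """One read reduced to (template, product, classifications) or a failure."""

    read_id: str
    template: str = ""
    product: str = ""
    classifications: Tuple[str, ...] = ()
    n_incorporated: int = 0
    status: str = "pass"
    fail_reason: Optional[FailReason] = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _fail(read_id: str, reason: FailReason) -> ProcessedRead:
    return ProcessedRead(read_id=read_id, status="fail", fail_reason=reason)


def extract_regions(
    read_id: str,
    sequence: str,
    qualities: List[int],
    spec: ConstructSpec,
    system: ChemistrySystem,
    max_anchor_mismatches: int = 1,
    min_quality: int = 20,
) -> ProcessedRead:
    """Locate the construct in one read and decode template and product.

    Anchors are verified at fixed offsets within ``max_anchor_mismatches``
    substitutions each. The quality filter applies only to the two
    analyzed regions; constant regions are exempt beyond anchor matching.
    A product region longer than the template is a length anomaly (the
    model never over-extends), as is a read too short to contain the
    construct.
    """
    sequence = sequence.upper()
    if len(sequence) < spec.min_read_length:
        return _fail(read_id, FailReason.LENGTH_ANOMALY)

    h = len(spec.handle5)
    if _hamming(sequence[:h], spec.handle5) > max_anchor_mismatches:
        return _fail(read_id, FailReason.ANCHOR_MISMATCH)
    lo = spec.loop_offset
    loop_obs = sequence[lo : lo + len(spec.loop)]
    if _hamming(loop_obs, spec.loop) > max_anchor_mismatches:
        return _fail(read_id, FailReason.ANCHOR_MISMATCH)

    tmpl_dna = sequence[h : h + spec.template_len]
    prod_dna = sequence[lo + len(spec.loop) :]
    if len(prod_dna) > spec.template_len:
        return _fail(read_id, FailReason.LENGTH_ANOMALY)

    tmpl_qual = qualities[h : h + spec.template_len]
    prod_qual = qualities[lo + len(spec.loop) : lo + len(spec.loop) + len(prod_dna)]
    if "N" in tmpl_dna or "N" in prod_dna:
        return _fail(read_id, FailReason.AMBIGUOUS_BASE)
    if any(q < min_quality for q in tmpl_qual) or any(q < min_quality for q in prod_qual):
        return _fail(read_id, FailReason.LOW_QUALITY)

    # reverse template region into copying order (position 1 adjacent to primer)
    template = system.decode_from_sequencer(tmpl_dna)[::-1]
    product = system.decode_from_sequencer(prod_dna)
    return ProcessedRead(read_id=read_id, template=template, product=product)


def classify_read(pr: ProcessedRead, system: ChemistrySystem) -> ProcessedRead:
    """Fill position-wise T:P classifications for a passing read."""
    if not pr.passed:
        raise ValueError("classify_read requires a passing read")
    labels = tuple(
        system.classify_pair(t, p).label for t, p in zip(pr.template, pr.product)
    )
    return replace(pr, classifications=labels, n_incorporated=len(pr.product))


@dataclass
class ProcessingSummary:
    n_total: int = 0
    n_pass: int = 0
    fail_counts: Dict[str, int] = field(default_factory=dict)

    def record(self, pr: ProcessedRead) -> None:
        self.n_total += 1
        if pr.passed:
            self.n_pass += 1
        else:
            key = pr.fail_reason.value
            self.fail_counts[key] = self.fail_counts.get(key, 0) + 1

    def as_dict(self) -> Dict[str, object]:
        return {
            "n_total": self.n_total,
            "n_pass": self.n_pass,
            "n_fail": self.n_total - self.n_pass,
            "fail_counts": dict(self.fail_counts),
        }


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def iter_fastq(path: str | Path) -> Iterator[Tuple[str, str, List[int]]]:
    """Yield (read_id, sequence, phred qualities) from a FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]


def process_library(
    fastq_path: str | Path,
    spec: ConstructSpec,
    system: ChemistrySystem,
    max_anchor_mismatches: int = 1,
    min_quality: int = 20,
) -> Tuple[List[ProcessedRead], ProcessingSummary]:
    """Process every read in a FASTQ file; one ProcessedRead per input read."""
    summary = ProcessingSummary()
    out: List[ProcessedRead] = []
    for read_id, seq, quals in iter_fastq(fastq_path):
        pr = extract_regions(
            read_id, seq, quals, spec, system,
            max_anchor_mismatches=max_anchor_mismatches, min_quality=min_quality,
        )
        if pr.passed:
            pr = classify_read(pr, system)
        summary.record(pr)
        out.append(pr)
    return out, summary


def write_reads_tsv(reads: Iterable[ProcessedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttemplate\tproduct\tclassifications\tn_incorporated\tstatus\tfail_reason\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.template}\t{r.product}\t{','.join(r.classifications)}\t"
                f"{r.n_incorporated}\t{r.status}\t{r.fail_reason.value if r.fail_reason else ''}\n"
            )
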