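"""Genetic alphabets, base-pairing rules and sequencer-letter encoding.

Two four-letter alphabets are supported: the canonical ``AUCG`` RNA
alphabet and the noncanonical ``DUCG`` alphabet in which
2,6-diaminopurine (D) replaces adenine. D pairs with U through three
hydrogen bonds, so the complement rule is D↔U (or A↔U) and C↔G in both
systems. Reverse transcription renders both A and D as A in cDNA, and U
as T, so reads are carried in DNA letters and decoded back into the
declared alphabet before any statistic is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Tuple

__all__ = [
    "InvalidBaseError",
    "PairStatus",
    "PairClass",
    "ChemistrySystem",
    "AUCG",
    "DUCG",
    "get_system",
]


class InvalidBaseError(ValueError):
    """A symbol fell outside the alphabet (or DNA letters) it must belong to."""


class PairStatus(str, Enum):
    COMPLEMENTARY = "complementary"
    MISMATCH = "mismatch"


@dataclass(frozen=True)
class PairClass:
    """An ordered template:product base pair and its Watson–Crick status.

    ``label`` uses the field's T:P notation, e.g. ``"D:C"`` for template D
    opposite an incorporated C.
    """

    template_base: str
    product_base: str
    status: PairStatus
    label: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", f"{self.template_base}:{self.product_base}")

    @property
    def is_mismatch(self) -> bool:
        return self.status is PairStatus.MISMATCH


@dataclass(frozen=True)
class ChemistrySystem:
    """A four-letter genetic alphabet with complement and RT-encoding rules.

    Parameters
    ----------
    name
        ``"AUCG"`` or ``"DUCG"``.
    alphabet
        Ordered 4-tuple of base symbols. The order fixes the indexing of
        every vector/matrix statistic (template distributions, propensity
        matrices, mismatch catalogues) and aligns D with A across systems.
    complement
        Involution on the alphabet mapping each template base to its
        unique complementary product base.
    sequencer_letter
        Map from base symbol to the DNA letter it appears as in a read
        (A→A, D→A, U→T, C→C, G→G).
    """

    name: str
    alphabet: Tuple[str, str, str, str]
    complement: Dict[str, str]
    sequencer_letter: Dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != 4:
            raise ValueError("alphabet must contain exactly 4 distinct symbols")
        for b in self.alphabet:
            c = self.complement.get(b)
            if c not in self.alphabet or self.complement[c] != b:
                raise ValueError(f"complement is not an involution at {b!r}")
            if self.sequencer_letter.get(b) not in "ACGT":
                raise ValueError(f"sequencer letter for {b!r} outside ACGT")

    # -- classification -------------------------------------------------

    def _check_base(self, base: str) -> None:
        if base not in self.alphabet:
            raise InvalidBaseError(
                f"base {base!r} is not in the {self.name} alphabet {''.join(self.alphabet)}"
            )

    def classify_pair(self, template_base: str, product_base: str) -> PairClass:
        """Classify an ordered template:product pair as complementary or mismatch."""
        self._check_base(template_base)
        self._check_base(product_base)
        status = (
            PairStatus.COMPLEMENTARY
            if product_base == self.complement[template_base]
            else PairStatus.MISMATCH
        )
        return PairClass(template_base, product_base, status)

    def enumerate_mismatches(self) -> List[PairClass]:
        """The 12-member mismatch catalogue, in alphabet order.

        Ordered pairs (t, p) with p ≠ complement(t); template varies
        slowest. Together with the 4 complementary pairs this covers all
        16 ordered pairs exactly once.
        """
        return [
            self.classify_pair(t, p)
            for t in self.alphabet
            for p in self.alphabet
            if p != self.complement[t]
        ]

    def all_pairs(self) -> List[PairClass]:
        """All 16 ordered template:product pairs, template varying slowest."""
        return [self.classify_pair(t, p) for t in self.alphabet for p in self.alphabet]

    # -- sequencer (cDNA) encoding --------------------------------------

    def encode_for_sequencer(self, seq: str) -> str:
        """Render a base string as the DNA letters a sequencer reports.

        Mirrors reverse transcription: U→T, and D→A (MMLV RT incorporates
        T opposite D, so D is indistinguishable from A in cDNA).
        """
        out = []
        for b in seq:
            if b not in self.alphabet:
                raise InvalidBaseError(
                    f"base {b!r} is not in the {self.name} alphabet"
                )
            out.append(self.sequencer_letter[b])
        return "".join(out)

    def decode_from_sequencer(self, dna: str) -> str:
        """Invert the RT encoding under this declared system.

        T→U; in DUCG mode A decodes to D (the alphabet has no A, so the
        restricted letter map is injective). N passes through as an
        ambiguity marker and is never counted as an incorporation.
        """
        inverse = {v: k for k, v in self.sequencer_letter.items()}
        out = []
        for ch in dna:
            if ch == "N":
                out.append("N")
            elif ch in inverse:
                out.append(inverse[ch])
            else:
                raise InvalidBaseError(f"DNA letter {ch!r} not in {{A,C,G,T,N}}")
        return "".join(out)

    def base_index(self, base: str) -> int:
        self._check_base(base)
        return self.alphabet.index(base)


AUCG = ChemistrySystem(
    name="AUCG",
    alphabet=("A", "U", "C", "G"),
    complement={"A": "U", "U": "A", "C": "G", "G": "C"},
    sequencer_letter={"A": "A", "U": "T", "C": "C", "G": "G"},
)

DUCG = ChemistrySystem(
    name="DUCG",
    alphabet=("D", "U", "C", "G"),
    complement={"D": "U", "U": "D", "C": "G", "G": "C"},
    sequencer_letter={"D": "A", "U": "T", "C": "C", "G": "G"},
)

_SYSTEMS = {"AUCG": AUCG, "DUCG": DUCG}


def get_system(name: str) -> ChemistrySystem:
    """Look up a chemistry system by name (``"AUCG"`` or ``"DUCG"``)."""
    try:
        return _SYSTEMS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown chemistry system {name!r}; expected AUCG or DUCG")
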