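"""Sequencing-derived fidelity statistics for nonenzymatic copying.

All statistics operate on passing :class:`~nerpe.reads.ProcessedRead`
collections and are computed in system-alphabet space. At each
templating position every read is exactly one of complementary,
mismatched, or unextended, so the three frequencies sum to 1. The
mismatch frequency m is the fraction of mismatched over total
incorporations within a position window (default positions 1–4, the
window attached to the reported numbers). The bridged-dinucleotide
distribution is inferred from adjacent incorporated pairs in fully
complementary products: each such pair N1N2 reports one use of the
bridged substrate N1*N2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import ChemistrySystem
from .reads import ProcessedRead

__all__ = [
    "PositionTally", "FidelityReport", "EmptyInputError", "UndefinedStatisticError",
    "tally_positions", "mismatch_frequency", "product_base_distribution",
    "inferred_bridged_distribution", "mismatch_composition", "tp_pair_distribution",
    "extension_past_pair", "per_mismatch_stalling", "post_mismatch_error",
    "build_report", "system_ratio",
]


class EmptyInputError(ValueError):
    """No passing reads were supplied."""


class UndefinedStatisticError(ValueError):
    """The statistic's conditioning set is empty."""


def _passing(reads: Iterable[ProcessedRead]) -> List[ProcessedRead]:
    out = [r for r in reads if r.passed]
    if not out:
        raise EmptyInputError("no passing reads")
    return out


@dataclass
class PositionTally:
    """Per-position counts of complementary / mismatch / unextended reads.

    ``n_mismatch_by_label`` is a 12-label × position DataFrame; at every
    position, ``n_comp + Σ n_mismatch + n_unextended == n_total``.
    """

    system: ChemistrySystem
    template_len: int
    n_total: int
    n_comp: np.ndarray
    n_mismatch_by_label: pd.DataFrame
    n_unextended: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.template_len + 1)

    @property
    def n_mismatch(self) -> np.ndarray:
        return self.n_mismatch_by_label.to_numpy().sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        """Normalized {complementary, mismatch, unextended} by position."""
        f = pd.DataFrame(
            {
                "complementary": self.n_comp / self.n_total,
                "mismatch": self.n_mismatch / self.n_total,
                "unextended": self.n_unextended / self.n_total,
            },
            index=pd.Index(self.positions, name="position"),
        )
        return f


def tally_positions(
    reads: Iterable[ProcessedRead],
    system: ChemistrySystem,
    template_len: int = 6,
) -> PositionTally:
    """Count complementary/mismatch/unextended reads at every position.

    A read counts as complementary or mismatched at position i iff it
    incorporated at least i nucleotides, and as unextended otherwise, so
    the three categories partition the passing reads at every position.
    """
    reads = _passing(reads)
    labels = [m.label for m in system.enumerate_mismatches()]
    n_comp = np.zeros(template_len, dtype=int)
    n_mis = pd.DataFrame(
        np.zeros((len(labels), template_len), dtype=int),
        index=pd.Index(labels, name="mismatch"),
        columns=pd.Index(range(1, template_len + 1), name="position"),
    )
    n_unext = np.zeros(template_len, dtype=int)
    for r in reads:
        for i in range(template_len):
            if r.n_incorporated <= i:
                n_unext[i] += 1
            else:
                label = r.classifications[i]
                t, p = label.split(":")
                if p == system.complement[t]:
                    n_comp[i] += 1
                else:
                    n_mis.loc[label, i + 1] += 1
    return PositionTally(system, template_len, len(reads), n_comp, n_mis, n_unext)


def mismatch_frequency(
    tally: PositionTally, positions: Sequence[int] = (1, 2, 3, 4)
) -> float:
    """m = mismatched / total incorporations over the position window."""
    idx = [p - 1 for p in positions]
    mis = tally.n_mismatch[idx].sum()
    total = mis + tally.n_comp[idx].sum()
    if total == 0:
        raise UndefinedStatisticError("no incorporations in the m window")
    return float(mis / total)


def _is_fully_complementary(read: ProcessedRead, system: ChemistrySystem) -> bool:
    return all(
        p == system.complement[t] for t, p in zip(read.template, read.product)
    )


def product_base_distribution(
    reads: Iterable[ProcessedRead],
    system: ChemistrySystem,
    template_len: int = 6,
) -> pd.DataFrame:
    """Product base frequency by position among fully complementary products.

    Only reads whose every incorporated base is complementary contribute
    (full 6-nt extension is not required); a read with any mismatch is
    excluded from all rows. Rows with no qualifying reads are NaN
    (undefined), not 0.
    """
    reads = _passing(reads)
    counts = np.zeros((template_len, 4), dtype=float)
    for r in reads:
        if not _is_fully_complementary(r, system):
            continue
        for i, p in enumerate(r.product):
            counts[i, system.base_index(p)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(
        freq,
        index=pd.Index(range(1, template_len + 1), name="position"),
        columns=pd.Index(system.alphabet, name="base"),
    )


def _dinucleotide_index(system: ChemistrySystem) -> pd.Index:
    return pd.Index(
        [f"{a}*{b}" for a in system.alphabet for b in system.alphabet],
        name="bridged",
    )


def inferred_bridged_distribution(
    reads: Iterable[ProcessedRead],
    system: ChemistrySystem,
    template_normalized: bool = False,
) -> pd.Series:
    """Normalized distribution of the 16 inferred bridged dinucleotides.

    Every adjacent incorporated pair (product[i], product[i+1]) within a
    fully complementary product contributes one count to species
    ``product[i]*product[i+1]`` (overlapping pairs all count). With
    ``template_normalized`` the raw counts are first divided by the
    availability of the corresponding template dinucleotide among the
    same reads, then renormalized.
    """
    reads = _passing(reads)
    counts = pd.Series(0.0, index=_dinucleotide_index(system))
    tmpl_avail = pd.Series(0.0, index=_dinucleotide_index(system))
    n_pairs = 0
    for r in reads:
        if not _is_fully_complementary(r, system):
            continue
        for i in range(len(r.product) - 1):
            counts[f"{r.product[i]}*{r.product[i + 1]}"] += 1
            n_pairs += 1
            c1 = system.complement[r.template[i]]
            c2 = system.complement[r.template[i + 1]]
            tmpl_avail[f"{c1}*{c2}"] += 1
    if n_pairs == 0:
        raise UndefinedStatisticError("no adjacent incorporated pairs")
    if template_normalized:
        with np.errstate(invalid="ignore", divide="ignore"):
            counts = counts / tmpl_avail.replace(0.0, np.nan)
        counts = counts.fillna(0.0)
    return counts / counts.sum()


def mismatch_composition(tally: PositionTally) -> pd.DataFrame:
    """Frequency of each of the 12 mismatches among incorporations, by position.

    At every position the 12 label frequencies plus the complementary
    frequency sum to 1; positions with no incorporations are NaN.
    """
    inc = tally.n_comp + tally.n_mismatch
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = tally.n_mismatch_by_label.to_numpy() / np.where(inc > 0, inc, np.nan)
    return pd.DataFrame(
        freq, index=tally.n_mismatch_by_label.index,
        columns=tally.n_mismatch_by_label.columns,
    )


def tp_pair_distribution(
    reads: Iterable[ProcessedRead], system: ChemistrySystem
) -> pd.Series:
    """Frequencies of all 16 T:P pairs among all incorporations (pooled positions)."""
    reads = _passing(reads)
    index = pd.Index([pc.label for pc in system.all_pairs()], name="pair")
    counts = pd.Series(0.0, index=index)
    for r in reads:
        for label in r.classifications:
            counts[label] += 1
    total = counts.sum()
    if total == 0:
        raise UndefinedStatisticError("no incorporations")
    return counts / total


def extension_past_pair(
    reads: Iterable[ProcessedRead], system: ChemistrySystem, position: int = 1
) -> Dict[str, Optional[float]]:
    """Probability of extending past a complementary vs a mismatched pair.

    Conditions on reads incorporating at least ``position`` nucleotides;
    "extension" means incorporating at position+1. Empty conditioning
    sets yield None for that side (and for the ratio).
    """
    reads = _passing(reads)
    n = {"comp": 0, "mis": 0}
    ext = {"comp": 0, "mis": 0}
    for r in reads:
        if r.n_incorporated < position:
            continue
        label = r.classifications[position - 1]
        t, p = label.split(":")
        key = "comp" if p == system.complement[t] else "mis"
        n[key] += 1
        if r.n_incorporated >= position + 1:
            ext[key] += 1
    p_comp = ext["comp"] / n["comp"] if n["comp"] else None
    p_mis = ext["mis"] / n["mis"] if n["mis"] else None
    ratio = p_comp / p_mis if p_comp and p_mis else None
    return {
        "p_ext_given_comp": p_comp,
        "p_ext_given_mismatch": p_mis,
        "ratio": ratio,
        "n_comp": n["comp"],
        "n_mismatch": n["mis"],
    }


def per_mismatch_stalling(
    reads: Iterable[ProcessedRead], system: ChemistrySystem, position: int = 1
) -> pd.DataFrame:
    """Extension probability and stalling factor for each mismatch type.

    For each mismatch label observed at ``position``: the probability of
    extending to position+1, and S(label) = p_ext_given_comp / p_ext(label).
    Labels never observed at the position are absent from the table.
    """
    reads = _passing(reads)
    overall = extension_past_pair(reads, system, position=position)
    p_comp = overall["p_ext_given_comp"]
    counts: Dict[str, List[int]] = {}
    for r in reads:
        if r.n_incorporated < position:
            continue
        label = r.classifications[position - 1]
        t, p = label.split(":")
        if p == system.complement[t]:
            continue
        rec = counts.setdefault(label, [0, 0])
        rec[0] += 1
        if r.n_incorporated >= position + 1:
            rec[1] += 1
    rows = []
    for label, (n_at, n_ext) in sorted(counts.items()):
        p_ext = n_ext / n_at
        s = (p_comp / p_ext) if (p_comp is not None and p_ext > 0) else np.nan
        rows.append({"mismatch": label, "n": n_at, "p_ext": p_ext, "S": s})
    return pd.DataFrame(rows).set_index("mismatch") if rows else pd.DataFrame(
        columns=["n", "p_ext", "S"]
    )


def post_mismatch_error(
    reads: Iterable[ProcessedRead],
    system: ChemistrySystem,
    m_positions: Sequence[int] = (1, 2, 3, 4),
    template_len: int = 6,
) -> Dict[str, float]:
    """Error frequency immediately after a mismatch vs the overall m.

    Considers every transition (position i mismatched, position i+1
    incorporated) and reports the fraction of those i+1 incorporations
    that are themselves mismatched, alongside the overall mismatch
    frequency, plus the raw counts for contingency testing.
    """
    reads = _passing(reads)
    n_trans = 0
    n_err = 0
    for r in reads:
        for i in range(r.n_incorporated - 1):
            label = r.classifications[i]
            t, p = label.split(":")
            if p == system.complement[t]:
                continue
            n_trans += 1
            t2, p2 = r.classifications[i + 1].split(":")
            if p2 != system.complement[t2]:
                n_err += 1
    if n_trans == 0:
        raise UndefinedStatisticError("no post-mismatch incorporations")
    tally = tally_positions(reads, system, template_len)
    m = mismatch_frequency(tally, m_positions)
    return {
        "error_freq_after_mismatch": n_err / n_trans,
        "overall_m": m,
        "n_transitions": n_trans,
        "n_errors": n_err,
    }


@dataclass
class FidelityReport:
    """All sequencing-derived statistics for one system/condition."""

    system_name: str
    n_reads: int
    position_freq: pd.DataFrame
    m: float
    product_base_dist: pd.DataFrame
    bridged_dist: pd.Series
    mismatch_comp: pd.DataFrame
    tp_pair_dist: pd.Series
    extension: Dict[str, Optional[float]]
    stalling: pd.DataFrame
    post_mismatch: Dict[str, float]
    m_positions: Tuple[int, ...] = (1, 2, 3, 4)
    stalling_position: int = 1

    def to_json_dict(self) -> Dict[str, object]:
        return {
            "system": self.system_name,
            "n_reads": self.n_reads,
            "m": self.m,
            "m_positions": list(self.m_positions),
            "position_freq": self.position_freq.to_dict(orient="index"),
            "product_base_dist": self.product_base_dist.to_dict(orient="index"),
            "bridged_dist": self.bridged_dist.to_dict(),
            "mismatch_comp": self.mismatch_comp.to_dict(orient="index"),
            "tp_pair_dist": self.tp_pair_dist.to_dict(),
            "extension": self.extension,
            "stalling_position": self.stalling_position,
            "stalling": self.stalling.reset_index().to_dict(orient="records"),
            "post_mismatch": self.post_mismatch,
        }

    def write(self, outdir: str | Path, prefix: str = "") -> Path:
        """Write one TSV per table plus a consolidated JSON report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = f"{prefix}{self.system_name}_"
        self.position_freq.to_csv(outdir / f"{p}position_freq.tsv", sep="\t")
        self.product_base_dist.to_csv(outdir / f"{p}product_base_dist.tsv", sep="\t")
        self.bridged_dist.rename("frequency").to_csv(outdir / f"{p}bridged_dist.tsv", sep="\t")
        self.mismatch_comp.to_csv(outdir / f"{p}mismatch_composition.tsv", sep="\t")
        self.tp_pair_dist.rename("frequency").to_csv(outdir / f"{p}tp_pair_dist.tsv", sep="\t")
        self.stalling.to_csv(outdir / f"{p}stalling.tsv", sep="\t")
        json_path = outdir / f"{p}report.json"
        with open(json_path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=float)
        return json_path


def build_report(
    reads: Iterable[ProcessedRead],
    system: ChemistrySystem,
    template_len: int = 6,
    m_positions: Sequence[int] = (1, 2, 3, 4),
    stalling_position: int = 1,
) -> FidelityReport:
    """Compute the full set of fidelity statistics from passing reads."""
    reads = _passing(reads)
    tally = tally_positions(reads, system, template_len)
    try:
        bridged = inferred_bridged_distribution(reads, system)
    except UndefinedStatisticError:
        bridged = pd.Series(np.nan, index=_dinucleotide_index(system))
    try:
        post = post_mismatch_error(reads, system, m_positions, template_len)
    except UndefinedStatisticError:
        post = {"error_freq_after_mismatch": float("nan"),
                "overall_m": mismatch_frequency(tally, m_positions),
                "n_transitions": 0, "n_errors": 0}
    return FidelityReport(
        system_name=system.name,
        n_reads=len(reads),
        position_freq=tally.frequencies(),
        m=mismatch_frequency(tally, m_positions),
        product_base_dist=product_base_distribution(reads, system, template_len),
        bridged_dist=bridged,
        mismatch_comp=mismatch_composition(tally),
        tp_pair_dist=tp_pair_distribution(reads, system),
        extension=extension_past_pair(reads, system, stalling_position),
        stalling=per_mismatch_stalling(reads, system, stalling_position),
        post_mismatch=post,
        m_positions=tuple(m_positions),
        stalling_position=stalling_position,
    )


def _aligned(values: pd.Series | pd.DataFrame) -> np.ndarray:
    return np.asarray(values, dtype=float)


def system_ratio(report_a: FidelityReport, report_b: FidelityReport) -> Dict[str, pd.DataFrame]:
    """Element-wise A/B frequency ratios between two systems' reports.

    Tables are aligned positionally by alphabet index, so D in a DUCG
    report lines up with A in an AUCG report (the corresponding base).
    Ratios over a zero denominator are NaN (flagged undefined), never
    infinity. Conventionally A = DUCG and B = AUCG, so values above 1
    mean enrichment in the noncanonical system.
    """
    out: Dict[str, pd.DataFrame] = {}
    for name in ("product_base_dist", "tp_pair_dist", "bridged_dist"):
        a = getattr(report_a, name)
        b = getattr(report_b, name)
        va, vb = _aligned(a), _aligned(b)
        if va.shape != vb.shape:
            raise ValueError(f"table {name} shapes differ: {va.shape} vs {vb.shape}")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(vb != 0, va / vb, np.nan)
        if isinstance(a, pd.DataFrame):
            labels = [f"{x}/{y}" for x, y in zip(a.columns, b.columns)]
            out[name] = pd.DataFrame(ratio, index=a.index, columns=labels)
        else:
            labels = [f"{x}/{y}" for x, y in zip(a.index, b.index)]
            out[name] = pd.Series(ratio, index=labels, name="ratio").to_frame()
    return out
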