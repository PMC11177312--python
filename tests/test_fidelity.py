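"""Fidelity statistics: hand-counted oracles, invariants, cross-system ratios."""

import numpy as np
import pandas as pd
import pytest

from nerpe import AUCG, DUCG, CopyingModel, ConstructSpec
from nerpe.construct import simulate_library
from nerpe.fidelity import (
    EmptyInputError,
    UndefinedStatisticError,
    build_report,
    extension_past_pair,
    inferred_bridged_distribution,
    mismatch_composition,
    mismatch_frequency,
    per_mismatch_stalling,
    post_mismatch_error,
    product_base_distribution,
    system_ratio,
    tally_positions,
    tp_pair_distribution,
)
from nerpe.reads import ProcessedRead, classify_read

from conftest import binomial_se


def mk_read(rid, template, product, system=DUCG):
    return classify_read(ProcessedRead(rid, template=template, product=product), system)


def truths_to_reads(truths, system=DUCG):
    return [mk_read(t.read_id, t.template, t.product, system) for t in truths]


# ---------------------------------------------------------------- tallies

def test_tally_hand_count():
    """Three reads stopping at 0, 1, 2 give the hand-counted frequency table."""
    reads = [
        mk_read("a", "GDCUCG", ""),
        mk_read("b", "GDCUCG", "C"),
        mk_read("c", "GDCUCG", "CU"),
    ]
    tally = tally_positions(reads, DUCG, 6)
    f = tally.frequencies()
    assert np.allclose(f["complementary"], [2 / 3, 1 / 3, 0, 0, 0, 0])
    assert np.allclose(f["unextended"], [1 / 3, 2 / 3, 1, 1, 1, 1])
    assert np.allclose(f.sum(axis=1), 1.0)


def test_tally_fully_complementary():
    reads = [mk_read(str(i), "GDCUCG", "CUGDGC") for i in range(5)]
    f = tally_positions(reads, DUCG, 6).frequencies()
    assert np.allclose(f["complementary"], 1.0)


def test_tally_partition_invariant(clean_library):
    tally = tally_positions(clean_library["processed"], DUCG, 6)
    total = tally.n_comp + tally.n_mismatch + tally.n_unextended
    assert np.all(total == tally.n_total)
    assert np.all(np.diff(tally.n_unextended) >= 0)


def test_tally_empty_raises():
    with pytest.raises(EmptyInputError):
        tally_positions([], DUCG, 6)


# ---------------------------------------------------------- mismatch freq

def test_mismatch_frequency_hand_arithmetic():
    """m over positions 1-4 from constructed counts: 40/(40 + 300)."""
    reads = []
    rid = 0
    # 10 all-mismatch reads of length 4: n_mismatch = (10, 10, 10, 10)
    for _ in range(10):
        reads.append(mk_read(str(rid), "GGGGGG", "GGGG")); rid += 1
    # complementary reads stopping at lengths 1..4: n_comp = (90, 80, 70, 60)
    full_comp = "CUGDGC"
    for length, count in [(1, 10), (2, 10), (3, 10), (4, 60)]:
        for _ in range(count):
            reads.append(mk_read(str(rid), "GDCUCG", full_comp[:length])); rid += 1
    tally = tally_positions(reads, DUCG, 6)
    assert list(tally.n_mismatch[:4]) == [10, 10, 10, 10]
    assert list(tally.n_comp[:4]) == [90, 80, 70, 60]
    # mismatched / total incorporations = 40 / (40 + 90 + 80 + 70 + 60)
    m = mismatch_frequency(tally, (1, 2, 3, 4))
    assert m == pytest.approx(40 / 340)


def test_mismatch_frequency_extremes():
    all_comp = [mk_read("a", "GDCUCG", "CUGD")]
    assert mismatch_frequency(tally_positions(all_comp, DUCG, 6)) == 0.0
    all_mis = [mk_read("b", "GGGGGG", "GGGG")]
    assert mismatch_frequency(tally_positions(all_mis, DUCG, 6)) == 1.0
    unextended = [mk_read("c", "GDCUCG", "")]
    with pytest.raises(UndefinedStatisticError):
        mismatch_frequency(tally_positions(unextended, DUCG, 6))


# ------------------------------------------------- product base distribution

def test_product_distribution_excludes_mismatched_reads():
    reads = [
        mk_read("a", "GDCUCG", "CUG"),   # fully complementary, len 3
        mk_read("b", "GDCUCG", "CUC"),   # mismatch at position 3 -> excluded
    ]
    dist = product_base_distribution(reads, DUCG, 6)
    assert dist.loc[1, "C"] == 1.0
    assert dist.loc[3, "G"] == 1.0  # only read "a" contributes at position 3
    assert dist.loc[4].isna().all()  # no qualifying reads: undefined, not 0


def test_product_distribution_forced_by_template(spec):
    """A template distribution concentrated on G forces C-rich products."""
    model = CopyingModel(
        template_dist=np.array([0.01, 0.01, 0.01, 0.97]),
        seq_error_rate=0.0, seed=41,
    )
    truths, _ = simulate_library(model, spec, 4000)
    dist = product_base_distribution(truths_to_reads(truths), DUCG, 6)
    assert dist.loc[1, "C"] > 0.9


def test_product_distribution_uniform_under_forced_extension(spec):
    n = 10_000
    model = CopyingModel(
        propensity=np.eye(4)[:, [1, 0, 3, 2]] + 1e-12,
        p_ext_initial=1.0, p_ext_after_match=1.0,
        seq_error_rate=0.0, seed=43,
    )
    truths, _ = simulate_library(model, spec, n)
    dist = product_base_distribution(truths_to_reads(truths), DUCG, 6)
    for pos in dist.index:
        for b in DUCG.alphabet:
            assert abs(dist.loc[pos, b] - 0.25) < 3 * binomial_se(0.25, n)


# --------------------------------------------------- bridged dinucleotides

def test_bridged_distribution_hand_enumeration():
    reads = [mk_read("a", "CUGDCG", "GDC")]  # fully complementary
    dist = inferred_bridged_distribution(reads, DUCG)
    assert len(dist) == 16
    assert dist["G*D"] == 0.5 and dist["D*C"] == 0.5
    assert dist.sum() == pytest.approx(1.0)


def test_bridged_distribution_requires_adjacent_pairs():
    reads = [mk_read("a", "GDCUCG", "C"), mk_read("b", "GDCUCG", "")]
    with pytest.raises(UndefinedStatisticError):
        inferred_bridged_distribution(reads, DUCG)


def test_bridged_distribution_index_order():
    reads = [mk_read("a", "CUGDCG", "GDC")]
    dist = inferred_bridged_distribution(reads, DUCG)
    assert list(dist.index[:4]) == ["D*D", "D*U", "D*C", "D*G"]


# ----------------------------------------------------- mismatch composition

def test_mismatch_composition_labels_and_normalization(clean_library):
    tally = tally_positions(clean_library["processed"], DUCG, 6)
    comp = mismatch_composition(tally)
    assert list(comp.index) == [m.label for m in DUCG.enumerate_mismatches()]
    inc = tally.n_comp + tally.n_mismatch
    for pos in comp.columns:
        if inc[pos - 1] > 0:
            total = comp[pos].sum() + tally.n_comp[pos - 1] / inc[pos - 1]
            assert total == pytest.approx(1.0, abs=1e-9)


def test_mismatch_composition_forced_label(spec):
    """Elevating only G-opposite-D propensity makes D:G dominate row 1."""
    w = np.full((4, 4), 1e-6)
    for t, p in zip(range(4), [1, 0, 3, 2]):
        w[t, p] = 1.0
    w[0, 3] = 0.5  # template D, product G
    model = CopyingModel(propensity=w, seq_error_rate=0.0, seed=47)
    truths, _ = simulate_library(model, spec, 4000)
    tally = tally_positions(truths_to_reads(truths), DUCG, 6)
    comp = mismatch_composition(tally)
    assert comp[1].idxmax() == "D:G"


# --------------------------------------------------------- stalling et al.

def test_extension_past_pair_null_and_degenerate():
    # all reads stop at position 1: both extension probabilities are 0
    reads = [mk_read(str(i), "GDCUCG", "C") for i in range(5)]
    reads += [mk_read("m", "GDCUCG", "G")]
    out = extension_past_pair(reads, DUCG, 1)
    assert out["p_ext_given_comp"] == 0.0
    assert out["p_ext_given_mismatch"] == 0.0
    assert out["ratio"] is None
    # no mismatched reads at all -> mismatch side undefined
    out = extension_past_pair(reads[:5], DUCG, 1)
    assert out["p_ext_given_mismatch"] is None


def test_extension_ratio_null_case(spec):
    model = CopyingModel(
        p_ext_after_match=0.5, p_ext_after_mismatch=0.5,
        seq_error_rate=0.0, seed=53,
    )
    truths, _ = simulate_library(model, spec, 30_000)
    out = extension_past_pair(truths_to_reads(truths), DUCG, 1)
    assert out["ratio"] == pytest.approx(1.0, rel=0.1)


def test_per_mismatch_stalling_uniform_across_labels(spec):
    """Label-independent stalling: every per-mismatch S near the global one."""
    model = CopyingModel(
        propensity=np.ones((4, 4)),  # frequent mismatches of every kind
        p_ext_initial=1.0, p_ext_after_match=0.6, p_ext_after_mismatch=0.2,
        post_mismatch_error_boost=1.0, seq_error_rate=0.0, seed=59,
    )
    truths, _ = simulate_library(model, spec, 40_000)
    reads = truths_to_reads(truths)
    table = per_mismatch_stalling(reads, DUCG, 1)
    assert len(table) == 12
    for s in table["S"]:
        assert s == pytest.approx(3.0, rel=0.15)
    assert (table["S"] > 1).all()


def test_post_mismatch_error_boost_raises_error_rate(spec):
    base = dict(p_ext_after_mismatch=0.5, seq_error_rate=0.0, seed=61)
    boosted = CopyingModel(post_mismatch_error_boost=5.0, **base)
    truths, _ = simulate_library(boosted, spec, 20_000)
    out = post_mismatch_error(truths_to_reads(truths), DUCG)
    assert out["error_freq_after_mismatch"] > out["overall_m"]


def test_post_mismatch_error_undefined_without_transitions():
    reads = [mk_read("a", "GDCUCG", "CU")]
    with pytest.raises(UndefinedStatisticError):
        post_mismatch_error(reads, DUCG)


# ------------------------------------------------------------ system ratio

def _tiny_report(system, truths):
    return build_report(truths_to_reads(truths, system), system, template_len=6)


def test_system_ratio_identity(spec):
    model = CopyingModel(seq_error_rate=0.0, seed=67)
    truths, _ = simulate_library(model, spec, 3000)
    rep = _tiny_report(DUCG, truths)
    ratios = system_ratio(rep, rep)
    pb = ratios["product_base_dist"].to_numpy()
    assert np.allclose(pb[~np.isnan(pb)], 1.0)
    tp = ratios["tp_pair_dist"].to_numpy()
    assert np.allclose(tp[~np.isnan(tp)], 1.0)


def test_system_ratio_aligns_d_with_a(spec):
    """D (DUCG) and A (AUCG) occupy the same row; 0.17/0.10 -> 1.7."""
    model_d = CopyingModel(system=DUCG, seq_error_rate=0.0, seed=71)
    model_a = CopyingModel(system=AUCG, seq_error_rate=0.0, seed=71)
    truths_d, _ = simulate_library(model_d, spec, 2000)
    truths_a, _ = simulate_library(model_a, spec, 2000)
    rep_d = _tiny_report(DUCG, truths_d)
    rep_a = _tiny_report(AUCG, truths_a)
    ratios = system_ratio(rep_d, rep_a)
    assert ratios["product_base_dist"].columns[0] == "D/A"
    # hand-check one cell against the two reports
    pos = 1
    expected = rep_d.product_base_dist.loc[pos, "D"] / rep_a.product_base_dist.loc[pos, "A"]
    assert ratios["product_base_dist"].loc[pos, "D/A"] == pytest.approx(expected)


def test_system_ratio_zero_denominator_flagged():
    reads = [mk_read("a", "CUGDCG", "GDC")]
    rep = build_report(reads, DUCG)
    rep2 = build_report(reads, DUCG)
    rep2.tp_pair_dist = rep2.tp_pair_dist * 0.0
    ratios = system_ratio(rep, rep2)
    assert np.isnan(ratios["tp_pair_dist"].to_numpy()).all()


def test_report_normalization_and_permutation_invariance(spec):
    model = CopyingModel(seq_error_rate=0.0, seed=73)
    truths, _ = simulate_library(model, spec, 5000)
    reads = truths_to_reads(truths)
    rep = build_report(reads, DUCG)
    assert np.allclose(rep.position_freq.sum(axis=1), 1.0, atol=1e-9)
    assert rep.bridged_dist.sum() == pytest.approx(1.0, abs=1e-9)
    assert rep.tp_pair_dist.sum() == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= rep.m <= 1.0
    rng = np.random.default_rng(0)
    shuffled = list(reads)
    rng.shuffle(shuffled)
    rep2 = build_report(shuffled, DUCG)
    assert rep.m == rep2.m
    pd.testing.assert_frame_equal(rep.position_freq, rep2.position_freq)
    pd.testing.assert_series_equal(rep.bridged_dist, rep2.bridged_dist)
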