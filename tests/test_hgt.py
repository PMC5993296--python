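import numpy as np
import pandas as pd
import pytest

from aims_architect._kmer import revcomp
from aims_architect.hgt import (
    InsertionRecord,
    OccurrenceIndex,
    bias_curve,
    call_insertions,
    cumulative_curve,
    loss_fraction,
    permissive_fraction,
)
from aims_architect.io import HOMOLOGY_COLUMNS
from aims_architect.model import GeneFeature, Genome, ReplichoreMap


def homology_table(rows):
    return pd.DataFrame(rows, columns=HOMOLOGY_COLUMNS)


def genes_on_grid(ids, start=0, step=1000, glen=800):
    return [
        GeneFeature(g, start + i * step, start + i * step + glen, 1)
        for i, g in enumerate(ids)
    ]


GENOME = Genome("rec", "A" * 20_000)
RMAP = ReplichoreMap(ori=10_000, ter=0, length=20_000)
SISTERS = ["sis1"]
STRAINS = ["st1", "st2"]


def _row(q, sub, subj_gene, sim, rb):
    return (q, sub, subj_gene, sim, 100.0, rb)


def base_rows(gene_ids):
    rows = []
    for g in gene_ids:
        for sub in SISTERS + STRAINS:
            rows.append(_row(g, sub, g + "_h", 95.0, True))
    return rows


def test_foreign_gene_filter_rules():
    genes = genes_on_grid(["n1", "f1", "p1"])
    rows = base_rows(["n1"])
    # f1: absent everywhere, best conspecific similarity 30 -> foreign
    for sub in SISTERS + STRAINS:
        rows.append(_row("f1", sub, None, 0.0, False))
    rows.append(_row("f1", "st1", "f1_weak", 30.0, False))
    # p1: absent in sister but reciprocal-best in one strain -> native
    rows.append(_row("p1", "sis1", None, 0.0, False))
    rows.append(_row("p1", "st1", "p1_h", 95.0, True))
    rows.append(_row("p1", "st2", None, 0.0, False))
    recs = call_insertions(GENOME, genes, homology_table(rows), SISTERS, STRAINS,
                           rmap=RMAP)
    assert [r.gene_ids for r in recs] == [["f1"]]


def test_high_similarity_conspecific_homolog_blocks_call():
    genes = genes_on_grid(["f1"])
    rows = [_row("f1", sub, None, 0.0, False) for sub in SISTERS + STRAINS]
    rows.append(_row("f1", "st2", "f1_para", 60.0, False))  # >= 40% similarity
    recs = call_insertions(GENOME, genes, homology_table(rows), SISTERS, STRAINS)
    assert recs == []


def test_consecutive_foreign_genes_merge():
    genes = genes_on_grid(["n1", "f1", "f2", "f3", "n2"])
    rows = base_rows(["n1", "n2"])
    for g in ("f1", "f2", "f3"):
        for sub in SISTERS + STRAINS:
            rows.append(_row(g, sub, None, 25.0, False))
    recs = call_insertions(GENOME, genes, homology_table(rows), SISTERS, STRAINS,
                           rmap=RMAP)
    assert len(recs) == 1
    rec = recs[0]
    assert rec.gene_ids == ["f1", "f2", "f3"]
    assert (rec.start, rec.end) == (1000, 3800)  # intergenic DNA included
    assert rec.midpoint_pct == pytest.approx(
        RMAP.distance_from_terminus(2400, clamp=False)
    )


def test_missing_genomes_are_named():
    genes = genes_on_grid(["n1"])
    with pytest.raises(ValueError, match="ghost"):
        call_insertions(GENOME, genes, homology_table(base_rows(["n1"])),
                        ["ghost"], STRAINS)


def test_permissive_fraction_arithmetic_and_naive_scan(rng):
    """4 leading + 1 lagging planted occurrences -> 0.8, matching a naive scan."""
    pat = "ACGGTCAT"
    L = 40_000
    arr = rng.choice(list("CT"), size=L)  # background free of the pattern
    rmap = ReplichoreMap(ori=20_000, ter=0, length=L)
    span = (22_000, 30_000)  # on the forward arm: Watson is leading
    for k, pos in enumerate(range(23_000, 28_000, 1000)):
        s = pat if k < 4 else revcomp(pat)  # 4 leading, 1 lagging
        arr[pos : pos + 8] = list(s)
    genome = Genome("g", "".join(arr))
    idx = OccurrenceIndex(genome, [pat], rmap)
    rec = InsertionRecord("g", span[0], span[1], ["x"])
    pf = permissive_fraction(rec, idx)
    assert (rec.n_permissive, rec.n_nonpermissive) == (4, 1)
    assert pf.value == 0.8

    # naive scan oracle over the span
    seq = genome.sequence
    n_lead = n_lag = 0
    for p, strand in ((pat, 1), (revcomp(pat), -1)):
        for i in range(span[0], span[1] - 7):
            if seq[i : i + 8] == p:
                if rmap.is_leading(i, strand):
                    n_lead += 1
                else:
                    n_lag += 1
    assert (n_lead, n_lag) == (4, 1)


def _insertion(mid, value_num, value_den, length=1000):
    rec = InsertionRecord("g", 0, length, ["x"], midpoint_pct=mid)
    rec.n_permissive = value_num
    rec.n_nonpermissive = value_den - value_num
    return rec


def test_bias_curve_exact_model_recovery():
    a, b, c = 0.3, 10.0, 0.55
    recs = []
    den = 10**9
    for mid in np.arange(1.0, 50.0, 2.0):
        val = a * np.exp(-mid / b) + c
        recs.append(_insertion(float(mid), int(round(val * den)), den))
    curve = bias_curve(recs, bin_pct=2.0)
    assert curve.a == pytest.approx(a, abs=1e-6)
    assert curve.b == pytest.approx(b, abs=1e-5)
    assert curve.c == pytest.approx(c, abs=1e-6)
    assert curve.r_squared == pytest.approx(1.0, abs=1e-9)


def test_bias_curve_constant_input_degenerate():
    recs = [_insertion(float(m), 60, 100) for m in np.arange(1.0, 50.0, 2.0)]
    with pytest.warns(UserWarning, match="constant"):
        curve = bias_curve(recs, bin_pct=2.0)
    assert curve.a == pytest.approx(0.0, abs=1e-4)
    assert curve.c == pytest.approx(0.6, abs=1e-4)
    assert curve.r_squared is None


def test_bias_curve_needs_three_bins():
    recs = [_insertion(1.0, 8, 10), _insertion(3.0, 7, 10)]
    with pytest.warns(UserWarning, match="fewer than 3"):
        curve = bias_curve(recs, bin_pct=2.0)
    assert curve.a is None


def test_min_span_filter_drops_short_fragments():
    recs = [_insertion(float(m), 9, 10, length=500) for m in (1, 11, 21)]
    recs += [_insertion(float(m), 5, 10, length=5000) for m in (3, 13, 23, 33, 43)]
    curve = bias_curve(recs, bin_pct=10.0, min_span_bp=1000)
    assert sum(curve.bin_n) == 5


def test_loss_identical_windows_is_zero():
    frags = [_insertion(3.0, 7, 10), _insertion(3.0, 9, 10)]
    frags += [_insertion(45.0, 7, 10), _insertion(45.0, 9, 10)]
    out = loss_fraction(frags)
    assert out["loss"] == 0.0


def test_loss_hand_computed_example():
    """ori window {0.5, 1.0} (equal lengths) vs ter window {1.0} -> 0.25."""
    frags = [
        _insertion(45.0, 5, 10),
        _insertion(45.0, 10, 10),
        _insertion(3.0, 10, 10),
    ]
    out = loss_fraction(frags)
    assert out["loss"] == pytest.approx(0.25)
    # antisymmetry under swapping the windows
    swapped = loss_fraction(frags, ter_window=(42.0, 48.0), ori_window=(0.0, 6.0))
    assert swapped["loss"] == pytest.approx(-0.25)


def test_loss_equals_cumulative_area_difference(rng):
    frags = []
    for _ in range(200):
        n = int(rng.integers(1, 30))
        k = int(rng.integers(0, n + 1))
        mid = float(rng.uniform(0, 6))
        rec = _insertion(mid, k, n, length=int(rng.integers(500, 5000)))
        frags.append(rec)
    for _ in range(200):
        n = int(rng.integers(1, 30))
        k = int(rng.integers(0, n + 1))
        rec = _insertion(float(rng.uniform(42, 48)), k, n,
                         length=int(rng.integers(500, 5000)))
        frags.append(rec)
    out = loss_fraction(frags)
    s = np.linspace(0, 1, 2001)
    ter = [r for r in frags if r.midpoint_pct < 6]
    ori = [r for r in frags if r.midpoint_pct >= 42]
    area_ter = np.trapezoid(cumulative_curve(ter, s), s)
    area_ori = np.trapezoid(cumulative_curve(ori, s), s)
    assert out["loss"] == pytest.approx(area_ori - area_ter, abs=1e-3)


def test_loss_empty_window_errors():
    with pytest.raises(ValueError, match="window"):
        loss_fraction([_insertion(3.0, 5, 10)])
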