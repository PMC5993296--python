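import re

import numpy as np
import pytest

from aims_architect._kmer import expand_degenerate, revcomp, string_of
from aims_architect.aims import (
    AimsParams,
    AIMSSet,
    AimsRecord,
    _scan_space,
    _six_tables,
    backbone_genome,
    cluster_aims,
    count_octamer,
    identify_aims,
    shuffle_arms,
)
from aims_architect.model import Genome, ReplichoreMap


def all_leading_watson_map(length):
    """Map whose forward arm covers every octamer start of a linear genome."""
    return ReplichoreMap(ori=0, ter=length - 1, length=length)


# --------------------------------------------------------------------------
# counting


def test_overlapping_occurrences_on_leading_strand():
    g = Genome("g", "A" * 10, circular=False)
    rmap = all_leading_watson_map(10)
    assert count_octamer(g, rmap, "A" * 8) == (3, 0)
    # reverse-complement occurrences sit on the other strand
    assert count_octamer(g, rmap, "T" * 8) == (0, 3)


def naive_strand_counts(seq, pattern, rmap):
    """Regex-style scan oracle over both strands of a linear sequence."""
    n_lead = n_lag = 0
    for pat, strand in ((pattern, 1), (revcomp(pattern), -1)):
        regex = "".join(
            "[" + "".join("ACGT"[b] for b in sorted(expand_degenerate(s))) + "]"
            if s not in "ACGT" else s
            for s in pat
        )
        for m in re.finditer(f"(?=({regex}))", seq):
            if rmap.is_leading(m.start(), strand):
                n_lead += 1
            else:
                n_lag += 1
    return n_lead, n_lag


def test_degenerate_count_equals_naive_scan(rng):
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    g = Genome("g", seq, circular=False)
    rmap = ReplichoreMap(ori=2_000, ter=8_000, length=10_000)
    for pattern in ("AANAAAAA", "ACGRYCGT", "GGGCAGGG"):
        assert count_octamer(g, rmap, pattern) == naive_strand_counts(
            seq, pattern, rmap
        )


def test_degenerate_equals_sum_of_expansions(planted_genome):
    genome, _, rmap, _ = planted_genome
    pattern = "ACGNTCAT"
    nl, ng = count_octamer(genome, rmap, pattern)
    parts = [
        count_octamer(genome, rmap, string_of(c, 8))
        for c in expand_degenerate(pattern)
    ]
    assert nl == sum(p[0] for p in parts)
    assert ng == sum(p[1] for p in parts)


# --------------------------------------------------------------------------
# backbone excision


def test_backbone_no_insertions_is_identity():
    g = Genome("g", "ACGT" * 100)
    bb, remap = backbone_genome(g, [])
    assert bb.sequence == g.sequence and remap == [(0, 400, 0)]


def test_backbone_excision_and_merge():
    g = Genome("g", "A" * 10_000)
    bb, _ = backbone_genome(g, [(1000, 2000)])
    assert bb.length == 9000
    # adjacent spans merge into one excision
    bb2, remap = backbone_genome(g, [(100, 200), (200, 300)])
    assert bb2.length == 9800
    assert remap == [(0, 100, 0), (300, 10_000, 100)]
    with pytest.warns(UserWarning, match="overlapping"):
        bb3, _ = backbone_genome(g, [(100, 250), (200, 300)])
    assert bb3.length == 9800


# --------------------------------------------------------------------------
# arm shuffling


def test_shuffle_is_seeded_and_reproducible(planted_genome):
    genome, _, rmap, _ = planted_genome
    a = shuffle_arms(genome, rmap, segment_bp=10_000, seed=3)
    b = shuffle_arms(genome, rmap, segment_bp=10_000, seed=3)
    c = shuffle_arms(genome, rmap, segment_bp=10_000, seed=4)
    assert a.sequence == b.sequence
    assert a.sequence != c.sequence
    assert a.sequence != genome.sequence


def test_shuffle_conserves_strand_counts_up_to_junctions(planted_genome):
    genome, _, rmap, _ = planted_genome
    segment_bp = 10_000
    shuffled = shuffle_arms(genome, rmap, segment_bp=segment_bp, seed=5)
    n_junctions = genome.length // segment_bp + 4
    tol = 7 * n_junctions
    for pattern in ("ACGGTCAT", "TTGCAACG"):
        before = count_octamer(genome, rmap, pattern)
        after = count_octamer(shuffled, rmap, pattern)
        assert abs(before[0] - after[0]) <= tol
        assert abs(before[1] - after[1]) <= tol


def test_shuffle_leaves_short_arm_intact():
    g = Genome("g", "ACGT" * 2500)  # 10 kb
    rmap = ReplichoreMap(ori=0, ter=5_000, length=10_000)
    with pytest.warns(UserWarning, match="left intact"):
        out = shuffle_arms(g, rmap, segment_bp=40_000, seed=0)
    assert out.sequence == g.sequence


# --------------------------------------------------------------------------
# detection


def test_identify_aims_recovers_planted_truth(planted_genome):
    genome, _, rmap, truth = planted_genome
    params = AimsParams(min_copies=60, n_null=3)
    result = identify_aims(genome, rmap, params, seed=0)
    got = set(result.patterns)
    assert set(truth.planted_aims) <= got
    planted_rec = {r.pattern: r for r in result.records}
    for pat, t in truth.planted_aims.items():
        assert planted_rec[pat].n_leading == t["n_leading"]


def test_identify_aims_null_destroys_gradient(planted_genome):
    """Arm shuffling keeps strand bias but erases the terminus gradient.

    After shuffling, a planted octamer can only pass the terminus-increase
    criteria by chance, so across shuffle seeds the planted patterns survive
    in a small minority of replicates (at this 300 kb fixture scale the
    chance rate per octamer is nonzero but well below half).
    """
    genome, _, rmap, truth = planted_genome
    params = AimsParams(min_copies=60, n_null=0)
    survived = total = 0
    for seed in range(6):
        shuffled = shuffle_arms(genome, rmap, segment_bp=10_000, seed=seed)
        result = identify_aims(shuffled, rmap, params, seed=0)
        survived += len(set(truth.planted_aims) & set(result.patterns))
        total += len(truth.planted_aims)
    assert survived <= total / 3


def test_stringency_monotonicity(planted_genome):
    """AIMS counts are non-increasing along every threshold axis."""
    genome, _, rmap, _ = planted_genome
    tables = _six_tables(genome, rmap)
    base = dict(min_copies=60, n_null=0)
    for axis, values in (
        ("min_bias", [0.6, 0.7, 0.8, 0.9]),
        ("min_ter_increase", [0.0, 0.25, 0.5, 1.0]),
        ("min_copies", [40, 80, 160]),
    ):
        points = [AimsParams(**{**base, axis: v}) for v in values]
        counts, _ = _scan_space(tables, points)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# --------------------------------------------------------------------------
# clustering


def _mkset(patterns):
    recs = [AimsRecord(p, 100, 10, 0.9, 2.0, 0.9, 0.8) for p in patterns]
    return AIMSSet("g", recs, AimsParams())


def test_cluster_overlapping_octamers_one_family():
    s = cluster_aims(_mkset(["GGGCAGGG", "GGCAGGGN"]))
    assert len({r.family for r in s.records}) == 1


def test_cluster_disjoint_octamers_two_families():
    s = cluster_aims(_mkset(["AAAATTTT", "CCCCGGGG"]))
    assert len({r.family for r in s.records}) == 2


def test_cluster_order_independent(rng):
    pats = ["GGGCAGGG", "GGCAGGGA", "TTTTACCC", "NGGCAGGG", "CCCCGGGG"]
    ref = cluster_aims(_mkset(pats))
    ref_fams = {r.pattern: r.family for r in ref.records}
    for _ in range(5):
        perm = list(rng.permutation(pats))
        out = cluster_aims(_mkset(perm))
        assert {r.pattern: r.family for r in out.records} == ref_fams


def test_aims_set_json_round_trip(tmp_path):
    s = _mkset(["GGGCAGGG", "CCCCGGGG"])
    s.null_counts = [1, 2]
    s.fold_enrichment = 5.0
    p = tmp_path / "aims.json"
    s.to_json(p)
    back = AIMSSet.from_json(p)
    assert back.patterns == s.patterns
    assert [vars(r) for r in back.records] == [vars(r) for r in s.records]
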