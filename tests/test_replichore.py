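import numpy as np
import pytest

from aims_architect.model import GeneFeature, Genome, ReplichoreMap
from aims_architect.replichore import (
    DIF_CONSENSUS,
    classify_ori_ter,
    delta_statistic,
    find_breakpoints,
    find_motif,
    pentamer_profile,
    validate_terminus,
)
from aims_architect.synthetic import GenomeSpec, generate_genome

# --------------------------------------------------------------------------
# pentamer profiles


def brute_pentamer_conditionals(seqs):
    """Independent pooled-count oracle for the frame-specific conditionals."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - 4):
            frame = i % 3
            counts.setdefault((frame, seq[i : i + 4]), [0, 0, 0, 0])
            counts[(frame, seq[i : i + 4])]["ACGT".index(seq[i + 4])] += 1
    return counts


def test_single_gene_poly_a_profile():
    g = Genome("g", "AAAAAAA" + "C" * 100)
    prof = pentamer_profile([GeneFeature("a", 0, 7, 1)], g)
    # 3 AAAAA pentamers, one per frame; smoothed P(A|AAAA) = (1+1)/(1+4)
    tet_aaaa = 0
    for frame in range(3):
        assert prof.freqs[frame, tet_aaaa, 0] == pytest.approx(2 / 5)
        assert prof.freqs[frame, tet_aaaa].sum() == pytest.approx(1.0)


def test_short_gene_contributes_nothing():
    g = Genome("g", "ACGTACGTACGT")
    with pytest.warns(UserWarning, match="shorter"):
        prof = pentamer_profile(
            [GeneFeature("a", 0, 4, 1), GeneFeature("b", 0, 12, 1)], g
        )
    assert prof.n_genes == 1


def test_profile_matches_hand_counted_oracle(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(2)]
    genome = Genome("g", seqs[0] + "T" * 10 + seqs[1])
    genes = [GeneFeature("a", 0, 60, 1), GeneFeature("b", 70, 130, 1)]
    prof = pentamer_profile(genes, genome)
    oracle = brute_pentamer_conditionals(seqs)
    for (frame, tet), vec in oracle.items():
        code = 0
        for ch in tet:
            code = code * 4 + "ACGT".index(ch)
        total = sum(vec)
        for b in range(4):
            assert prof.freqs[frame, code, b] == pytest.approx(
                (vec[b] + 1) / (total + 4)
            )


def test_rows_sum_to_one_everywhere(planted_genome):
    genome, feats, _, _ = planted_genome
    prof = pentamer_profile(feats[:50], genome)
    assert np.allclose(prof.freqs.sum(axis=2), 1.0, atol=1e-9)


def test_delta_properties(planted_genome):
    genome, feats, rmap, _ = planted_genome
    lead = [f for f in feats if rmap.is_leading(f.midpoint(genome.length), f.strand)]
    lag = [f for f in feats if f not in lead]
    p_lead = pentamer_profile(lead, genome)
    p_lag = pentamer_profile(lag, genome)
    assert delta_statistic(p_lead, p_lag) > 0
    assert delta_statistic(p_lead, p_lag) == delta_statistic(p_lag, p_lead)
    assert delta_statistic(p_lead, p_lead) == 0.0


def test_empty_gene_set_errors():
    with pytest.raises(ValueError):
        pentamer_profile([], Genome("g", "ACGT" * 100))


# --------------------------------------------------------------------------
# breakpoint search


def test_breakpoints_recover_planted_positions(planted_genome):
    # at this 300-gene fixture scale the delta landscape is flatter than at
    # full scale, so allow 2% of genome length per breakpoint
    genome, feats, true_map, _ = planted_genome
    pred = find_breakpoints(genome, feats)
    L = genome.length
    for got, true in ((pred.ori, true_map.ori), (pred.ter, true_map.ter)):
        err = min(abs(got - true), L - abs(got - true))
        assert err < 0.02 * L


def test_no_signal_flags_low_confidence():
    spec = GenomeSpec(
        length=150_000, n_genes=150, mean_codons=150,
        codon_bias_effect=0.0, leading_fraction=0.5, genome_id="null",
    )
    genome, feats, _, _ = generate_genome(spec, seed=7)
    pred = find_breakpoints(genome, feats)
    assert pred.low_confidence


def test_polarity_classification_majority():
    # genes on [0, 100) arm pointing away from 0 (strand +1) dominate
    L = 1000
    rmap = ReplichoreMap(ori=0, ter=500, length=L)
    genes = [GeneFeature(f"g{i}", i * 40 + 5, i * 40 + 35, 1) for i in range(12)]
    out = classify_ori_ter(
        ReplichoreMap(ori=0, ter=500, length=L, delta=1.0), genes
    )
    assert out.ori == 0 and not out.ambiguous_polarity
    # flipping every strand flips the labelling
    flipped = [GeneFeature(f.gene_id, f.start, f.end, -1) for f in genes]
    out2 = classify_ori_ter(
        ReplichoreMap(ori=0, ter=500, length=L, delta=1.0), flipped
    )
    assert out2.ori == 500


def test_polarity_forced_tie_is_ambiguous():
    L = 1000
    genes = [
        GeneFeature("a", 10, 40, 1),
        GeneFeature("b", 60, 90, -1),
        GeneFeature("c", 510, 540, 1),
        GeneFeature("d", 560, 590, -1),
    ]
    out = classify_ori_ter(ReplichoreMap(ori=0, ter=500, length=L), genes)
    assert out.ambiguous_polarity and out.ori == 0


# --------------------------------------------------------------------------
# motif scanning


def naive_iupac_scan(seq, consensus, max_mm, circular):
    from aims_architect._kmer import IUPAC_SETS, revcomp

    hits = []
    m = len(consensus)
    ext = seq + (seq[: m - 1] if circular else "")
    for pat, strand in ((consensus, 1), (revcomp(consensus), -1)):
        for i in range(len(ext) - m + 1):
            mm = 0
            for j, sym in enumerate(pat):
                ch = ext[i + j]
                ok = ch != "N" and "ACGT".index(ch) in IUPAC_SETS[sym]
                if ch == "N" and sym == "N":
                    ok = True
                mm += not ok
            if mm <= max_mm:
                hits.append((i, strand, mm))
    return sorted(hits)


def test_dif_consensus_instance_both_strands():
    from aims_architect._kmer import revcomp

    instance = "ACTTCGCATAATGTATATTATGTTAAAT"  # R->A, N->C, K->T
    g = Genome("g", "G" * 50 + instance + "G" * 50, circular=False)
    hits = find_motif(g, DIF_CONSENSUS)
    assert hits == [(50, 1, 0)]
    g2 = Genome("g", "G" * 50 + revcomp(instance) + "G" * 50, circular=False)
    assert find_motif(g2, DIF_CONSENSUS) == [(50, -1, 0)]


@pytest.mark.parametrize("max_mm", [0, 1])
def test_motif_scan_equals_naive_oracle(rng, max_mm):
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    g = Genome("g", seq, circular=True)
    consensus = "ACGTRYKM"
    assert find_motif(g, consensus, max_mismatch=max_mm) == naive_iupac_scan(
        seq, consensus, max_mm, circular=True
    )


def test_consensus_longer_than_genome_warns_empty():
    g = Genome("g", "ACGT", circular=False)
    with pytest.warns(UserWarning):
        assert find_motif(g, "A" * 10) == []


# --------------------------------------------------------------------------
# terminus validation


def test_validate_terminus_offsets():
    rmap = ReplichoreMap(ori=2_000_000, ter=0, length=4_000_000)
    assert validate_terminus(rmap, [(0, 1, 0)])["offset_bp"] == 0
    rep = validate_terminus(rmap, [(40_000, 1, 0)])
    assert rep["offset_pct"] == pytest.approx(1.0)
    assert validate_terminus(rmap, [])["found"] is False


def test_validate_terminus_picks_nearest_of_many(rng):
    rmap = ReplichoreMap(ori=500_000, ter=0, length=1_000_000)
    hits = [(int(p), 1, 0) for p in rng.integers(0, 1_000_000, size=20)]
    rep = validate_terminus(rmap, hits)
    brute = min(min(p, 1_000_000 - p) for p, _, _ in hits)
    assert rep["offset_bp"] == brute
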