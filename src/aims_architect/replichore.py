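"""Replication origin/terminus inference from frame-specific pentamer skew.

Protein-coding genes on the leading and lagging strands accumulate different
codon-level composition. For a candidate pair of replication breakpoints the
genes are partitioned into putative leading/lagging classes and, within each
class, the conditional frequency of every pentamer ``P(B5 | first-4-mer)`` is
tabulated separately in the three reading frames. The breakpoint pair
maximising

    delta = sum_r sum_tetramer sum_base (f_lead - f_lag)^2

is reported as the origin/terminus pair; the breakpoint from which most genes
are transcribed away is labelled the origin. Predicted termini can be
cross-checked against dif-site motif hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kmer import IUPAC_SETS, encode, kmer_codes, revcomp
from .model import GeneFeature, Genome, ReplichoreMap

_COMP = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}


@dataclass
class PentamerProfile:
    """Frame-specific conditional pentamer frequencies P(B5 | tetramer, frame).

    ``freqs`` has shape (3, 256, 4): reading frame, prefix tetramer code,
    final base. Rows are additively smoothed (pseudocount 1 per pentamer) so
    every observed tetramer row sums to 1.
    """

    freqs: np.ndarray
    n_genes: int
    strand_class: str = ""


def coding_sequence(genome: Genome, gene: GeneFeature) -> str:
    """Gene sequence in its own coding orientation."""
    if gene.wraps:
        seq = genome.sequence[gene.start :] + genome.sequence[: gene.end]
    else:
        seq = genome.sequence[gene.start : gene.end]
    if gene.strand == -1:
        seq = revcomp(seq)
    return seq


def _gene_pentamer_counts(genome: Genome, gene: GeneFeature) -> np.ndarray:
    """Flat (3*1024,) pentamer counts of one gene, indexed frame*1024 + code."""
    seq = coding_sequence(genome, gene)
    out = np.zeros(3 * 1024, dtype=np.float64)
    if len(seq) < 5:
        return out
    codes = kmer_codes(encode(seq), 5)
    frames = np.arange(len(codes)) % 3
    ok = codes >= 0
    np.add.at(out, frames[ok] * 1024 + codes[ok], 1.0)
    return out


def _counts_to_profile(counts: np.ndarray) -> np.ndarray:
    """Smooth flat counts into conditional frequencies, shape (3, 256, 4)."""
    c = counts.reshape(3, 256, 4) + 1.0
    return c / c.sum(axis=2, keepdims=True)


def pentamer_profile(
    genes: list[GeneFeature], genome: Genome, strand_class: str = ""
) -> PentamerProfile:
    """Pooled conditional pentamer profile of a set of CDS features."""
    cds = [g for g in genes if g.kind == "CDS"]
    if not cds:
        raise ValueError("empty gene set: pentamer profile undefined")
    counts = np.zeros(3 * 1024)
    n_used = 0
    for g in cds:
        c = _gene_pentamer_counts(genome, g)
        if c.sum() == 0:
            warnings.warn(f"{g.gene_id}: shorter than a pentamer, skipped")
            continue
        counts += c
        n_used += 1
    return PentamerProfile(_counts_to_profile(counts), n_used, strand_class)


def delta_statistic(lead: PentamerProfile, lag: PentamerProfile) -> float:
    """Sum of squared differences between leading and lagging profiles."""
    return float(((lead.freqs - lag.freqs) ** 2).sum())


def _boundary_positions(genes: list[GeneFeature], length: int) -> np.ndarray:
    """Midpoint of the intergenic gap after each gene (sorted circular order)."""
    n = len(genes)
    pos = np.empty(n, dtype=np.int64)
    for i in range(n):
        a = genes[i]
        b = genes[(i + 1) % n]
        gap = (b.start - a.end) % length
        pos[i] = (a.end + gap // 2) % length
    return pos


def _pair_delta(
    prefix_plus: np.ndarray, prefix_minus: np.ndarray, i: int, j: int
) -> float:
    """Delta for breakpoints after genes i and j (i < j) given prefix sums."""
    tot_minus = prefix_minus[-1]
    # class 1: genes (i, j] on +1 plus the rest on -1 (label-symmetric)
    c1 = (prefix_plus[j] - prefix_plus[i]) + (
        tot_minus - (prefix_minus[j] - prefix_minus[i])
    )
    c2 = (prefix_plus[-1] + tot_minus) - c1
    return float(((_counts_to_profile(c1) - _counts_to_profile(c2)) ** 2).sum())


def find_breakpoints(
    genome: Genome,
    genes: list[GeneFeature],
    grid: int = 10,
    refine_pct: float = 5.0,
    flat_ratio: float = 2.0,
) -> ReplichoreMap:
    """Locate the replication breakpoints maximising the pentamer delta.

    Candidate breakpoints are intergenic midpoints; a coarse pass over every
    ``grid``-th gap is refined over all gaps within ``refine_pct`` % of the
    coarse optimum. Genes spanning a candidate are classified by midpoint.
    A flat delta landscape (max/median < ``flat_ratio``) sets the
    ``low_confidence`` flag.
    """
    L = genome.length
    cds = sorted(
        (g for g in genes if g.kind == "CDS"),
        key=lambda g: g.midpoint(L) % L,
    )
    n = len(cds)
    if n < 4:
        raise ValueError("need at least 4 CDS features to search breakpoints")

    per_gene = np.stack([_gene_pentamer_counts(genome, g) for g in cds])
    plus = np.array([g.strand == 1 for g in cds])
    prefix_plus = np.zeros((n + 1, per_gene.shape[1]))
    prefix_minus = np.zeros_like(prefix_plus)
    np.cumsum(np.where(plus[:, None], per_gene, 0.0), axis=0, out=prefix_plus[1:])
    np.cumsum(np.where(~plus[:, None], per_gene, 0.0), axis=0, out=prefix_minus[1:])

    bpos = _boundary_positions(cds, L)

    def evaluate(pairs):
        return [(i, j, _pair_delta(prefix_plus, prefix_minus, i, j)) for i, j in pairs]

    coarse_idx = list(range(0, n, max(1, grid)))
    if len(coarse_idx) < 2:
        coarse_idx = list(range(n))
    results = evaluate(
        [(i, j) for ii, i in enumerate(coarse_idx) for j in coarse_idx[ii + 1 :]]
    )
    best_i, best_j, _ = max(results, key=lambda r: r[2])

    win = refine_pct / 100.0 * L
    near_i = [k for k in range(n) if _circ_dist(bpos[k], bpos[best_i], L) <= win]
    near_j = [k for k in range(n) if _circ_dist(bpos[k], bpos[best_j], L) <= win]
    fine = evaluate(
        [(min(a, b), max(a, b)) for a in near_i for b in near_j if a != b]
    )
    results.extend(fine)
    best_i, best_j, best_delta = max(results, key=lambda r: r[2])

    deltas = np.array([r[2] for r in results])
    low_conf = best_delta < flat_ratio * float(np.median(deltas))

    rmap = ReplichoreMap(
        ori=int(bpos[best_i]),
        ter=int(bpos[best_j]),
        length=L,
        delta=best_delta,
        delta_profile=[(int(bpos[i]), int(bpos[j]), d) for i, j, d in results],
        low_confidence=bool(low_conf),
    )
    return classify_ori_ter(rmap, cds)


def _circ_dist(a: int, b: int, length: int) -> int:
    d = abs(int(a) - int(b))
    return min(d, length - d)


def classify_ori_ter(rmap: ReplichoreMap, genes: list[GeneFeature]) -> ReplichoreMap:
    """Label the breakpoint pair so most genes are transcribed away from ori.

    A gene is transcribed away from the origin exactly when it lies on the
    leading strand; the labelling maximising the leading-gene count wins.
    Exact ties fall back to the lower-coordinate origin with the ambiguous
    flag set.
    """
    cds = [g for g in genes if g.kind == "CDS"]
    L = rmap.length
    mids = np.array([g.midpoint(L) % L for g in cds])
    strands = np.array([g.strand for g in cds])
    away = int(np.count_nonzero(rmap.is_leading(mids.astype(np.int64), strands)))
    n = len(cds)
    if 2 * away < n:
        rmap.ori, rmap.ter = rmap.ter, rmap.ori
    elif 2 * away == n:
        # forced tie: leading fractions are complementary, so no tie-break helps
        rmap.ambiguous_polarity = True
        if rmap.ter < rmap.ori:
            rmap.ori, rmap.ter = rmap.ter, rmap.ori
    return rmap


DIF_CONSENSUS = "RNTKCGCATAATGTATATTATGTTAAAT"
TER_CONSENSUS = "AGNATGTTGTAACTAA"


def find_motif(
    genome: Genome,
    consensus: str,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[tuple[int, int, int]]:
    """Scan for an IUPAC consensus, allowing up to ``max_mismatch`` violations.

    Returns (position, strand, mismatches) triples; reverse-complement
    matches are reported on strand -1 at their leftmost Watson coordinate.
    Circular genomes are scanned across the wrap.
    """
    m = len(consensus)
    if m > genome.length:
        warnings.warn("consensus longer than genome; no hits possible")
        return []
    enc = encode(genome.sequence)
    if genome.circular:
        enc = np.concatenate([enc, enc[: m - 1]])
    n = len(enc) - m + 1
    hits: list[tuple[int, int, int]] = []
    patterns = [(consensus.upper(), 1)]
    if both_strands:
        patterns.append((revcomp(consensus), -1))
    for pat, strand in patterns:
        mism = np.zeros(n, dtype=np.int32)
        for j, sym in enumerate(pat):
            allowed = set(IUPAC_SETS[sym])
            if sym == "N":
                allowed.add(4)
            ok = np.isin(enc[j : j + n], list(allowed))
            mism += ~ok
        for p in np.nonzero(mism <= max_mismatch)[0]:
            hits.append((int(p), strand, int(mism[p])))
    hits.sort()
    return hits


def validate_terminus(
    rmap: ReplichoreMap, dif_hits: list[tuple[int, int, int]]
) -> dict:
    """Circular offset between the predicted terminus and the nearest dif hit."""
    if not dif_hits:
        return {"found": False, "message": "no dif found"}
    dists = [_circ_dist(pos, rmap.ter, rmap.length) for pos, _, _ in dif_hits]
    k = int(np.argmin(dists))
    return {
        "found": True,
        "nearest_pos": dif_hits[k][0],
        "offset_bp": int(dists[k]),
        "offset_pct": 100.0 * dists[k] / rmap.length,
    }


def gc_skew_profile(genome: Genome, window: int = 10000) -> np.ndarray:
    """Cumulative (G-C)/(G+C) skew per window — diagnostic output only.

    The pentamer method is the primary breakpoint predictor; this profile is
    provided for visual comparison.
    """
    enc = encode(genome.sequence)
    g = (enc == 2).astype(np.int64)
    c = (enc == 1).astype(np.int64)
    nwin = genome.length // window
    skew = np.zeros(nwin)
    for i in range(nwin):
        sl = slice(i * window, (i + 1) * window)
        gs, cs = g[sl].sum(), c[sl].sum()
        skew[i] = 0.0 if gs + cs == 0 else (gs - cs) / (gs + cs)
    return np.cumsum(skew)
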