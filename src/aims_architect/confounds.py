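"""Alternative-hypothesis controls for the terminus gradients.

If inversions or insertions were avoided near the terminus for reasons other
than AIMS — more highly expressed genes there (codon-usage bias), fewer
inversion-catalysing inverted repeats, longer operons, or older insertions —
these regressions would detect it. Each operation reports a regression of a
per-gene or per-window statistic against distance from the replication
terminus; significance is reported, never asserted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from ._kmer import encode, kmer_codes, revcomp_code
from .model import GeneFeature, Genome, ReplichoreMap
from .replichore import coding_sequence

_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial code
_STOPS = set(_TABLE.stop_codons)
_AA_OF = dict(_TABLE.forward_table)
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _AA_OF.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def _regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    if len(x) < 3:
        raise ValueError("need at least 3 points for a regression")
    reg = stats.linregress(x, y)
    return RegressionResult(reg.slope, reg.intercept, reg.rvalue, reg.pvalue, len(x))


# ---------------------------------------------------------------------------
# codon usage bias

def _codon_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c = seq[i : i + 3]
        if set(c) <= set("ACGT"):
            counts[c] = counts.get(c, 0) + 1
    return counts


def _has_internal_stop(seq: str) -> bool:
    body = seq[: len(seq) - len(seq) % 3]
    return any(body[i : i + 3] in _STOPS for i in range(0, max(len(body) - 3, 0), 3))


def effective_number_of_codons(counts: dict[str, int]) -> float | None:
    """Wright's ENC: 20 for one codon per amino acid, 61 for uniform usage."""
    f_by_deg: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for _aa, codons in _FAMILIES.items():
        deg = len(codons)
        if deg == 1:
            continue
        ns = np.array([counts.get(c, 0) for c in codons], dtype=float)
        n = ns.sum()
        if n < 2:
            continue
        p = ns / n
        f = (n * (p**2).sum() - 1) / (n - 1)
        if f > 0:
            f_by_deg[deg].append(f)
    fbar = {d: np.mean(v) if v else None for d, v in f_by_deg.items()}
    if fbar[2] is None or fbar[4] is None or fbar[6] is None:
        return None
    if fbar[3] is None:  # Ile family unobserved: interpolate
        fbar[3] = (fbar[2] + fbar[4]) / 2
    nc = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return float(min(nc, 61.0))


def _family_freqs(counts: dict[str, int]) -> dict[str, np.ndarray]:
    out = {}
    for aa, codons in _FAMILIES.items():
        ns = np.array([counts.get(c, 0) for c in codons], dtype=float)
        if len(codons) > 1 and ns.sum() > 0:
            out[aa] = ns / ns.sum()
    return out


def codon_deviation(counts: dict[str, int], genome_freqs: dict[str, np.ndarray]) -> float | None:
    """Mean absolute deviation of within-family codon frequencies from genome-wide."""
    gene_freqs = _family_freqs(counts)
    devs = [
        np.abs(gene_freqs[aa] - genome_freqs[aa]).mean()
        for aa in gene_freqs
        if aa in genome_freqs
    ]
    return float(np.mean(devs)) if devs else None


def gc3(counts: dict[str, int]) -> float | None:
    tot = sum(counts.values())
    if tot == 0:
        return None
    gc = sum(n for c, n in counts.items() if c[2] in "GC")
    return gc / tot


def rscu(counts: dict[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage: observed / uniform-expected per family."""
    out = {}
    for aa, codons in _FAMILIES.items():
        if len(codons) == 1:
            continue
        ns = np.array([counts.get(c, 0) for c in codons], dtype=float)
        if ns.sum() == 0:
            continue
        vals = ns / ns.sum() * len(codons)
        for c, v in zip(codons, vals):
            out[c] = float(v)
    return out


def rscu_distance(counts: dict[str, int], genome_rscu: dict[str, float]) -> float | None:
    gene = rscu(counts)
    shared = [c for c in gene if c in genome_rscu]
    if not shared:
        return None
    d = np.array([gene[c] - genome_rscu[c] for c in shared])
    return float(np.sqrt((d**2).mean()))


CODON_METRICS = ("enc", "codon_deviation", "gc3_deviation", "rscu_distance")


def codon_bias_gradient(
    genes: list[GeneFeature],
    genome: Genome,
    rmap: ReplichoreMap,
    metrics: tuple[str, ...] = CODON_METRICS,
) -> dict[str, RegressionResult]:
    """Regress per-gene codon-usage bias against distance from the terminus.

    Four metrics: effective number of codons (lower = more biased),
    within-family frequency deviation from the genome average, |GC3 - genome
    GC3|, and the RMS RSCU distance from the genome profile. Genes with
    internal stops are excluded with a warning.
    """
    cds = [g for g in genes if g.kind == "CDS"]
    usable, counts_list = [], []
    for g in cds:
        seq = coding_sequence(genome, g)
        if _has_internal_stop(seq):
            warnings.warn(f"{g.gene_id}: internal stop codon, excluded")
            continue
        usable.append(g)
        counts_list.append(_codon_counts(seq))
    pooled: dict[str, int] = {}
    for c in counts_list:
        for k, v in c.items():
            pooled[k] = pooled.get(k, 0) + v
    genome_freqs = _family_freqs(pooled)
    genome_rscu = rscu(pooled)
    genome_gc3 = gc3(pooled)

    dist = np.array(
        [rmap.distance_from_terminus(g.midpoint(genome.length)) for g in usable]
    )
    out = {}
    for metric in metrics:
        vals = []
        for c in counts_list:
            if metric == "enc":
                vals.append(effective_number_of_codons(c))
            elif metric == "codon_deviation":
                vals.append(codon_deviation(c, genome_freqs))
            elif metric == "gc3_deviation":
                v = gc3(c)
                vals.append(None if v is None else abs(v - genome_gc3))
            elif metric == "rscu_distance":
                vals.append(rscu_distance(c, genome_rscu))
            else:
                raise ValueError(f"unknown metric {metric!r}")
        ok = np.array([v is not None for v in vals])
        y = np.array([v for v in vals if v is not None], dtype=float)
        out[metric] = _regress(dist[ok], y)
    return out


# ---------------------------------------------------------------------------
# inverted-repeat spacing

def inverted_repeat_spacing(
    genome: Genome,
    rmap: ReplichoreMap,
    k: int = 6,
    window_bp: int = 10_000,
) -> RegressionResult:
    """Regress mean adjacent inverted-repeat spacing per window vs ter distance.

    For each k-mer w, the sorted occurrence positions of w and of its reverse
    complement are merged within each arm; an inverted pair is a consecutive
    pair of occurrences in opposite orientations (for palindromic k-mers,
    every consecutive pair). The mean spacing of pairs whose midpoint falls
    in each window is regressed against the window's distance from the
    terminus.
    """
    rc = revcomp_code(k)
    win_sum: dict[int, float] = {}
    win_cnt: dict[int, int] = {}
    L = rmap.length
    for intervals in rmap.arm_intervals().values():
        # concatenate arm with coordinate bookkeeping per interval
        for a, b in intervals:
            if b - a < k:
                continue
            codes = kmer_codes(encode(genome.sequence[a:b]), k)
            order = np.argsort(codes, kind="stable")
            sorted_codes = codes[order]
            uniq, starts = np.unique(sorted_codes, return_index=True)
            idx_of = {int(c): i for i, c in enumerate(uniq)}
            bounds = np.append(starts, len(sorted_codes))
            for ci, c in enumerate(uniq):
                if c < 0:
                    continue
                rcc = int(rc[c])
                if rcc < int(c):
                    continue  # processed from the partner
                pos_w = order[bounds[ci] : bounds[ci + 1]]
                if rcc == int(c):  # palindrome: all consecutive pairs inverted
                    pos = np.sort(pos_w)
                    lab = np.zeros(len(pos), dtype=np.int8)
                    pairs = np.ones(max(len(pos) - 1, 0), dtype=bool)
                else:
                    if rcc not in idx_of:
                        continue
                    ri = idx_of[rcc]
                    pos_c = order[bounds[ri] : bounds[ri + 1]]
                    pos = np.concatenate([pos_w, pos_c])
                    lab = np.concatenate(
                        [np.zeros(len(pos_w), np.int8), np.ones(len(pos_c), np.int8)]
                    )
                    so = np.argsort(pos)
                    pos, lab = pos[so], lab[so]
                    pairs = lab[1:] != lab[:-1]
                if len(pos) < 2 or not pairs.any():
                    continue
                spacing = (pos[1:] - pos[:-1])[pairs]
                midpt = ((pos[1:] + pos[:-1]) / 2)[pairs] + a
                d_bp = np.asarray(
                    rmap.distance_from_terminus(midpt.astype(np.int64))
                ) / 100.0 * L
                widx = (d_bp // window_bp).astype(int)
                for w, sp in zip(widx, spacing):
                    win_sum[w] = win_sum.get(w, 0.0) + float(sp)
                    win_cnt[w] = win_cnt.get(w, 0) + 1
    if len(win_cnt) < 3:
        raise ValueError("fewer than 3 occupied windows")
    xs = np.array(sorted(win_cnt))
    ys = np.array([win_sum[w] / win_cnt[w] for w in xs])
    return _regress((xs + 0.5) * window_bp, ys)


# ---------------------------------------------------------------------------
# operons

def derive_operons(
    genes: list[GeneFeature], max_gap: int = 50
) -> list[tuple[int, int, int]]:
    """Heuristic operons: same-strand CDS runs with intergenic gap < max_gap.

    Returns (start, end, n_genes) tuples.
    """
    cds = sorted((g for g in genes if g.kind == "CDS"), key=lambda g: g.start)
    operons = []
    i = 0
    while i < len(cds):
        j = i
        while (
            j + 1 < len(cds)
            and cds[j + 1].strand == cds[i].strand
            and cds[j + 1].start - cds[j].end < max_gap
        ):
            j += 1
        operons.append((cds[i].start, cds[j].end, j - i + 1))
        i = j + 1
    return operons


def operon_gradient(
    operons: list[tuple[int, int, int]], rmap: ReplichoreMap
) -> dict[str, RegressionResult]:
    """Regress operon length and genes-per-operon against terminus distance."""
    if not operons:
        raise ValueError("empty operon list")
    dist = np.array(
        [rmap.distance_from_terminus((a + b) / 2) for a, b, _ in operons]
    )
    length = np.array([b - a for a, b, _ in operons], dtype=float)
    ngenes = np.array([n for _, _, n in operons], dtype=float)
    return {
        "length": _regress(dist, length),
        "n_genes": _regress(dist, ngenes),
    }


# ---------------------------------------------------------------------------
# synonymous divergence (insertion age proxy)

@dataclass
class KsResult:
    ks: float | None
    ps: float
    syn_sites: float
    syn_diffs: float
    n_codons: int
    saturated: bool = False


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at pos that are synonymous."""
    aa = _AA_OF.get(codon)
    if aa is None:
        return 0.0
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if _AA_OF.get(alt) == aa:
            syn += 1
    return syn / 3.0


def _syn_sites(codon: str) -> float:
    return sum(_syn_fraction(codon, p) for p in range(3))


def _path_diffs(ca: str, cb: str) -> tuple[float, float] | None:
    """(syn, nonsyn) differences averaged over mutational pathways (NG86)."""
    diff_pos = [p for p in range(3) if ca[p] != cb[p]]
    paths = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt in _STOPS or cur in _STOPS:
                ok = False
                break
            if _AA_OF[cur] == _AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def ks_ng86(seq_a: str, seq_b: str) -> KsResult:
    """Synonymous substitution rate (Nei-Gojobori 1986, Jukes-Cantor corrected).

    Sequences must be equal-length in-frame codon alignments; codons with
    gaps, Ns or stops are skipped. Saturated pairs (pS >= 3/4) carry
    ``ks=None`` with the saturated flag set.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    s_sites = 0.0
    s_diffs = 0.0
    n_codons = 0
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        n_codons += 1
        s_sites += (_syn_sites(ca) + _syn_sites(cb)) / 2
        if ca != cb:
            path = _path_diffs(ca, cb)
            if path is not None:
                s_diffs += path[0]
    if s_sites == 0:
        raise ValueError("zero synonymous sites: Ks undefined")
    ps = s_diffs / s_sites
    if ps >= 0.75:
        return KsResult(None, ps, s_sites, s_diffs, n_codons, saturated=True)
    ks = -0.75 * np.log(1 - 4.0 * ps / 3.0)
    return KsResult(float(ks), ps, s_sites, s_diffs, n_codons)
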