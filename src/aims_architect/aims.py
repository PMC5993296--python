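"""AIMS discovery: strand-biased octamers enriched toward the terminus.

AIMS (Architecture IMparting Sequences) are degenerate octamers that (i) are
strand-biased toward the leading strand, (ii) increase in leading-strand
abundance toward the replication terminus, and (iii) increase in strand-bias
toward the terminus. Candidates are all octamers degenerate at up to two
positions; specificity is calibrated against null genomes built by permuting
fixed-size segments within each chromosome arm, which preserves overall
strand-bias but erases the origin-to-terminus gradient.

Counting is organised around the 4^8 concrete-octamer count table: the count
of any degenerate octamer is the sum over its concrete expansions, and a
leading-strand occurrence of octamer w on the reverse arm is a Watson-strand
occurrence of revcomp(w), so two per-arm Watson tables determine every
leading/lagging count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kmer import (
    DEGENERATE_CODES,
    IUPAC_SETS,
    bincount_codes,
    encode,
    expand_degenerate,
    kmer_codes,
    revcomp_code,
    string_of,
)
from .model import Genome, ReplichoreMap, intersect_intervals, region_intervals

K = 8
NCODES = 4**K
_RC8 = revcomp_code(K)

# membership matrix of the 11 degenerate IUPAC codes over ACGT
_MDEG = np.zeros((len(DEGENERATE_CODES), 4))
for _i, _sym in enumerate(DEGENERATE_CODES):
    for _b in IUPAC_SETS[_sym]:
        _MDEG[_i, _b] = 1.0


# ---------------------------------------------------------------------------
# count tables

def _watson_table(codes: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Counts of octamer start positions (Watson strand) within intervals."""
    parts = [codes[a:b] for a, b in intervals]
    if not parts:
        return np.zeros(NCODES, dtype=np.int64)
    return bincount_codes(np.concatenate(parts), NCODES)


def strand_tables(
    genome: Genome,
    rmap: ReplichoreMap,
    intervals: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(leading, lagging) occurrence-count tables over all 4^8 octamers.

    An occurrence is assigned to an arm by its start position; windows
    crossing an arm boundary are attributed to the arm of their start.
    """
    codes = kmer_codes(encode(genome.sequence), K, circular=genome.circular)
    arms = rmap.arm_intervals()
    if intervals is None:
        intervals = [(0, genome.length if genome.circular else len(codes))]
    w1 = _watson_table(codes, intersect_intervals(intervals, arms[1]))
    w2 = _watson_table(codes, intersect_intervals(intervals, arms[2]))
    leading = w1 + w2[_RC8]
    lagging = w1[_RC8] + w2
    return leading, lagging


def count_octamer(
    genome: Genome,
    rmap: ReplichoreMap,
    octamer: str,
    region: list[tuple[int, int]] | None = None,
) -> tuple[int, int]:
    """(n_leading, n_lagging) occurrences of a possibly degenerate octamer.

    Occurrences on both strands are counted (overlaps included, circular wrap
    included); a degenerate octamer counts as the sum over its concrete
    expansions.
    """
    lead, lag = strand_tables(genome, rmap, region)
    codes = expand_degenerate(octamer)
    return int(lead[codes].sum()), int(lag[codes].sum())


# ---------------------------------------------------------------------------
# backbone construction and null genomes

def backbone_genome(
    genome: Genome, spans: list[tuple[int, int]]
) -> tuple[Genome, list[tuple[int, int, int]]]:
    """Excise insertion spans, returning the backbone and a coordinate remap.

    Overlapping or adjacent spans are merged (with a warning when a true
    overlap is collapsed). The remap is a list of (old_start, old_end,
    new_start) for each retained block.
    """
    if not spans:
        return Genome(genome.id, genome.sequence, genome.circular), [
            (0, genome.length, 0)
        ]
    spans = sorted((int(a), int(b)) for a, b in spans)
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a < merged[-1][1]:
            warnings.warn("overlapping insertion spans merged")
            merged[-1][1] = max(merged[-1][1], b)
        elif a == merged[-1][1]:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    pieces, remap = [], []
    prev = 0
    new_pos = 0
    for a, b in merged:
        if a > prev:
            pieces.append(genome.sequence[prev:a])
            remap.append((prev, a, new_pos))
            new_pos += a - prev
        prev = b
    if prev < genome.length:
        pieces.append(genome.sequence[prev:])
        remap.append((prev, genome.length, new_pos))
    return Genome(genome.id, "".join(pieces), genome.circular), remap


def shuffle_arms(
    genome: Genome,
    rmap: ReplichoreMap,
    segment_bp: int = 40_000,
    seed: int | np.random.Generator = 0,
) -> Genome:
    """Permute fixed-size segments within each chromosome arm.

    Segments never cross arms and are never strand-flipped, so overall
    leading/lagging k-mer counts are preserved (up to windows spanning
    segment junctions) while any origin-to-terminus positional gradient is
    destroyed. An arm shorter than two segments is left intact.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = genome.sequence
    out = list(seq)
    for arm, intervals in rmap.arm_intervals().items():
        arm_seq = "".join(seq[a:b] for a, b in intervals)
        n_full = len(arm_seq) // segment_bp
        if n_full < 2:
            warnings.warn(f"arm {arm} shorter than two segments; left intact")
            continue
        segments = [
            arm_seq[i * segment_bp : (i + 1) * segment_bp] for i in range(n_full)
        ]
        tail = arm_seq[n_full * segment_bp :]
        order = rng.permutation(n_full)
        shuffled = "".join(segments[i] for i in order) + tail
        k = 0
        for a, b in intervals:
            out[a:b] = shuffled[k : k + (b - a)]
            k += b - a
    return Genome(genome.id, "".join(out), genome.circular)


# ---------------------------------------------------------------------------
# candidate scoring over the degenerate octamer space

def region_geometry(rmap: ReplichoreMap) -> dict:
    """Terminus and origin regions used by the abundance/bias criteria.

    Terminus region: ter +/- 12.5% of genome length (25% of the genome);
    origin region: ori +/- 30% (60%); the remaining 15% is a buffer belonging
    to neither.
    """
    L = rmap.length
    ter_iv = region_intervals(rmap.ter, int(round(0.125 * L)), L)
    ori_iv = region_intervals(rmap.ori, int(round(0.30 * L)), L)
    return {
        "ter": ter_iv,
        "ori": ori_iv,
        "ter_bp": sum(b - a for a, b in ter_iv),
        "ori_bp": sum(b - a for a, b in ori_iv),
    }


@dataclass
class AimsParams:
    """Detection thresholds (defaults: the calibrated operating point)."""

    min_bias: float = 0.70
    min_copies: int = 96
    # least-stringent default for the terminus density-increase criterion: a
    # genuine two-fold planted gradient, diluted by the uniform background
    # occurrence floor, measures well above a 15% per-bp increase
    min_ter_increase: float = 0.15
    bias_increase_margin: float = 0.0
    n_null: int = 100
    enrichment_fold: float = 10.0
    segment_bp: int = 40_000
    max_degenerate: int = 2
    alphabet: str = DEGENERATE_CODES  # degenerate symbols allowed


@dataclass
class AimsRecord:
    pattern: str
    n_leading: int  # N_i: leading-strand copies genome-wide
    n_lagging: int
    bias: float
    ter_density_ratio: float
    ter_bias: float
    ori_bias: float
    family: int = -1


@dataclass
class AIMSSet:
    genome_id: str
    records: list[AimsRecord]
    params: AimsParams
    null_counts: list[int] = field(default_factory=list)
    fold_enrichment: float | None = None
    fold_infinite: bool = False

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patterns(self) -> list[str]:
        return [r.pattern for r in self.records]

    def to_json(self, path) -> None:
        obj = {
            "schema": 1,
            "genome_id": self.genome_id,
            "params": vars(self.params),
            "null_counts": list(map(int, self.null_counts)),
            "fold_enrichment": self.fold_enrichment,
            "records": [vars(r) for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AIMSSet":
        with open(path) as fh:
            obj = json.load(fh)
        params = AimsParams(**obj["params"])
        recs = [AimsRecord(**r) for r in obj["records"]]
        return cls(obj["genome_id"], recs, params, obj["null_counts"],
                   obj["fold_enrichment"])


def _six_tables(genome: Genome, rmap: ReplichoreMap) -> dict:
    geo = region_geometry(rmap)
    lead_g, lag_g = strand_tables(genome, rmap)
    lead_t, lag_t = strand_tables(genome, rmap, geo["ter"])
    lead_o, lag_o = strand_tables(genome, rmap, geo["ori"])
    return {
        "lead_g": lead_g.astype(np.float64), "lag_g": lag_g.astype(np.float64),
        "lead_t": lead_t.astype(np.float64), "lag_t": lag_t.astype(np.float64),
        "lead_o": lead_o.astype(np.float64), "lag_o": lag_o.astype(np.float64),
        "ter_bp": geo["ter_bp"], "ori_bp": geo["ori_bp"],
    }


def _criteria_mask(stats: dict, p: AimsParams, ter_bp: int, ori_bp: int) -> np.ndarray:
    nl, ng = stats["lead_g"], stats["lag_g"]
    tot = nl + ng
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.where(tot > 0, nl / np.maximum(tot, 1), 0.0)
        dens_t = stats["lead_t"] / ter_bp
        dens_o = stats["lead_o"] / ori_bp
        tt = stats["lead_t"] + stats["lag_t"]
        to = stats["lead_o"] + stats["lag_o"]
        bias_t = np.where(tt > 0, stats["lead_t"] / np.maximum(tt, 1), 0.0)
        bias_o = np.where(to > 0, stats["lead_o"] / np.maximum(to, 1), 1.0)
    ok = bias >= p.min_bias
    ok &= nl >= p.min_copies
    ok &= dens_t >= (1.0 + p.min_ter_increase) * dens_o
    ok &= (tt > 0) & (to > 0)
    ok &= bias_t > bias_o + p.bias_increase_margin
    return ok


_TABLE_KEYS = ("lead_g", "lag_g", "lead_t", "lag_t", "lead_o", "lag_o")


def _scan_space(
    tables: dict,
    param_points: list[AimsParams],
    collect_for: int | None = None,
) -> tuple[np.ndarray, list[tuple[str, dict]]]:
    """Count qualifying octamers (<=2 degenerate positions) per param point.

    Returns per-point counts and, for ``collect_for``, the qualifying
    patterns with their count statistics.
    """
    p0 = param_points[0]
    deg_syms = p0.alphabet
    mdeg = _MDEG[[DEGENERATE_CODES.index(s) for s in deg_syms]]
    nd = len(deg_syms)
    counts = np.zeros(len(param_points), dtype=np.int64)
    collected: list[tuple[str, dict]] = []
    ter_bp, ori_bp = tables["ter_bp"], tables["ori_bp"]

    def handle(stats: dict, describe) -> None:
        for pi, p in enumerate(param_points):
            mask = _criteria_mask(stats, p, ter_bp, ori_bp)
            counts[pi] += int(mask.sum())
            if collect_for == pi:
                for flat in np.nonzero(mask.ravel())[0]:
                    idx = np.unravel_index(flat, mask.shape)
                    collected.append(
                        (describe(idx), {k: float(stats[k].ravel()[flat])
                                         for k in _TABLE_KEYS})
                    )

    # 0 degenerate positions
    stats0 = {k: tables[k] for k in _TABLE_KEYS}
    handle(stats0, lambda idx: string_of(int(idx[0]), K))

    reshaped = {k: tables[k].reshape([4] * K) for k in _TABLE_KEYS}

    if p0.max_degenerate >= 1:
        for i in range(K):
            stats1 = {
                k: np.tensordot(mdeg, reshaped[k], axes=([1], [i])).reshape(nd, -1)
                for k in _TABLE_KEYS
            }

            def desc1(idx, i=i):
                rest = string_of(int(idx[1]), K - 1)
                return rest[:i] + deg_syms[int(idx[0])] + rest[i:]

            handle(stats1, desc1)

    if p0.max_degenerate >= 2:
        for i in range(K):
            partial = {
                k: np.tensordot(mdeg, reshaped[k], axes=([1], [i]))
                for k in _TABLE_KEYS
            }
            # partial axes: (deg_i, then original axes with axis i removed);
            # original position j > i now sits at axis j (1-based shift cancels)
            for j in range(i + 1, K):
                stats2 = {
                    k: np.tensordot(mdeg, partial[k], axes=([1], [j])).reshape(
                        nd, nd, -1
                    )
                    for k in _TABLE_KEYS
                }

                def desc2(idx, i=i, j=j):
                    rest = string_of(int(idx[2]), K - 2)
                    s = rest[:i] + deg_syms[int(idx[1])] + rest[i:]
                    return s[:j] + deg_syms[int(idx[0])] + s[j:]

                handle(stats2, desc2)

    return counts, collected


def identify_aims(
    backbone: Genome,
    rmap: ReplichoreMap,
    params: AimsParams | None = None,
    seed: int = 0,
) -> AIMSSet:
    """Detect AIMS in a backbone genome and calibrate against arm shuffles.

    The genuine genome is scored over the full degenerate-octamer space; the
    same detector is then applied to ``params.n_null`` segment-shuffled null
    genomes and the genuine/null fold-enrichment reported.
    """
    params = params or AimsParams()
    tables = _six_tables(backbone, rmap)
    counts, collected = _scan_space(tables, [params], collect_for=0)
    records = []
    for pattern, st in collected:
        nl, ng = st["lead_g"], st["lag_g"]
        tt = st["lead_t"] + st["lag_t"]
        to = st["lead_o"] + st["lag_o"]
        dens_ratio = (st["lead_t"] / tables["ter_bp"]) / max(
            st["lead_o"] / tables["ori_bp"], 1e-300
        )
        records.append(
            AimsRecord(
                pattern=pattern,
                n_leading=int(nl),
                n_lagging=int(ng),
                bias=nl / (nl + ng),
                ter_density_ratio=dens_ratio,
                ter_bias=st["lead_t"] / tt,
                ori_bias=st["lead_o"] / to,
            )
        )
    records.sort(key=lambda r: (-r.n_leading, r.pattern))

    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(params.n_null):
        null = shuffle_arms(backbone, rmap, params.segment_bp, rng)
        ntab = _six_tables(null, rmap)
        ncount, _ = _scan_space(ntab, [params])
        null_counts.append(int(ncount[0]))
    genuine = int(counts[0])
    mean_null = float(np.mean(null_counts)) if null_counts else 0.0
    fold_infinite = mean_null == 0 and genuine > 0
    fold = float("inf") if fold_infinite else (
        genuine / mean_null if mean_null > 0 else 0.0
    )
    return AIMSSet(
        genome_id=backbone.id,
        records=records,
        params=params,
        null_counts=null_counts,
        fold_enrichment=fold,
        fold_infinite=fold_infinite,
    )


def calibrate_thresholds(
    backbone: Genome,
    rmap: ReplichoreMap,
    ter_increase_grid: list[float],
    bias_grid: list[float],
    base_params: AimsParams | None = None,
    min_genuine: int = 100,
    seed: int = 0,
) -> dict:
    """Sweep (min_ter_increase, min_bias) and pick the calibrated point.

    For every grid point the genuine AIMS count, the null mean +/- 2 SD over
    arm-shuffled genomes, and the fold-enrichment are tabulated. The chosen
    operating point is the least stringent one with fold >= the specificity
    floor and genuine count > ``min_genuine``; the most stringent qualifying
    point is also reported (abundant-but-weak vs sparse-but-strong sets).
    """
    base = base_params or AimsParams()
    points = []
    for b in sorted(bias_grid):
        for t in sorted(ter_increase_grid):
            p = AimsParams(**{**vars(base), "min_bias": b, "min_ter_increase": t})
            points.append(p)

    tables = _six_tables(backbone, rmap)
    genuine, _ = _scan_space(tables, points)

    rng = np.random.default_rng(seed)
    null = np.zeros((base.n_null, len(points)))
    for r in range(base.n_null):
        shuffled = shuffle_arms(backbone, rmap, base.segment_bp, rng)
        ntab = _six_tables(shuffled, rmap)
        null[r], _ = _scan_space(ntab, points)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if base.n_null > 1 else np.zeros(len(points))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(null_mean > 0, genuine / np.maximum(null_mean, 1e-300),
                        np.where(genuine > 0, np.inf, 0.0))

    table = [
        {
            "min_bias": p.min_bias,
            "min_ter_increase": p.min_ter_increase,
            "genuine": int(genuine[k]),
            "null_mean": float(null_mean[k]),
            "null_2sd": float(2 * null_sd[k]),
            "fold": float(fold[k]),
        }
        for k, p in enumerate(points)
    ]
    qualifying = [
        k for k in range(len(points))
        if fold[k] >= base.enrichment_fold and genuine[k] > min_genuine
    ]
    result = {"table": table, "chosen": None, "stringent": None}
    if qualifying:
        # least stringent: smallest (bias, ter_increase); most stringent: largest
        least = min(qualifying, key=lambda k: (points[k].min_bias,
                                               points[k].min_ter_increase))
        most = max(qualifying, key=lambda k: (points[k].min_bias,
                                              points[k].min_ter_increase))
        result["chosen"] = table[least]
        result["stringent"] = table[most]
    return result


# ---------------------------------------------------------------------------
# clustering

def cluster_aims(aims_set: AIMSSet) -> AIMSSet:
    """Greedy single-linkage grouping of related/overlapping octamers.

    Two octamers are linked if their concrete expansion sets intersect or a
    7-symbol prefix/suffix of one equals a suffix/prefix of the other.
    Family labels are written back onto the records (order-independent).
    """
    recs = sorted(aims_set.records, key=lambda r: r.pattern)
    n = len(recs)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    sets = [frozenset(expand_degenerate(r.pattern)) for r in recs]
    for a in range(n):
        for b in range(a + 1, n):
            pa, pb = recs[a].pattern, recs[b].pattern
            if (sets[a] & sets[b]) or pa[1:] == pb[:-1] or pb[1:] == pa[:-1]:
                union(a, b)

    roots = sorted({find(i) for i in range(n)})
    label = {r: k for k, r in enumerate(roots)}
    for i, r in enumerate(recs):
        r.family = label[find(i)]
    aims_set.records = recs
    return aims_set
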