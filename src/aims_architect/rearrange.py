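"""Arm-restricted inversion detection between closely related genome pairs.

Given the signed orders of shared orthologs in two genomes (strand encoded as
sign), an inversion is a maximal block of genes that is order-reversed and
sign-flipped in one genome relative to the other, validated by syntenic
flanking genes on both sides. Writing leading-strand genes uppercase and
lagging lowercase, genes DEF are inverted if region ABCDEFGHJ appears as
ABCfedGHJ in the sister taxon. Blocks whose span contains the replication
origin or terminus of either genome are discarded, since such inversions do
not flip replichore polarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import GeneFeature, ReplichoreMap


@dataclass
class InversionRecord:
    genes: frozenset
    pair_id: str = ""
    span_a: tuple[int, int] | None = None
    span_b: tuple[int, int] | None = None
    length_bp: float | None = None
    midpoint_a: float | None = None
    midpoint_b: float | None = None
    midpoint_mean: float | None = None
    provenance: list = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _span_of(genes: list[str], feats: dict[str, GeneFeature], length: int
             ) -> tuple[int, int]:
    """Smallest circular interval covering a set of features.

    Chooses the orientation minimising span length, so gene sets crossing
    the coordinate wrap are handled.
    """
    pts = sorted((feats[g].start, feats[g].end) for g in genes)
    starts = [p[0] for p in pts]
    ends = [p[1] for p in pts]
    # candidate: linear hull
    best = (min(starts), max(ends))
    best_len = best[1] - best[0]
    # candidate: wrap between consecutive genes (largest gap excluded)
    n = len(pts)
    for i in range(n - 1):
        gap = starts[i + 1] - ends[i]
        wrap_len = length - gap
        if 0 < gap and wrap_len < best_len:
            best = (starts[i + 1], ends[i] % length)
            best_len = wrap_len
    return best


def _contains(span: tuple[int, int], pos: int, length: int) -> bool:
    a, b = span
    if a <= b:
        return a <= pos < b
    return pos >= a or pos < b


def _span_len(span: tuple[int, int], length: int) -> int:
    a, b = span
    return (b - a) % length if a > b else b - a


def detect_inversions(
    order_a: list[tuple[str, int]],
    order_b: list[tuple[str, int]],
    map_a: ReplichoreMap | None = None,
    map_b: ReplichoreMap | None = None,
    feats_a: dict[str, GeneFeature] | None = None,
    feats_b: dict[str, GeneFeature] | None = None,
    flank_k: int = 2,
    circular: bool = True,
    pair_id: str = "",
) -> list[InversionRecord]:
    """Find maximal reversed+flipped ortholog blocks with syntenic flanks.

    ``order_a``/``order_b`` are signed gene orders over (a superset of) the
    shared orthologs; genes present in only one genome are skipped as
    transparent. Candidates need ``flank_k`` syntenic genes on each side and
    must not span ori or ter of either genome (checked when maps and feature
    dicts are supplied; otherwise records carry gene content only).
    """
    shared = {g for g, _ in order_a} & {g for g, _ in order_b}
    a = [(g, s) for g, s in order_a if g in shared]
    b = [(g, s) for g, s in order_b if g in shared]
    n = len(a)
    if n < 2 * flank_k + 1:
        warnings.warn("too few shared orthologs for inversion detection")
        return []
    pos_a = {g: i for i, (g, _) in enumerate(a)}
    sign_a = {g: s for g, s in a}

    p = np.array([pos_a[g] for g, _ in b], dtype=np.int64)
    s = np.array([sb * sign_a[g] for g, sb in b], dtype=np.int64)

    def step(x: int, y: int) -> int:
        """+1 for a syntenic step, -1 for a reversed step, 0 otherwise."""
        d = (y - x) % n if circular else y - x
        if d == 1:
            return 1
        if (circular and d == n - 1) or (not circular and d == -1):
            return -1
        return 0

    def syntenic(k: int) -> bool:
        return s[k % n] == 1 if circular else (0 <= k < n and s[k] == 1)

    def rel(k: int) -> tuple[int, int]:
        return int(p[k % n]), int(s[k % n])

    records: list[InversionRecord] = []
    seen: set[frozenset] = set()
    limit = n if circular else n
    k = 0
    while k < limit:
        if (s[k % n] if circular else s[k]) != -1:
            k += 1
            continue
        # grow a maximal reversed block from k
        end = k
        while end + 1 < k + n:
            if not circular and end + 1 >= n:
                break
            pn, sn = rel(end + 1)
            if sn == -1 and step(rel(end)[0], pn) == -1:
                end += 1
            else:
                break
        block_idx = list(range(k, end + 1))
        k_next = end + 1
        # flank validation
        ok = True
        d_first, _ = rel(block_idx[0])
        d_last, _ = rel(block_idx[-1])
        # left flank: ascending syntenic run ending at (A-index of last block gene) - 1
        prev_expected = d_last
        for f in range(1, flank_k + 1):
            kk = block_idx[0] - f
            if not circular and kk < 0:
                ok = False
                break
            pf, sf = rel(kk)
            if sf != 1 or step(pf, prev_expected) != 1:
                ok = False
                break
            prev_expected = pf
        if ok:
            next_expected = d_first
            for f in range(1, flank_k + 1):
                kk = block_idx[-1] + f
                if not circular and kk >= n:
                    ok = False
                    break
                pf, sf = rel(kk)
                if sf != 1 or step(next_expected, pf) != 1:
                    ok = False
                    break
                next_expected = pf
        if not ok:
            k = k_next
            continue

        genes_b_order = [b[i % n][0] for i in block_idx]
        sig = frozenset(genes_b_order)
        if sig in seen:
            k = k_next
            continue
        seen.add(sig)

        rec = InversionRecord(genes=sig, pair_id=pair_id,
                              provenance=[pair_id] if pair_id else [])
        if feats_a and feats_b and map_a and map_b:
            span_a = _span_of(genes_b_order, feats_a, map_a.length)
            span_b = _span_of(genes_b_order, feats_b, map_b.length)
            drop = False
            for span, rmap in ((span_a, map_a), (span_b, map_b)):
                if _contains(span, rmap.ori, rmap.length) or _contains(
                    span, rmap.ter, rmap.length
                ):
                    drop = True
            if drop:
                k = k_next
                continue
            la = _span_len(span_a, map_a.length)
            lb = _span_len(span_b, map_b.length)
            mid_a = (span_a[0] + la / 2) % map_a.length
            mid_b = (span_b[0] + lb / 2) % map_b.length
            rec.span_a, rec.span_b = span_a, span_b
            rec.length_bp = (la + lb) / 2
            rec.midpoint_a = map_a.distance_from_terminus(mid_a, clamp=False)
            rec.midpoint_b = map_b.distance_from_terminus(mid_b, clamp=False)
            rec.midpoint_mean = (rec.midpoint_a + rec.midpoint_b) / 2
        records.append(rec)
        k = k_next
    return records


def dedupe_inversions(records: list[InversionRecord]) -> list[InversionRecord]:
    """Collapse inversions with identical ortholog content across comparisons.

    The first record is kept; provenance lists are concatenated. Idempotent.
    """
    out: dict[frozenset, InversionRecord] = {}
    for rec in records:
        if rec.genes in out:
            out[rec.genes].provenance.extend(rec.provenance)
        else:
            kept = InversionRecord(**{**vars(rec)})
            kept.provenance = list(rec.provenance)
            out[rec.genes] = kept
    return list(out.values())


def positional_summary(records: list[InversionRecord], bin_pct: float = 5.0) -> dict:
    """Binned count / total inverted bp / mean size vs distance from terminus.

    Records with undefined midpoints or midpoints beyond 50% (long-arm
    excess) are dropped from the binned series. Pearson correlations of each
    series against the bin midpoint are reported, not asserted.
    """
    edges = np.arange(0.0, 50.0 + bin_pct / 2, bin_pct)
    nb = len(edges) - 1
    count = np.zeros(nb)
    total_bp = np.zeros(nb)
    for rec in records:
        if rec.midpoint_mean is None or rec.midpoint_mean > 50.0:
            continue
        i = min(int(rec.midpoint_mean / bin_pct), nb - 1)
        count[i] += 1
        total_bp[i] += rec.length_bp or 0.0
    with np.errstate(invalid="ignore"):
        mean_size = np.where(count > 0, total_bp / np.maximum(count, 1), 0.0)
    mids = (edges[:-1] + edges[1:]) / 2
    corr = {}
    for name, series in (("count", count), ("total_bp", total_bp),
                         ("mean_size", mean_size)):
        if np.std(series) > 0:
            r, pv = stats.pearsonr(mids, series)
            corr[name] = {"r": float(r), "p": float(pv)}
        else:
            corr[name] = {"r": float("nan"), "p": float("nan")}
    return {
        "bin_edges": edges.tolist(),
        "count": count.tolist(),
        "total_bp": total_bp.tolist(),
        "mean_size": mean_size.tolist(),
        "correlations": corr,
    }
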