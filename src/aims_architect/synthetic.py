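"""Synthetic circular genomes with planted architecture signals.

Every pipeline stage is exercisable without external data: the generator
emits a circular chromosome with two replichores, protein-coding genes whose
codon usage differs between leading and lagging strands (the replichore
signal the breakpoint finder detects), planted octamers whose abundance and
leading-strand bias increase linearly from origin to terminus (the AIMS
gradient), and sister genomes carrying point substitutions, arm-restricted
inversions, and foreign insertions with controllable AIMS orientation bias.
All planted truth is recorded; AIMS truth counts are recounts of the emitted
sequence, so coincidental background occurrences are included.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kmer import decode, encode, revcomp
from .aims import count_octamer, region_geometry
from .io import HOMOLOGY_COLUMNS
from .model import GeneFeature, Genome, ReplichoreMap, TruthTable

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
]
_SENSE_CODES = np.array([encode(c) for c in _SENSE])  # (61, 3)


@dataclass
class AimsPlant:
    """One octamer planted with a linear origin-to-terminus gradient.

    ``copies`` total copies are placed with per-bp density ``density_ratio``
    times higher at the terminus than at the origin; each copy is written in
    the leading orientation with probability interpolating linearly from
    ``p_ori`` (at the origin) to ``p_ter`` (at the terminus).
    """

    pattern: str
    copies: int = 200
    p_ter: float = 0.9
    p_ori: float = 0.6
    density_ratio: float = 2.0


@dataclass
class GenomeSpec:
    length: int = 2_000_000
    gc: float = 0.50
    n_genes: int = 2000
    mean_codons: int = 300
    leading_fraction: float = 0.75
    codon_bias_effect: float = 0.20  # leading/lagging codon-usage skew
    aims_plants: list[AimsPlant] = field(default_factory=list)
    genome_id: str = "synth"

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        needed = self.n_genes * (self.mean_codons * 3 + 50)
        if needed > self.length:
            raise ValueError("spec overcommitted: genes exceed genome capacity")
        for p in self.aims_plants:
            if not (0 <= p.p_ter <= 1 and 0 <= p.p_ori <= 1):
                raise ValueError("plant probabilities must be in [0, 1]")
            if p.density_ratio < 1:
                raise ValueError("density_ratio must be >= 1 (denser at terminus)")


def _codon_usage(gc: float, effect: float, leading: bool) -> np.ndarray:
    """Codon sampling weights with a leading/lagging compositional skew.

    Leading-strand genes prefer G/T-ending codons (keto skew), lagging-strand
    genes C/A-ending ones, each by a factor (1 + effect); base weights follow
    the requested GC content.
    """
    pgc = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    w = np.array([pgc[c[0]] * pgc[c[1]] * pgc[c[2]] for c in _SENSE_CODES])
    third = _SENSE_CODES[:, 2]
    keto = (third == 2) | (third == 3)  # G or T
    if leading:
        w = w * np.where(keto, 1 + effect, 1.0)
    else:
        w = w * np.where(~keto, 1 + effect, 1.0)
    return w / w.sum()


def _sample_gradient_distance(rng: np.random.Generator, n: int, ratio: float
                              ) -> np.ndarray:
    """Distances from terminus (fraction of arm, 0=ter) with linear density.

    Density is ``ratio`` at the terminus relative to 1 at the origin.
    """
    u = rng.uniform(size=n)
    if abs(ratio - 1.0) < 1e-12:
        return u
    r = ratio
    # inverse CDF of f(d) = (r - (r-1) d) / (r - (r-1)/2)
    disc = r * r - (r - 1) * (r + 1) * u
    return (r - np.sqrt(disc)) / (r - 1)


def generate_genome(
    spec: GenomeSpec, seed: int = 0
) -> tuple[Genome, list[GeneFeature], ReplichoreMap, TruthTable]:
    """Emit a synthetic genome, its features, replichore map, and truth table.

    ter sits at coordinate 0 and ori at length/2 (equal arms). Genes are laid
    out on an even grid; each is leading-strand with the configured
    probability, its codons drawn from the strand-class usage table. AIMS
    copies are written last so nothing overwrites them; their truth counts
    are recounts of the emitted sequence.
    """
    rng = np.random.default_rng(seed)
    L = spec.length
    ter, ori = 0, L // 2
    rmap = ReplichoreMap(ori=ori, ter=ter, length=L)

    pgc = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    arr = rng.choice(4, size=L, p=pgc).astype(np.uint8)

    usage = {
        True: _codon_usage(spec.gc, spec.codon_bias_effect, leading=True),
        False: _codon_usage(spec.gc, spec.codon_bias_effect, leading=False),
    }
    slot = L // spec.n_genes
    features: list[GeneFeature] = []
    for i in range(spec.n_genes):
        n_codons = int(np.clip(rng.normal(spec.mean_codons, spec.mean_codons / 5),
                               60, (slot - 20) // 3))
        start = i * slot + 10
        end = start + 3 * n_codons
        leading = rng.uniform() < spec.leading_fraction
        mid = (start + end) // 2
        # choose the strand that realises the requested strand class
        strand = 1 if (rmap.arm_of(mid) == 1) == leading else -1
        codons = rng.choice(61, size=n_codons, p=usage[leading])
        gene_arr = _SENSE_CODES[codons].reshape(-1)
        if strand == -1:
            gene_arr = (3 - gene_arr)[::-1]
        arr[start:end] = gene_arr
        features.append(GeneFeature(f"{spec.genome_id}_g{i:05d}", start, end, strand))

    truth = TruthTable(ori=ori, ter=ter)
    occupied = np.zeros(L, dtype=bool)
    injected: dict[str, list[tuple[int, int]]] = {}
    arm_len = {1: (ter - ori) % L, 2: (ori - ter) % L}
    for plant in spec.aims_plants:
        pat_f = encode(plant.pattern)
        pat_r = encode(revcomp(plant.pattern))
        placed = []
        d = _sample_gradient_distance(rng, plant.copies, plant.density_ratio)
        arms = rng.integers(1, 3, size=plant.copies)
        p_lead = plant.p_ter + (plant.p_ori - plant.p_ter) * d
        lead = rng.uniform(size=plant.copies) < p_lead
        for k in range(plant.copies):
            for _try in range(200):
                dk = d[k] if _try == 0 else rng.uniform()
                if arms[k] == 1:
                    pos = int((ter - dk * arm_len[1]) % L)
                else:
                    pos = int((ter + dk * arm_len[2]) % L)
                pos = min(pos, L - 8)
                if not occupied[pos : pos + 8].any():
                    break
            else:
                raise ValueError("spec overcommitted: no room for AIMS copy")
            watson_is_leading = rmap.arm_of(pos) == 1
            forward = pat_f if (lead[k] == watson_is_leading) else pat_r
            arr[pos : pos + 8] = forward
            occupied[pos : pos + 8] = True
            placed.append((pos, 1 if lead[k] else -1))
        injected[plant.pattern] = placed

    genome = Genome(spec.genome_id, decode(arr), circular=True)

    geo = region_geometry(rmap)
    for plant in spec.aims_plants:
        nl, ng = count_octamer(genome, rmap, plant.pattern)
        tl, tg = count_octamer(genome, rmap, plant.pattern, geo["ter"])
        ol, og = count_octamer(genome, rmap, plant.pattern, geo["ori"])
        n_inj = len(injected[plant.pattern])
        assert nl + ng >= n_inj, "emitted sequence lost planted copies"
        truth.planted_aims[plant.pattern] = {
            "injected": n_inj,
            "n_leading": nl, "n_lagging": ng,
            "ter_leading": tl, "ter_lagging": tg,
            "ori_leading": ol, "ori_lagging": og,
            "p_ter": plant.p_ter, "p_ori": plant.p_ori,
            "density_ratio": plant.density_ratio,
        }
    return genome, features, rmap, truth


# ---------------------------------------------------------------------------
# sister genomes

@dataclass
class SisterResult:
    genome: Genome
    features: list[GeneFeature]
    rmap: ReplichoreMap
    homology: pd.DataFrame
    truth: TruthTable


def signed_order(features: list[GeneFeature]) -> list[tuple[str, int]]:
    """Signed gene order (sorted by start coordinate)."""
    return [(g.gene_id, g.strand) for g in sorted(features, key=lambda f: f.start)]


def _substitute(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    hit = np.nonzero(rng.uniform(size=len(arr)) < rate)[0]
    # substitute to one of the three other bases
    arr = arr.copy()
    arr[hit] = (arr[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return arr


def derive_sister(
    genome: Genome,
    features: list[GeneFeature],
    rmap: ReplichoreMap,
    divergence: float = 0.01,
    n_inversions: int = 0,
    inversion_genes: tuple[int, int] = (2, 8),
    n_insertions: int = 0,
    insertion_genes: tuple[int, int] = (1, 3),
    insertion_aims: list[str] | None = None,
    insertion_copies: int = 30,
    p_permissive: tuple[float, float] = (0.9, 0.55),  # at ter, at ori
    seed: int = 0,
    sister_id: str | None = None,
    strain_ids: tuple[str, str] = ("strainA", "strainB"),
) -> SisterResult:
    """Derive a sister genome with substitutions, inversions, and insertions.

    Inversions reverse and strand-flip contiguous gene blocks confined to one
    arm (never spanning ori or ter, with two syntenic genes clear on each
    side). Insertions add novel random-sequence genes absent from the parent;
    when ``insertion_aims`` patterns are given, ``insertion_copies`` copies
    are written into each insertion, leading-strand with a probability that
    interpolates linearly in distance-from-terminus between ``p_permissive``
    (terminus value first). The homology table covers the parent (sister
    species) and two pseudo-strains so the insertion caller is exercisable:
    native genes are reciprocal-best everywhere, inserted genes are absent
    everywhere with best conspecific similarity drawn in [20, 35).
    """
    if divergence >= 0.1:
        raise ValueError("divergence must stay below 0.1 to preserve gene identity")
    rng = np.random.default_rng(seed)
    sister_id = sister_id or genome.id + "_sister"
    L = genome.length
    arr = _substitute(encode(genome.sequence), divergence, rng)
    feats = sorted((_copy.copy(f) for f in features), key=lambda f: f.start)
    truth = TruthTable(ori=rmap.ori, ter=rmap.ter)

    # --- inversions ------------------------------------------------------
    n = len(feats)
    used = np.zeros(n, dtype=bool)
    attempts = 0
    while sum(1 for _ in truth.planted_inversions) < n_inversions:
        attempts += 1
        if attempts > 500 * max(n_inversions, 1):
            raise ValueError("could not place all requested inversions")
        g = int(rng.integers(inversion_genes[0], inversion_genes[1] + 1))
        i = int(rng.integers(2, n - g - 2))
        j = i + g - 1
        if used[max(i - 2, 0) : min(j + 3, n)].any():
            continue
        span_a, span_b = feats[i].start - 1, feats[j].end + 1
        # block must sit inside one arm: span may not contain ori or ter
        if rmap.arm_of(span_a) != rmap.arm_of(span_b - 1):
            continue
        if ((rmap.ori - span_a) % L < span_b - span_a) or (
            (rmap.ter - span_a) % L < span_b - span_a
        ):
            continue
        used[i - 2 : j + 3] = True
        a, b = feats[i].start, feats[j].end
        arr[a:b] = (3 - arr[a:b])[::-1]
        inverted = feats[i : j + 1]
        for f in inverted:
            f.start, f.end = a + (b - f.end), a + (b - f.start)
            f.strand = -f.strand
        feats[i : j + 1] = inverted[::-1]
        truth.planted_inversions.append(
            {"genes": frozenset(f.gene_id for f in inverted),
             "span": (a, b), "n_genes": len(inverted)}
        )

    # --- insertions ------------------------------------------------------
    # choose intergenic points, then rebuild the sequence piecewise
    points = []
    if n_insertions > 0:
        gaps = [
            (feats[i].end + 2, i)
            for i in range(len(feats) - 1)
            if feats[i + 1].start - feats[i].end > 4
        ]
        if len(gaps) < n_insertions:
            raise ValueError("not enough intergenic gaps for insertions")
        for gi in rng.choice(len(gaps), size=n_insertions, replace=False):
            points.append(gaps[gi][0])
        points.sort()

    pieces = []
    new_feats: list[GeneFeature] = list(feats)
    prev = 0
    offset = 0
    fragments = []
    for point in points:
        n_new = int(rng.integers(insertion_genes[0], insertion_genes[1] + 1))
        gene_len = 3 * int(rng.integers(150, 400))
        frag_len = n_new * (gene_len + 20) + 20
        fragments.append((point, n_new, gene_len, frag_len))

    ins_meta = []
    for point, n_new, gene_len, frag_len in fragments:
        pieces.append(arr[prev:point])
        frag = rng.choice(4, size=frag_len).astype(np.uint8)
        final_start = point + offset
        # relative order of ori/ter and the insertion point is shift-invariant,
        # so the parent map gives the correct sister arm and distance
        d_pct = rmap.distance_from_terminus((point + frag_len // 2) % L, clamp=True)
        p_lead = p_permissive[0] + (p_permissive[1] - p_permissive[0]) * d_pct / 50.0
        n_perm_planted = 0
        n_placed = 0
        if insertion_aims:
            watson_is_leading = rmap.arm_of(point % L) == 1
            spots = rng.choice(frag_len - 8, size=insertion_copies, replace=False)
            spots = np.sort(spots)
            keep = np.concatenate([[True], np.diff(spots) >= 8])
            for sp in spots[keep]:
                pat = insertion_aims[int(rng.integers(len(insertion_aims)))]
                leading = rng.uniform() < p_lead
                s = pat if (leading == watson_is_leading) else revcomp(pat)
                frag[sp : sp + 8] = encode(s)
                n_perm_planted += int(leading)
                n_placed += 1
        gene_ids = []
        for gk in range(n_new):
            gs = final_start + 10 + gk * (gene_len + 20)
            gid = f"{sister_id}_hgt{len(ins_meta):03d}_{gk}"
            new_feats.append(GeneFeature(gid, gs, gs + gene_len,
                                         1 if rng.uniform() < 0.5 else -1))
            gene_ids.append(gid)
        ins_meta.append(
            {"span": (final_start, final_start + frag_len),
             "genes": gene_ids, "p_lead": float(p_lead),
             "planted_permissive": n_perm_planted, "planted_total": n_placed,
             "midpoint_pct_parent": float(d_pct)}
        )
        pieces.append(frag)
        offset += frag_len
        prev = point
    pieces.append(arr[prev:])
    new_arr = np.concatenate(pieces) if pieces else arr

    # shift native features and ori/ter past each insertion point
    shift_points = [(p, fl) for (p, _n, _g, fl) in fragments]
    for f in feats:  # native features only
        off = sum(fl for p, fl in shift_points if f.start >= p)
        f.start += off
        f.end += off
    ori_new = rmap.ori + sum(fl for p, fl in shift_points if rmap.ori >= p)
    ter_new = rmap.ter + sum(fl for p, fl in shift_points if rmap.ter >= p)

    truth.planted_insertions = ins_meta
    truth.ori, truth.ter = ori_new, ter_new

    sister = Genome(sister_id, decode(new_arr), circular=True)
    sister_map = ReplichoreMap(ori=ori_new, ter=ter_new, length=sister.length)
    all_feats = sorted(new_feats, key=lambda f: f.start)

    # --- homology table (focal genome = sister) ---------------------------
    parent_by_id = {f.gene_id: f for f in features}
    rows = []
    subjects = [genome.id, *strain_ids]
    from .replichore import coding_sequence  # local import avoids cycle at top

    for f in all_feats:
        native = f.gene_id in parent_by_id
        if native:
            pa = coding_sequence(genome, parent_by_id[f.gene_id])
            pb = coding_sequence(sister, f)
            m = min(len(pa), len(pb))
            ident = float(np.mean(encode(pa[:m]) == encode(pb[:m]))) * 100.0
            for sub in subjects:
                rows.append((f.gene_id, sub, f.gene_id, round(ident, 2), 100.0, True))
        else:
            for sub in subjects:
                rows.append(
                    (f.gene_id, sub, None, round(float(rng.uniform(20, 35)), 2),
                     float(rng.uniform(10, 40)), False)
                )
    homology = pd.DataFrame(rows, columns=HOMOLOGY_COLUMNS)
    return SisterResult(sister, all_feats, sister_map, homology, truth)
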