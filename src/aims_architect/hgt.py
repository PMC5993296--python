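"""Horizontally acquired insertions and AIMS orientation bias within them.

Foreign genes are called from homology tables: a gene is foreign when it has
no ortholog in any sister species, no ortholog in any conspecific strain, and
its closest conspecific homolog falls below a similarity threshold (absence
from multiple strains guards against scoring a parallel loss as a gain).
Runs of consecutive foreign genes merge into one insertion. Within each
insertion the recipient backbone's AIMS are enumerated in permissive
(leading-strand) and nonpermissive orientations; the resulting fraction is
binned by distance from the terminus and fitted with a decaying exponential
trend a*exp(-d/b) + c. The difference of the length-weighted mean permissive
fractions between terminus- and origin-proximal windows (equivalently, the
difference of areas under the normalized cumulative inserted-length curves)
estimates the fraction of terminus-region insertions lost to selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._kmer import encode, expand_degenerate, kmer_codes, revcomp
from .model import GeneFeature, Genome, PermissiveFraction, ReplichoreMap


@dataclass
class InsertionRecord:
    genome_id: str
    start: int
    end: int
    gene_ids: list[str]
    midpoint_pct: float | None = None
    n_permissive: int = 0
    n_nonpermissive: int = 0
    ks: float | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def permissive(self) -> PermissiveFraction:
        return PermissiveFraction(self.n_permissive, self.n_nonpermissive)


class OccurrenceIndex:
    """Sorted positions of every AIMS occurrence in a genome, by orientation.

    Built once per (genome, AIMS set) pair so that per-span permissive counts
    are two binary searches.
    """

    def __init__(self, genome: Genome, patterns: list[str], rmap: ReplichoreMap):
        codes = kmer_codes(encode(genome.sequence), 8, circular=genome.circular)
        fw: set[int] = set()
        rv: set[int] = set()
        for pat in patterns:
            fw.update(expand_degenerate(pat))
            rv.update(expand_degenerate(revcomp(pat)))
        pos_w = np.nonzero(np.isin(codes, list(fw)))[0]
        pos_c = np.nonzero(np.isin(codes, list(rv)))[0]
        lead_w = rmap.is_leading(pos_w, np.ones_like(pos_w))
        lead_c = rmap.is_leading(pos_c, -np.ones_like(pos_c))
        self.perm = np.sort(np.concatenate([pos_w[lead_w], pos_c[lead_c]]))
        self.nonperm = np.sort(np.concatenate([pos_w[~lead_w], pos_c[~lead_c]]))

    def count(self, start: int, end: int) -> tuple[int, int]:
        """(n_permissive, n_nonpermissive) occurrences starting in [start, end)."""
        np_ = int(
            np.searchsorted(self.perm, end) - np.searchsorted(self.perm, start)
        )
        nn = int(
            np.searchsorted(self.nonperm, end) - np.searchsorted(self.nonperm, start)
        )
        return np_, nn


def permissive_fraction(
    insertion: InsertionRecord,
    index: OccurrenceIndex,
) -> PermissiveFraction:
    """Fraction of AIMS occurrences within the insertion on the leading strand.

    Writes the counts back onto the record; undefined (and flagged) when the
    span contains no AIMS occurrence.
    """
    n_perm, n_non = index.count(insertion.start, insertion.end)
    insertion.n_permissive, insertion.n_nonpermissive = n_perm, n_non
    return insertion.permissive


def call_insertions(
    genome: Genome,
    genes: list[GeneFeature],
    homology: pd.DataFrame,
    sister_species: list[str],
    conspecific_strains: list[str],
    rmap: ReplichoreMap | None = None,
    sim_threshold: float = 40.0,
    min_strains: int = 2,
) -> list[InsertionRecord]:
    """Call foreign-gene insertions from a homology table.

    A gene is foreign iff it has no reciprocal-best ortholog in any sister
    species, none in any conspecific strain, and its best conspecific
    similarity is below ``sim_threshold``. Consecutive foreign genes merge
    into one insertion spanning from the start of the first to the end of the
    last (intervening intergenic DNA included).
    """
    if not sister_species:
        raise ValueError("at least one sister species required")
    if len(conspecific_strains) < min_strains:
        raise ValueError(f"at least {min_strains} conspecific strains required")
    present = set(homology["subject_genome"].unique())
    missing = (set(sister_species) | set(conspecific_strains)) - present
    if missing:
        raise ValueError(f"homology table lacks genomes: {sorted(missing)}")

    has_sub = homology["subject_gene"].notna() & (
        homology["subject_gene"].astype(str) != ""
    )
    ortho = homology[has_sub & homology["reciprocal_best"]]
    ortho_in = {
        grp: set(ortho[ortho["subject_genome"].isin(ids)]["query_gene"])
        for grp, ids in (("sister", sister_species), ("strain", conspecific_strains))
    }
    consp_hits = homology[
        has_sub & homology["subject_genome"].isin(conspecific_strains)
    ]
    best_consp = consp_hits.groupby("query_gene")["similarity"].max()

    ordered = sorted(
        (g for g in genes if g.kind == "CDS"), key=lambda g: g.start
    )
    foreign = []
    for g in ordered:
        if g.gene_id in ortho_in["sister"] or g.gene_id in ortho_in["strain"]:
            foreign.append(False)
            continue
        foreign.append(float(best_consp.get(g.gene_id, 0.0)) < sim_threshold)

    records: list[InsertionRecord] = []
    i = 0
    while i < len(ordered):
        if not foreign[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(ordered) and foreign[j + 1]:
            j += 1
        start, end = ordered[i].start, ordered[j].end
        rec = InsertionRecord(
            genome_id=genome.id,
            start=start,
            end=end,
            gene_ids=[g.gene_id for g in ordered[i : j + 1]],
        )
        if rmap is not None:
            rec.midpoint_pct = rmap.distance_from_terminus(
                (start + end) / 2, clamp=False
            )
        records.append(rec)
        i = j + 1
    return records


@dataclass
class BiasCurve:
    bin_edges: list[float]
    bin_mean: list[float]  # per-bin (length-weighted) mean permissive fraction
    bin_n: list[int]
    a: float | None = None
    b: float | None = None
    c: float | None = None
    r_squared: float | None = None


def _weighted_bin_means(
    insertions: list[InsertionRecord],
    bin_pct: float,
    min_span_bp: int,
    length_weighted: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    edges = np.arange(0.0, 50.0 + bin_pct / 2, bin_pct)
    nb = len(edges) - 1
    num = np.zeros(nb)
    den = np.zeros(nb)
    cnt = np.zeros(nb, dtype=int)
    for rec in insertions:
        pf = rec.permissive
        if (
            rec.midpoint_pct is None
            or rec.midpoint_pct > 50.0
            or not pf.defined
            or rec.length_bp < min_span_bp
        ):
            continue
        i = min(int(rec.midpoint_pct / bin_pct), nb - 1)
        w = rec.length_bp if length_weighted else 1.0
        num[i] += w * pf.value
        den[i] += w
        cnt[i] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return edges, means, cnt


def bias_curve(
    insertions: list[InsertionRecord],
    bin_pct: float = 2.0,
    min_span_bp: int = 0,
    length_weighted: bool = True,
) -> BiasCurve:
    """Permissive fraction vs distance from terminus with exponential trend fit.

    Per-bin means (length-weighted by default) are fitted with
    SB(d) = a*exp(-d/b) + c, a in [0,1], b > 0, c in [0,1], by nonlinear
    least squares. Requires >= 3 occupied bins; non-convergence returns the
    binned curve with fit parameters left unset.
    """
    edges, means, cnt = _weighted_bin_means(
        insertions, bin_pct, min_span_bp, length_weighted
    )
    curve = BiasCurve(edges.tolist(), means.tolist(), cnt.tolist())
    mids = (edges[:-1] + edges[1:]) / 2
    ok = ~np.isnan(means)
    if ok.sum() < 3:
        warnings.warn("fewer than 3 occupied bins; no fit attempted")
        return curve
    x, y = mids[ok], means[ok]

    def model(d, a, b, c):
        return a * np.exp(-d / b) + c

    ymin, ymax = float(y.min()), float(y.max())
    p0 = [max(ymax - ymin, 1e-3), 10.0, ymin]
    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0,
            bounds=([0.0, 1e-9, 0.0], [1.0, np.inf, 1.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"bias-curve fit failed: {exc}")
        return curve
    resid = y - model(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    curve.a, curve.b, curve.c = map(float, popt)
    if ss_tot > 0:
        curve.r_squared = 1.0 - float((resid**2).sum()) / ss_tot
    else:
        warnings.warn("constant input: R^2 undefined")
    return curve


def loss_fraction(
    insertions: list[InsertionRecord],
    ter_window: tuple[float, float] = (0.0, 6.0),
    ori_window: tuple[float, float] = (42.0, 48.0),
) -> dict:
    """Estimated fraction of terminus-region insertions lost to selection.

    For each positional window, F(s) is the fraction of total inserted bp in
    fragments whose permissive fraction is <= s; the loss is the difference
    of areas, integral(F_ori) - integral(F_ter), which equals the difference
    of the length-weighted mean permissive fractions. A two-sample
    Kolmogorov-Smirnov test compares the per-fragment (unweighted)
    distributions.
    """

    def window_frags(window):
        lo, hi = window
        out = [
            r for r in insertions
            if r.midpoint_pct is not None and lo <= r.midpoint_pct < hi
            and r.permissive.defined
        ]
        if not out:
            raise ValueError(f"window {window} contains no usable insertions")
        return out

    ter = window_frags(ter_window)
    ori = window_frags(ori_window)

    def wmean(frags):
        w = np.array([r.length_bp for r in frags], dtype=float)
        v = np.array([r.permissive.value for r in frags])
        return float((w * v).sum() / w.sum())

    loss = wmean(ter) - wmean(ori)
    ks = stats.ks_2samp(
        [r.permissive.value for r in ter], [r.permissive.value for r in ori]
    )
    return {
        "loss": loss,
        "ks_p": float(ks.pvalue),
        "ks_stat": float(ks.statistic),
        "n_ter": len(ter),
        "n_ori": len(ori),
        "mean_ter": wmean(ter),
        "mean_ori": wmean(ori),
        "ter_window": ter_window,
        "ori_window": ori_window,
    }


def cumulative_curve(frags: list[InsertionRecord], s_grid: np.ndarray) -> np.ndarray:
    """Normalized cumulative inserted length F(s) over a permissive-fraction grid."""
    w = np.array([r.length_bp for r in frags], dtype=float)
    v = np.array([r.permissive.value for r in frags])
    total = w.sum()
    return np.array([(w[v <= s].sum()) / total for s in s_grid])
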