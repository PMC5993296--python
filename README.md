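# aims-architect

Analysis toolkit for the strand architecture of circular bacterial
chromosomes and the constraints it places on genome rearrangement and
horizontal gene transfer (HGT).

Bacterial chromosomes replicate bidirectionally from a single origin
(*ori*) to a terminus (*ter*), splitting the chromosome into two
replichores. Short sequence motifs — **AIMS** (Architecture IMparting
Sequences), degenerate octamers exemplified by the FtsK-orienting KOPS —
accumulate on the leading strand of each replichore, and both their
abundance and their strand bias increase toward the terminus. Because an
arm-restricted inversion flips every contained motif into its nonpermissive
orientation, and because newly inserted foreign DNA arrives with its motifs
in random orientation, selection on this architecture leaves measurable
fingerprints: fewer and shorter inversions near the terminus, and an excess
of permissively oriented motifs in surviving insertions there. This package
implements the full analytical chain for detecting and quantifying those
fingerprints, plus a synthetic-genome generator so every stage can be
validated against planted ground truth.

## What it computes

- **Replichore inference** (`replichore`): candidate breakpoints are
  intergenic midpoints; for each candidate pair, protein-coding genes are
  split into putative leading/lagging classes and the frame-specific
  conditional pentamer frequencies f(B₅ | T₁₂₃₄, frame) are compared via

      Δ = Σ_frames Σ_tetramers Σ_bases (f_lead − f_lag)²

  The pair maximising Δ gives *ori*/*ter*; the breakpoint most genes are
  transcribed away from is the origin. Predicted termini can be checked
  against *dif*-site motif hits (IUPAC consensus scan with mismatches).
- **AIMS discovery** (`aims`): all octamers degenerate at ≤ 2 positions are
  scored from the 4⁸ concrete-octamer count table for (i) leading-strand
  bias, (ii) copy number, (iii) terminus-region per-bp abundance increase,
  and (iv) terminus-region bias increase. Specificity is calibrated against
  null genomes built by permuting fixed-size segments within each arm
  (strand bias preserved, positional gradient destroyed), selecting
  thresholds so genuine detections exceed the null ≥ 10-fold.
- **Inversion detection** (`rearrange`): maximal ortholog blocks that are
  order-reversed and strand-flipped between two signed gene orders, with
  syntenic flanks; blocks spanning *ori*/*ter* are excluded; positional
  summaries bin count / total bp / mean size by distance from the terminus.
- **HGT analysis** (`hgt`): foreign genes from homology tables (absent in
  sister species and conspecific strains, best conspecific similarity
  < 40%), merged into insertions; per-insertion permissive fraction of
  recipient AIMS occurrences; exponential trend fit a·e^(−d/b) + c of bias
  vs distance from the terminus; and the terminus-loss estimate — the
  difference in area under normalized cumulative inserted-length curves,
  equal to the difference of length-weighted mean permissive fractions.
- **Ter counter-selection simulation** (`tersim`): random arm-restricted
  inversions rejected when they contain a polar replication-arrest site;
  sites placed with spacing growing linearly away from the terminus.
- **Compatibility scoring** (`compat`): the strand bias of each recipient
  AIMS measured in random 10 kb donor fragments, SBᵢ = max(N_W, N_C)/(N_W +
  N_C), aggregated as C_XY = Σᵢ SB̄ᵢ·Nᵢ / Σᵢ Nᵢ — an abundance-weighted
  prediction of which donors can transfer DNA into a recipient without
  disrupting its architecture.
- **Confound controls** (`confounds`): codon-usage-bias, inverted-repeat
  spacing, and operon-length gradients vs terminus distance; NG86
  synonymous distance (Ks) as an insertion-age proxy.
- **Synthetic genomes** (`synthetic`): circular chromosomes with planted
  replichore codon skew, AIMS gradients, sister pairs with inversions and
  insertions, and exact truth tables.

## Worked example

```python
from aims_architect.synthetic import GenomeSpec, AimsPlant, generate_genome
from aims_architect.replichore import find_breakpoints
from aims_architect.aims import AimsParams, identify_aims

spec = GenomeSpec(
    length=1_000_000, n_genes=1000,
    aims_plants=[AimsPlant("ACGGTCAT", copies=300, p_ter=0.95, p_ori=0.8,
                           density_ratio=4.0)],
    genome_id="demo",
)
genome, genes, true_map, truth = generate_genome(spec, seed=42)
pred = find_breakpoints(genome, genes)
print(f"predicted ori={pred.ori} ter={pred.ter} "
      f"(planted ori={true_map.ori} ter={true_map.ter})")

result = identify_aims(
    genome, pred,
    AimsParams(min_copies=200, min_ter_increase=0.4, n_null=5), seed=0,
)
print(f"octamers detected: {len(result)}  "
      f"fold enrichment vs null: {result.fold_enrichment:.1f}")
rec = next(r for r in result.records if r.pattern == "ACGGTCAT")
print(f"planted ACGGTCAT: N_i={rec.n_leading} bias={rec.bias:.3f} "
      f"ter/ori density ratio={rec.ter_density_ratio:.2f}")
```

Output:

```
predicted ori=500999 ter=999 (planted ori=500000 ter=0)
octamers detected: 1252  fold enrichment vs null: 626.0
planted ACGGTCAT: N_i=278 bias=0.820 ter/ori density ratio=2.09
```

The breakpoint finder lands within 0.1% of the planted positions. The
detector reports the planted octamer (278 leading-strand copies, 82%
strand bias, 2.1-fold terminus enrichment) along with its degenerate
relatives — related octamers matching the same planted signal — while
arm-shuffled null genomes yield several-hundred-fold fewer detections.

A command-line interface mirrors the library
(`aims-architect --help`): `synth-genome`, `replichore-find`,
`aims-detect`, `compat-score`, `tersim-run`, and `pipeline`, which runs
every stage on a synthetic fixture and writes a checksummed manifest.

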