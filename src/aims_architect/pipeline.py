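"""End-to-end orchestration on synthetic fixtures.

Runs the stages in dependency order (replichore -> AIMS -> {inversions, HGT}
-> compatibility) on a generated genome pair and writes versioned outputs
plus a manifest (parameters, derived seeds, SHA-256 checksums). Per-stage
seeds are derived from the global seed by fixed offsets so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import aims as aims_mod
from . import compat as compat_mod
from . import hgt as hgt_mod
from . import rearrange as rearrange_mod
from . import replichore as repl_mod
from .io import ensure_dir, write_fasta, write_features, write_homology
from .synthetic import AimsPlant, GenomeSpec, derive_sister, generate_genome, signed_order

# fixed per-stage seed offsets (documented scheme: global_seed * 10 + offset)
_STAGE_OFFSET = {"genome": 0, "sister": 1, "aims": 2, "compat": 3}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 10 + _STAGE_OFFSET[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _default_plants(rng: np.random.Generator, n: int = 6) -> list[AimsPlant]:
    plants = []
    seen = set()
    while len(plants) < n:
        pat = "".join(rng.choice(list("ACGT"), size=8))
        if pat in seen:
            continue
        seen.add(pat)
        plants.append(AimsPlant(pat, copies=120, p_ter=0.95, p_ori=0.75,
                                density_ratio=2.0))
    return plants


def run_pipeline(
    seed: int,
    outdir,
    genome_length: int = 400_000,
    n_genes: int = 400,
    mean_codons: int = 200,
    n_null: int = 3,
    n_fragments: int = 300,
) -> dict:
    """Full synthetic run; returns the manifest (also written to manifest.json)."""
    out = ensure_dir(outdir)
    manifest: dict = {
        "seed": seed,
        "parameters": {
            "genome_length": genome_length, "n_genes": n_genes,
            "n_null": n_null, "n_fragments": n_fragments,
        },
        "stage_seeds": {s: _stage_seed(seed, s) for s in _STAGE_OFFSET},
        "artifacts": {},
    }

    rng = np.random.default_rng(_stage_seed(seed, "genome"))
    spec = GenomeSpec(
        length=genome_length, n_genes=n_genes, mean_codons=mean_codons,
        aims_plants=_default_plants(rng), genome_id="pipe",
    )
    genome, feats, true_map, truth = generate_genome(spec, _stage_seed(seed, "genome"))
    write_fasta([genome], out / "genome.fasta")
    write_features(feats, out / "genome.gff3", seqid=genome.id)

    rmap = repl_mod.find_breakpoints(genome, feats)
    (out / "replichore.json").write_text(json.dumps({
        "ori": rmap.ori, "ter": rmap.ter, "delta": rmap.delta,
        "low_confidence": rmap.low_confidence,
        "true_ori": true_map.ori, "true_ter": true_map.ter,
    }, sort_keys=True, indent=1))

    params = aims_mod.AimsParams(min_copies=60, n_null=n_null)
    aims_set = aims_mod.identify_aims(genome, rmap, params,
                                      seed=_stage_seed(seed, "aims"))
    aims_mod.cluster_aims(aims_set)
    aims_set.to_json(out / "aims.json")

    sister = derive_sister(
        genome, feats, true_map,
        divergence=0.005, n_inversions=5, n_insertions=8,
        insertion_aims=[p.pattern for p in spec.aims_plants],
        seed=_stage_seed(seed, "sister"),
    )
    write_fasta([sister.genome], out / "sister.fasta")
    write_features(sister.features, out / "sister.gff3", seqid=sister.genome.id)
    write_homology(sister.homology, out / "homology.tsv")

    native = {f.gene_id for f in feats}
    inversions = rearrange_mod.detect_inversions(
        signed_order(feats), signed_order(sister.features),
        map_a=true_map, map_b=sister.rmap,
        feats_a={f.gene_id: f for f in feats},
        feats_b={f.gene_id: f for f in sister.features if f.gene_id in native},
        pair_id=f"{genome.id}:{sister.genome.id}",
    )
    with open(out / "inversions.tsv", "w") as fh:
        fh.write("pair\tn_genes\tlength_bp\tmidpoint_pct\tgenes\n")
        for rec in sorted(inversions, key=lambda r: sorted(r.genes)[0]):
            fh.write(
                f"{rec.pair_id}\t{rec.n_genes}\t{rec.length_bp}\t"
                f"{rec.midpoint_mean}\t{','.join(sorted(rec.genes))}\n"
            )

    insertions = hgt_mod.call_insertions(
        sister.genome, sister.features, sister.homology,
        sister_species=[genome.id], conspecific_strains=["strainA", "strainB"],
        rmap=sister.rmap,
    )
    index = hgt_mod.OccurrenceIndex(sister.genome, aims_set.patterns, sister.rmap)
    for rec in insertions:
        hgt_mod.permissive_fraction(rec, index)
    with open(out / "insertions.tsv", "w") as fh:
        fh.write("genome\tstart\tend\tn_genes\tmidpoint_pct\t"
                 "n_permissive\tn_nonpermissive\n")
        for rec in insertions:
            fh.write(f"{rec.genome_id}\t{rec.start}\t{rec.end}\t{rec.n_genes}\t"
                     f"{rec.midpoint_pct}\t{rec.n_permissive}\t"
                     f"{rec.n_nonpermissive}\n")

    # compatibility on the most abundant AIMS
    top = aims_mod.AIMSSet(
        aims_set.genome_id,
        sorted(aims_set.records, key=lambda r: -r.n_leading)[:40],
        aims_set.params,
    )
    score = compat_mod.compatibility(
        top, sister.genome, n_fragments=n_fragments,
        seed=_stage_seed(seed, "compat"),
    )
    (out / "compatibility.json").write_text(json.dumps({
        "recipient": score.recipient_id, "donor": score.donor_id,
        "C": score.value, "n_informative_aims": score.n_informative_aims,
    }, sort_keys=True, indent=1))

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest["artifacts"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
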