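"""Readers and writers for the file formats the pipeline touches.

External dialects (FASTA, GFF3, feature TSV, homology TSV) are converted at
this boundary to the internal convention: 0-based half-open coordinates,
strand in {+1, -1}, uppercase sequences.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .model import GeneFeature, Genome

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

HOMOLOGY_COLUMNS = [
    "query_gene",
    "subject_genome",
    "subject_gene",
    "similarity",
    "coverage",
    "reciprocal_best",
]


def read_fasta(path, circular: bool = True) -> list[Genome]:
    """Read all records of a FASTA file as Genome objects.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped to N
    with a warning.
    """
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID:
            n_bad = sum(c not in _VALID for c in seq)
            logger.warning("%s: %d non-ACGTN characters mapped to N", rec.id, n_bad)
            seq = "".join(c if c in _VALID else "N" for c in seq)
        genomes.append(Genome(id=rec.id, sequence=seq, circular=circular))
    if not genomes:
        raise ValueError(f"{path}: no FASTA records found")
    return genomes


def write_fasta(genomes: list[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def _strand_to_int(sym: str) -> int:
    if sym in ("+", "+1", "1"):
        return 1
    if sym in ("-", "-1"):
        return -1
    raise ValueError(f"strand required, got {sym!r}")


def read_features(path, dialect: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based inclusive) or 4-column TSV.

    The TSV dialect has columns gene_id, start, end, strand with 1-based
    inclusive coordinates, matching common annotation tables. Records with
    end < start or missing strand are rejected with a warning.
    """
    feats: list[GeneFeature] = []
    if dialect == "gff3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
            dtype={"start": "Int64", "end": "Int64"},
        )
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                strand = _strand_to_int(str(row.strand))
            except ValueError:
                warnings.warn(f"{path}:{i}: feature without strand rejected")
                continue
            start, end = int(row.start) - 1, int(row.end)
            if end <= start:
                warnings.warn(f"{path}:{i}: end < start, record rejected")
                continue
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("locus_tag") or f"feat{i}"
            kind = row.type if row.type in ("CDS", "rRNA", "tRNA") else "other"
            feats.append(GeneFeature(gid, start, end, strand, kind=kind))
    elif dialect == "tsv":
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         names=["gene_id", "start", "end", "strand"])
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                strand = _strand_to_int(str(row.strand))
            except ValueError:
                warnings.warn(f"{path}:{i}: feature without strand rejected")
                continue
            start, end = int(row.start) - 1, int(row.end)
            if end <= start:
                warnings.warn(f"{path}:{i}: end < start, record rejected")
                continue
            feats.append(GeneFeature(str(row.gene_id), start, end, strand))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return feats


def write_features(feats: list[GeneFeature], path, dialect: str = "gff3",
                   seqid: str = "chr") -> None:
    """Write features back out; inverse of :func:`read_features`."""
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in feats:
                strand = "+" if f.strand == 1 else "-"
                fh.write(
                    f"{seqid}\taims_architect\t{f.kind if f.kind != 'other' else 'gene'}"
                    f"\t{f.start + 1}\t{f.end}\t.\t{strand}\t.\tID={f.gene_id}\n"
                )
        elif dialect == "tsv":
            for f in feats:
                strand = "+" if f.strand == 1 else "-"
                fh.write(f"{f.gene_id}\t{f.start + 1}\t{f.end}\t{strand}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_homology(path) -> pd.DataFrame:
    """Read a homology table (TSV with header) and validate its ranges.

    Columns: query_gene, subject_genome, subject_gene (empty = absent),
    similarity and coverage in [0, 100], reciprocal_best boolean.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(HOMOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: homology table missing columns {sorted(missing)}")
    for col in ("similarity", "coverage"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{path}: {col} outside [0, 100]")
    df["reciprocal_best"] = df["reciprocal_best"].astype(bool)
    rb = df[df["reciprocal_best"] & df["subject_gene"].notna()]
    dup = rb.duplicated(subset=["query_gene", "subject_genome"])
    if dup.any():
        raise ValueError(f"{path}: multiple reciprocal-best subjects for one query")
    return df


def write_homology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=HOMOLOGY_COLUMNS)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
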