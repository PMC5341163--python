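"""Readers and writers for the pipeline's on-disk formats.

FASTA and FASTQ go through Biopython; GFF3 (1-based inclusive), BedGraph
(0-based half-open on disk, converted at the boundary) and the various TSV
tables are thin line formats written and read here directly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotationRecord, CoverageTrack, GenomeModel, SrnaInterval

GFF3_TYPE_BY_CLASS = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
GFF3_TYPE_BY_CATEGORY = {"ncRNA": "ncRNA", "asRNA": "antisense_RNA", "UTR": "UTR"}
_CATEGORY_BY_TYPE = {v: k for k, v in GFF3_TYPE_BY_CATEGORY.items()}


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeModel, path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.replicons]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> GenomeModel:
    replicons = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    if not replicons:
        raise ValueError(f"no sequences in {path}")
    return GenomeModel(replicons)


# ---------------------------------------------------------------- FASTQ

@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]  # phred scores, one per base

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def write_fastq(reads: list[FastqRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path: str | os.PathLike) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq).upper(), quals))
    return out


# ----------------------------------------------------------------- GFF3

def write_annotation_gff3(records: list[AnnotationRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = f"ID={r.gene_id}"
            fh.write(
                f"{r.replicon}\tsrna_seeker\t{GFF3_TYPE_BY_CLASS[r.feature_class]}\t"
                f"{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_annotation_gff3(path: str | os.PathLike) -> list[AnnotationRecord]:
    out = []
    class_by_type = {v: k for k, v in GFF3_TYPE_BY_CLASS.items()}
    for fields in _gff3_rows(path):
        ftype = fields[2]
        if ftype not in class_by_type:
            continue
        attrs = _parse_attrs(fields[8])
        out.append(
            AnnotationRecord(
                gene_id=attrs.get("ID", f"{fields[0]}:{fields[3]}-{fields[4]}"),
                replicon=fields[0],
                start=int(fields[3]),
                end=int(fields[4]),
                strand=fields[6] if fields[6] in "+-" else "+",
                feature_class=class_by_type[ftype],
            )
        )
    return out


def write_srna_gff3(srnas: list[SrnaInterval], path: str | os.PathLike) -> None:
    """Called sRNAs as GFF3; support/repeat status and any external labels ride as attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for s in srnas:
            attrs = [f"ID={s.id}", f"support={s.support}",
                     f"repeat_flag={'true' if s.repeat_flag else 'false'}"]
            for k in sorted(s.annotations):
                attrs.append(f"{k}={s.annotations[k]}")
            ftype = GFF3_TYPE_BY_CATEGORY.get(s.category or "ncRNA", "ncRNA")
            fh.write(
                f"{s.replicon}\tsrna_seeker\t{ftype}\t{s.start}\t{s.end}\t.\t.\t.\t"
                + ";".join(attrs) + "\n"
            )


def read_srna_gff3(path: str | os.PathLike) -> list[SrnaInterval]:
    out = []
    for fields in _gff3_rows(path):
        attrs = _parse_attrs(fields[8])
        extra = {k: v for k, v in attrs.items() if k not in ("ID", "support", "repeat_flag")}
        out.append(
            SrnaInterval(
                id=attrs["ID"],
                replicon=fields[0],
                start=int(fields[3]),
                end=int(fields[4]),
                category=_CATEGORY_BY_TYPE.get(fields[2]),
                support=int(attrs.get("support", 0)),
                repeat_flag=attrs.get("repeat_flag", "false") == "true",
                annotations=extra,
            )
        )
    return out


def _gff3_rows(path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            yield fields


def _parse_attrs(text: str) -> dict:
    out = {}
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


# -------------------------------------------------------------- BedGraph

def write_bedgraph(tracks: list[CoverageTrack], path: str | os.PathLike) -> None:
    """Run-length encoded; disk coordinates are 0-based half-open per the format."""
    with open(path, "w") as fh:
        sid = tracks[0].sample_id if tracks else ""
        fh.write(f'track type=bedGraph name="{sid}"\n')
        for t in tracks:
            d = t.depth
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                v = d[s]
                if v != 0:
                    fh.write(f"{t.replicon}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path: str | os.PathLike, replicon_lengths: dict[str, int],
                  sample_id: str = "", normalized: bool = False) -> list[CoverageTrack]:
    depths = {name: np.zeros(n) for name, n in replicon_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            rep, s, e, v = line.split("\t")
            if rep not in depths:
                raise ValueError(f"unknown replicon {rep!r} in {path}")
            depths[rep][int(s):int(e)] = float(v)
    return [CoverageTrack(name, depths[name], sample_id=sample_id, normalized=normalized)
            for name in replicon_lengths]


# ------------------------------------------------------------------- TSV

def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    # leading '# config_hash=...' comment lines from the pipeline are skipped
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def write_srna_table(srnas: list[SrnaInterval], annotation: list[AnnotationRecord],
                     path: str | os.PathLike) -> None:
    """Catalog table: id, location, flanking genes and distances, category, support."""
    rows = []
    for s in srnas:
        up, up_d, down, down_d = _flanking_genes(s, annotation)
        rows.append({
            "id": s.id, "replicon": s.replicon, "start": s.start, "end": s.end,
            "length": s.length, "category": s.category, "support": s.support,
            "repeat_flag": s.repeat_flag,
            "gene_5prime": up, "distance_5prime": up_d,
            "gene_3prime": down, "distance_3prime": down_d,
        })
    write_tsv(pd.DataFrame(rows), path)


def _flanking_genes(s: SrnaInterval, annotation: list[AnnotationRecord]):
    same = [a for a in annotation if a.replicon == s.replicon]
    left = [(s.start - a.end, a.gene_id) for a in same if a.end < s.start]
    right = [(a.start - s.end, a.gene_id) for a in same if a.start > s.end]
    up = min(left) if left else (None, "")
    down = min(right) if right else (None, "")
    return up[1], up[0] if left else "", down[1], down[0] if right else ""
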