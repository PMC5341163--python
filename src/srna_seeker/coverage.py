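"""Read mapping, per-nucleotide coverage, structural-RNA masking and
library-size normalization.

The mapper places reads by exact full-length match only; sequencing-error
tolerance comes from an iterative loop that trims the lower-quality terminal
base of an unmapped read and retries, up to 50 cycles, discarding reads that
would fall below 50 nt.  Reads matching at several loci are placed at every
match; the discovery stage's repeat flag compensates downstream.  The library
is unstranded, so a read is matched against both the forward sequence and its
reverse complement and only the forward-coordinate placement is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationRecord, CoverageTrack, GenomeModel, MappedRead
from .io import FastqRead

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SEED_K = 20


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIndex:
    """Exact-match lookup over all replicons via a k-mer seed table.

    Seeds are the leading SEED_K-mers of genome positions; a query is
    verified by direct string comparison at each seed hit, on both strands.
    """

    def __init__(self, genome: GenomeModel, k: int = SEED_K):
        if genome.total_length == 0:
            raise ValueError("empty genome")
        self.genome = genome
        self.k = k
        self._seeds: dict[str, list[tuple[int, int]]] = {}
        for ri, (_, seq) in enumerate(genome.replicons):
            for pos in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[pos : pos + k], []).append((ri, pos))

    def find_exact(self, query: str) -> list[tuple[str, int]]:
        """All loci (replicon, 1-based start) whose forward sequence equals
        the query on either strand.  Sorted, deduplicated."""
        hits: set[tuple[int, int]] = set()
        for q in (query, revcomp(query)):
            if len(q) >= self.k:
                for ri, pos in self._seeds.get(q[: self.k], ()):
                    seq = self.genome.replicons[ri][1]
                    if seq[pos : pos + len(q)] == q:
                        hits.add((ri, pos))
            else:  # shorter than a seed: fall back to a direct scan
                for ri, (_, seq) in enumerate(self.genome.replicons):
                    at = seq.find(q)
                    while at != -1:
                        hits.add((ri, at))
                        at = seq.find(q, at + 1)
        return [(self.genome.replicons[ri][0], pos + 1) for ri, pos in sorted(hits)]


@dataclass
class MappingSummary:
    """Per-sample accounting of the trim-and-remap loop."""

    reads_in: int = 0
    reads_mapped: int = 0
    reads_trimmed: int = 0  # mapped only after >= 1 trim
    reads_dropped: int = 0
    placements: int = 0

    @property
    def mapping_ratio(self) -> float:
        return self.reads_mapped / self.reads_in if self.reads_in else 0.0

    def as_dict(self) -> dict:
        return {
            "reads_in": self.reads_in, "reads_mapped": self.reads_mapped,
            "reads_trimmed": self.reads_trimmed, "reads_dropped": self.reads_dropped,
            "placements": self.placements, "mapping_ratio": round(self.mapping_ratio, 6),
        }


def _trim_lower_quality_end(seq: str, quals: tuple[int, ...]) -> tuple[str, tuple[int, ...]]:
    # ties go to the 3' end: terminal-cycle errors concentrate there
    if quals[0] < quals[-1]:
        return seq[1:], quals[1:]
    return seq[:-1], quals[:-1]


def map_reads_iterative(
    reads: list[FastqRead],
    genome: GenomeModel | GenomeIndex,
    min_len: int = 50,
    max_cycles: int = 50,
) -> tuple[list[MappedRead], MappingSummary]:
    """Map each read at its first exact full-length match, trimming the
    lower-quality terminal base and retrying on failure.

    A read is dropped once trimming would take it below ``min_len`` or after
    ``max_cycles`` trims.  Multi-mapping reads are placed at every matching
    locus rather than discarded.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    mapped: list[MappedRead] = []
    summary = MappingSummary(reads_in=len(reads))
    for read in reads:
        seq, quals = read.sequence, read.qualities
        placed = False
        for cycle in range(max_cycles + 1):
            if len(seq) < min_len:
                break
            hits = index.find_exact(seq)
            if hits:
                for rep, start in hits:
                    mapped.append(MappedRead(read.read_id, rep, start, len(seq), cycle))
                summary.placements += len(hits)
                summary.reads_mapped += 1
                if cycle > 0:
                    summary.reads_trimmed += 1
                placed = True
                break
            if cycle == max_cycles or len(seq) - 1 < min_len:
                break
            seq, quals = _trim_lower_quality_end(seq, quals)
        if not placed:
            summary.reads_dropped += 1
    return mapped, summary


def map_reads_fullscan(reads: list[FastqRead], genome: GenomeModel) -> list[MappedRead]:
    """Naive exact matcher (no trimming): every full-length match on either
    strand, found by scanning each replicon.  Reference oracle for the
    indexed mapper on uncorrupted reads."""
    if genome.total_length == 0:
        raise ValueError("empty genome")
    out = []
    for read in reads:
        hits = set()
        for q in (read.sequence, revcomp(read.sequence)):
            for name, seq in genome.replicons:
                at = seq.find(q)
                while at != -1:
                    hits.add((name, at + 1))
                    at = seq.find(q, at + 1)
        for name, start in sorted(hits):
            out.append(MappedRead(read.read_id, name, start, len(read.sequence), 0))
    return out


def compute_coverage(
    mapped_reads: list[MappedRead], genome: GenomeModel, sample_id: str = ""
) -> list[CoverageTrack]:
    """depth[i] = number of mapped reads whose span covers nucleotide i."""
    diffs = {name: np.zeros(genome.length(name) + 1) for name in genome.names}
    for r in mapped_reads:
        d = diffs[r.replicon]
        if r.end > len(d) - 1:
            raise ValueError(f"read {r.read_id} span {r.start}..{r.end} exceeds {r.replicon}")
        d[r.start - 1] += 1
        d[r.end] -= 1
    return [
        CoverageTrack(name, np.cumsum(diffs[name][:-1]), sample_id=sample_id)
        for name in genome.names
    ]


def mask_structural_rna(
    tracks: list[CoverageTrack], annotation: list[AnnotationRecord]
) -> list[CoverageTrack]:
    """Zero out coverage inside rRNA/tRNA records (for totaling purposes);
    the caller keeps the unmasked tracks separately."""
    masked = [t.copy() for t in tracks]
    by_rep = {t.replicon: t for t in masked}
    for rec in annotation:
        if rec.feature_class in ("rRNA", "tRNA") and rec.replicon in by_rep:
            t = by_rep[rec.replicon]
            t.depth[rec.start - 1 : rec.end] = 0.0
    return masked


def masked_total(tracks: list[CoverageTrack], annotation: list[AnnotationRecord]) -> float:
    return float(sum(t.depth.sum() for t in mask_structural_rna(tracks, annotation)))


def normalize_to_total(
    tracks: list[CoverageTrack],
    annotation: list[AnnotationRecord],
    target_total: float = 100_000_000,
) -> tuple[list[CoverageTrack], float]:
    """Scale one sample's tracks so the rRNA/tRNA-excluded total equals
    ``target_total`` mapped bases.  Every position is scaled, including
    positions inside masked records."""
    total = masked_total(tracks, annotation)
    if total == 0:
        raise ValueError("no usable coverage: masked total is zero")
    factor = target_total / total
    out = []
    for t in tracks:
        nt = t.copy()
        nt.depth = nt.depth * factor
        nt.normalized = True
        out.append(nt)
    return out, factor
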