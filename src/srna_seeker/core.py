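"""Shared domain types for the sRNA discovery pipeline.

Coordinates are 1-based inclusive everywhere at module interfaces (the
GFF3 convention); internal numpy arrays are 0-indexed but that is never
visible from outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

VALID_ALPHABET = frozenset("ACGT")
FEATURE_CLASSES = ("CDS", "rRNA", "tRNA")
SRNA_CATEGORIES = ("ncRNA", "asRNA", "UTR")

CONDITIONS = ("control", "ethanol", "butanol", "hexane", "salt", "Nstarve")
TIMEPOINTS = (24, 48, 72)


def sample_ids() -> list[str]:
    """The 18 sample identifiers: 6 conditions x 3 time points."""
    return [f"{c}_{t}h" for c in CONDITIONS for t in TIMEPOINTS]


@dataclass(frozen=True)
class GenomeModel:
    """A multi-replicon genome: ordered (name, sequence) pairs."""

    replicons: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [n for n, _ in self.replicons]
        if len(set(names)) != len(names):
            raise ValueError("replicon names must be unique")
        for name, seq in self.replicons:
            if not seq:
                raise ValueError(f"replicon {name!r} has empty sequence")
            if not set(seq) <= VALID_ALPHABET:
                bad = sorted(set(seq) - VALID_ALPHABET)
                raise ValueError(f"replicon {name!r} contains non-ACGT symbols: {bad}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.replicons)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.replicons]

    def sequence(self, replicon: str) -> str:
        for name, seq in self.replicons:
            if name == replicon:
                return seq
        raise KeyError(replicon)

    def length(self, replicon: str) -> int:
        return len(self.sequence(replicon))


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated gene (CDS, rRNA or tRNA), 1-based inclusive."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str  # '+' or '-'
    feature_class: str  # CDS | rRNA | tRNA

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.gene_id}: invalid span {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def validate_annotation(records: list[AnnotationRecord], genome: GenomeModel | None = None) -> None:
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("gene_ids must be unique")
    if genome is not None:
        for r in records:
            if r.end > genome.length(r.replicon):
                raise ValueError(f"{r.gene_id} extends past end of {r.replicon}")


@dataclass
class CoverageTrack:
    """Per-nucleotide unstranded read coverage of one replicon.

    ``depth[i-1]`` holds the coverage depth s_i at (1-based) nucleotide i.
    Raw tracks hold integers; normalized tracks hold reals.
    """

    replicon: str
    depth: np.ndarray
    sample_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if np.any(self.depth < 0):
            raise ValueError("depths must be nonnegative")

    def __len__(self) -> int:
        return int(self.depth.shape[0])

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depths over [start, end], 1-based inclusive."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(f"span {start}..{end} outside replicon of length {len(self)}")
        return self.depth[start - 1 : end]

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(self.replicon, self.depth.copy(), self.sample_id, self.normalized)


@dataclass(frozen=True)
class MappedRead:
    """A read placed on the genome after the trim-and-remap loop."""

    read_id: str
    replicon: str
    start: int  # 1-based
    length: int
    trims_applied: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("mapped read length must be positive")
        if not (0 <= self.trims_applied <= 50):
            raise ValueError("trims_applied must be within 0..50")

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SrnaInterval:
    """A called sRNA candidate with category, support and boundaries."""

    id: str
    replicon: str
    start: int
    end: int
    category: str | None = None  # ncRNA | asRNA | UTR
    support: int = 0
    repeat_flag: bool = False
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.id}: invalid span {self.start}..{self.end}")
        if self.category is not None and self.category not in SRNA_CATEGORIES:
            raise ValueError(f"{self.id}: unknown category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, start: int, end: int) -> int:
        """Number of shared positions with [start, end]."""
        return max(0, min(self.end, end) - max(self.start, start) + 1)

    def replaced(self, **kw) -> "SrnaInterval":
        out = _dc_replace(self)
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass(frozen=True)
class PlantedFeature:
    """Ground truth for a synthetic sRNA inserted by the generator."""

    replicon: str
    start: int
    end: int
    true_category: str
    per_sample_mean_depth: tuple[float, ...]
    trend_group: int = 0
    feature_id: str = ""

    def __post_init__(self):
        if self.true_category not in SRNA_CATEGORIES:
            raise ValueError(f"unknown category {self.true_category!r}")
        if any(d < 0 for d in self.per_sample_mean_depth):
            raise ValueError("depths must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DetectionParams:
    """Tunable thresholds of the discovery stage (defaults follow the study design)."""

    depth_threshold: float = 50.0  # normalized depth, x-fold
    min_length: int = 50  # bp
    min_support: int = 3  # samples out of 18
    merge_gap: int = 50  # bp
    utr_upstream: int = 100  # nt
    utr_downstream: int = 50  # nt
    rescue_flank: int = 50  # bp
    rescue_ratio: float = 2.0
    refine_window: int = 20  # nt, boundary search half-width
    jaccard_support: float = 0.5

    def __post_init__(self):
        for name in ("depth_threshold", "min_length", "min_support", "merge_gap",
                     "utr_upstream", "utr_downstream", "rescue_flank", "rescue_ratio",
                     "refine_window", "jaccard_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
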