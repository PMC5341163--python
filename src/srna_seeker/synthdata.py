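"""Synthetic study generator.

Emulates, at desk scale, the shape of a multi-replicon cyanobacterial
sRNA-seq study: a small genome with annotated CDS / rRNA-operon / tRNA
features, planted intergenic (ncRNA), antisense (asRNA) and UTR-proximal
sRNAs with condition-dependent expression over 6 conditions x 3 time points
(18 samples), unstranded short reads with a terminal-base corruption model
that exercises the mapper's trim loop, negative-binomial count fixtures for
the differential-expression stage, and target-prediction / pathway /
transcriptome tables with planted pathway enrichment for the network stage.

Everything regenerates bit-identically from one integer seed: every stage
derives its generator from a `numpy.random.SeedSequence` spawned off the
study seed in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CONDITIONS,
    AnnotationRecord,
    GenomeModel,
    PlantedFeature,
    sample_ids,
)
from .io import FastqRead

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ------------------------------------------------------------------ genome

def make_genome(
    sizes: dict[str, int] | None = None, gc: float = 0.48, seed: int = 0
) -> GenomeModel:
    """Random genome with the requested replicon sizes and GC content.

    Defaults to one 100 kb chromosome plus one 10 kb plasmid."""
    if sizes is None:
        sizes = {"chromosome": 100_000, "plasmid1": 10_000}
    if not (0 < gc < 1):
        raise ValueError("GC content must be in (0, 1)")
    for name, n in sizes.items():
        if n <= 0:
            raise ValueError(f"replicon {name!r} has nonpositive size")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    replicons = tuple(
        (name, "".join(rng.choice(BASES, size=n, p=p))) for name, n in sizes.items()
    )
    return GenomeModel(replicons)


def make_annotation(
    genome: GenomeModel,
    n_genes: int = 60,
    n_rrna_operons: int = 2,
    n_trna: int = 5,
    seed: int = 0,
) -> list[AnnotationRecord]:
    """Lay genes end to end with random intergenic gaps.

    CDS lengths ~U(600, 1200), gaps ~U(500, 900) so intergenic sRNAs are
    plantable; rRNA operons are 4.5 kb blocks and tRNAs 80 nt, all placed on
    the first replicon; remaining genes spill onto later replicons when the
    first fills up.
    """
    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    plan: list[tuple[str, int]] = []
    for i in range(n_rrna_operons):
        plan.append(("rRNA", 4500))
    for i in range(n_trna):
        plan.append(("tRNA", 80))
    for i in range(n_genes):
        plan.append(("CDS", int(rng.integers(600, 1201))))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    counters = {"CDS": 0, "rRNA": 0, "tRNA": 0}
    prefix = {"CDS": "gene", "rRNA": "rrn", "tRNA": "trn"}
    rep_idx = 0
    pos = int(rng.integers(400, 800))
    for fclass, length in plan:
        while rep_idx < len(genome.replicons):
            rep_name = genome.names[rep_idx]
            rep_len = genome.length(rep_name)
            if pos + length - 1 <= rep_len - 400:
                break
            rep_idx += 1
            pos = int(rng.integers(400, 800))
        if rep_idx >= len(genome.replicons):
            break  # genome full; stop placing
        counters[fclass] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            AnnotationRecord(
                gene_id=f"{prefix[fclass]}{counters[fclass]:03d}",
                replicon=genome.names[rep_idx],
                start=pos,
                end=pos + length - 1,
                strand=strand,
                feature_class=fclass,
            )
        )
        pos += length + int(rng.integers(500, 901))
    return records


# ---------------------------------------------------------------- planting

@dataclass
class PlantPlan:
    """How many sRNAs of each category to plant, and their expression."""

    n_ncrna: int = 20
    n_asrna: int = 10
    n_utr: int = 10
    n_decoys: int = 5  # sub-threshold intergenic features
    length_range: tuple[int, int] = (60, 100)
    baseline_depth: tuple[float, float] = (150.0, 300.0)
    effect_range: tuple[float, float] = (1.5, 2.5)  # condition-specific up-shift
    decoy_depth: float = 20.0
    n_condition_specific: int = 1  # expressed in one condition only (e.g. salt)
    min_feature_gap: int = 200  # keeps planted features from merging

    @property
    def n_true(self) -> int:
        return self.n_ncrna + self.n_asrna + self.n_utr


def plant_features(
    genome: GenomeModel,
    annotation: list[AnnotationRecord],
    plan: PlantPlan | None = None,
    seed: int = 0,
    utr_upstream: int = 100,
    utr_downstream: int = 50,
) -> list[PlantedFeature]:
    """Choose ground-truth sRNA intervals consistent with their category.

    ncRNAs sit >= 101 nt from every gene boundary; UTR features lie inside a
    gene's strand-aware 100 nt-upstream / 50 nt-downstream window without
    touching any gene body; asRNAs lie wholly inside a CDS body.  Decoys are
    intergenic features at sub-threshold depth.  Raises if the genome is too
    crowded to satisfy the request.
    """
    plan = plan or PlantPlan()
    rng = np.random.default_rng(seed)
    n_samples = len(sample_ids())
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in genome.names}

    def free(rep: str, s: int, e: int) -> bool:
        return all(
            e + plan.min_feature_gap < os or s - plan.min_feature_gap > oe
            for os, oe in occupied[rep]
        )

    genes = [a for a in annotation if a.replicon in genome.names]

    def far_from_genes(rep: str, s: int, e: int, margin: int) -> bool:
        for g in genes:
            if g.replicon != rep:
                continue
            if not (e < g.start - margin or s > g.end + margin):
                return False
        return True

    features: list[PlantedFeature] = []

    def depth_profile(kind: str, idx: int) -> tuple[tuple[float, ...], int]:
        if kind == "decoy":
            return tuple([plan.decoy_depth] * n_samples), -1
        cond_idx = int(rng.integers(0, len(CONDITIONS)))
        base = float(rng.uniform(*plan.baseline_depth))
        effect = float(rng.uniform(*plan.effect_range))
        if kind == "condition_specific":
            cond_idx = CONDITIONS.index("salt")
            profile = [
                base if c == "salt" else 5.0
                for c in CONDITIONS
                for _ in range(3)
            ]
            return tuple(profile), cond_idx
        profile = [
            base * effect if j // 3 == cond_idx else base for j in range(n_samples)
        ]
        return tuple(profile), cond_idx

    def place(category: str, kind: str, count: int, label: str):
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 20000:
                raise ValueError(
                    f"genome too crowded to place {count} {label} features"
                )
            length = int(rng.integers(plan.length_range[0], plan.length_range[1] + 1))
            if category == "asRNA":
                cds = [g for g in genes if g.feature_class == "CDS" and g.length >= length + 12]
                if not cds:
                    raise ValueError("no CDS large enough for antisense features")
                g = cds[int(rng.integers(0, len(cds)))]
                s = int(rng.integers(g.start + 5, g.end - length - 4))
                rep = g.replicon
                e = s + length - 1
            elif category == "UTR":
                cds = [g for g in genes if g.feature_class == "CDS"]
                g = cds[int(rng.integers(0, len(cds)))]
                rep = g.replicon
                if g.strand == "+":
                    ws, we = g.start - utr_upstream, g.start - 1
                else:
                    ws, we = g.end + 1, g.end + utr_upstream
                if we - ws + 1 < length or ws < 1 or we > genome.length(rep):
                    continue
                s = int(rng.integers(ws, we - length + 2))
                e = s + length - 1
                if not far_from_genes(rep, s, e, 0):
                    continue
            else:  # ncRNA / decoy: intergenic, clear of every window
                rep = genome.names[int(rng.integers(0, len(genome.replicons)))]
                rep_len = genome.length(rep)
                if rep_len < length + 400:
                    continue
                s = int(rng.integers(200, rep_len - length - 199))
                e = s + length - 1
                if not far_from_genes(rep, s, e, 101):
                    continue
            if not free(rep, s, e):
                continue
            profile, grp = depth_profile(kind, placed)
            features.append(
                PlantedFeature(
                    replicon=rep, start=s, end=e, true_category=category,
                    per_sample_mean_depth=profile, trend_group=grp,
                    feature_id=f"{label}{placed + 1}",
                )
            )
            occupied[rep].append((s, e))
            placed += 1

    n_cs = min(plan.n_condition_specific, plan.n_ncrna)
    place("ncRNA", "condition_specific", n_cs, "planted_nc_cs")
    place("ncRNA", "regular", plan.n_ncrna - n_cs, "planted_nc")
    place("asRNA", "regular", plan.n_asrna, "planted_as")
    place("UTR", "regular", plan.n_utr, "planted_utr")
    place("ncRNA", "decoy", plan.n_decoys, "decoy")
    return features


def ground_truth_table(features: list[PlantedFeature]) -> pd.DataFrame:
    rows = []
    for f in features:
        rows.append({
            "feature_id": f.feature_id, "replicon": f.replicon,
            "start": f.start, "end": f.end, "true_category": f.true_category,
            "trend_group": f.trend_group, "is_decoy": f.feature_id.startswith("decoy"),
            "max_depth": max(f.per_sample_mean_depth),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- reads

def simulate_reads(
    genome: GenomeModel,
    planted: list[PlantedFeature],
    sample_index: int,
    read_len: int = 100,
    background_depth: float = 1.0,
    corrupt_fraction: float = 0.1,
    seed: int = 0,
) -> list[FastqRead]:
    """Unstranded single-end reads for one sample.

    Background reads of ``read_len`` fall uniformly at Poisson rate
    ``background_depth``; each planted feature emits full-transcript reads
    (the features are 50-100 nt, within one read) at Poisson rate equal to
    its per-sample mean depth, giving near-rectangular coverage.  A
    ``corrupt_fraction`` of reads get one terminal base flipped and assigned
    quality 10 (< Q20) so the trim-and-remap loop has work to do.
    """
    if any(d < 0 for f in planted for d in f.per_sample_mean_depth):
        raise ValueError("depths must be nonnegative")
    rng = np.random.default_rng(seed)
    reads: list[FastqRead] = []
    serial = 0

    def emit(rep_seq: str, start: int, length: int):
        nonlocal serial
        serial += 1
        seq = rep_seq[start - 1 : start - 1 + length]
        if rng.random() < 0.5:
            seq = seq.translate(_COMPLEMENT)[::-1]
        quals = [35] * len(seq)
        if rng.random() < corrupt_fraction and len(seq) > 1:
            end3 = rng.random() < 0.5
            idx = len(seq) - 1 if end3 else 0
            old = seq[idx]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            seq = seq[:idx] + new + seq[idx + 1 :] if idx else new + seq[1:]
            quals[idx] = 10
        reads.append(FastqRead(f"s{sample_index}_r{serial}", seq, tuple(quals)))

    for name, seq in genome.replicons:
        if len(seq) < read_len:
            continue
        n_bg = rng.poisson(background_depth * len(seq) / read_len)
        for start in rng.integers(1, len(seq) - read_len + 2, size=n_bg):
            emit(seq, int(start), read_len)

    for f in planted:
        depth = f.per_sample_mean_depth[sample_index]
        if depth <= 0:
            continue
        n = rng.poisson(depth)
        rep_seq = genome.sequence(f.replicon)
        for _ in range(n):
            emit(rep_seq, f.start, f.length)
    return reads


def expected_masked_total(
    genome: GenomeModel,
    annotation: list[AnnotationRecord],
    planted: list[PlantedFeature],
    background_depth: float = 1.0,
) -> float:
    """Design-expected rRNA/tRNA-excluded mapped bases, averaged over the 18
    samples; the demo pipeline uses this as its normalization target so that
    normalized depths stay on the planted scale (the study's fixed 1e8 target
    plays the same role at its own sequencing scale)."""
    masked_len = sum(
        a.length for a in annotation if a.feature_class in ("rRNA", "tRNA")
    )
    bg = background_depth * (genome.total_length - masked_len)
    n_samples = len(sample_ids())
    planted_mean = sum(
        f.length * sum(f.per_sample_mean_depth) / n_samples for f in planted
    )
    return bg + planted_mean


# ------------------------------------------------------------------ counts

def simulate_counts(
    n_srnas: int,
    effects: dict[str, np.ndarray | float] | None = None,
    dispersion: float = 0.1,
    base_mean: float | np.ndarray = 200.0,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Negative-binomial count matrix over the 18-sample design.

    ``effects`` maps a condition name to per-sRNA fold changes (scalar or
    length-``n_srnas`` array) applied to that condition's replicates; null
    sRNAs keep the shared base mean.  ``dispersion`` = 0 degenerates to
    Poisson.  Columns are ``{condition}_{t}h``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    effects = effects or {}
    base = np.broadcast_to(np.asarray(base_mean, dtype=float), (n_srnas,))
    cols = {}
    timepoints = (24, 48, 72)[:n_reps]
    for cond in conditions:
        fc = np.broadcast_to(np.asarray(effects.get(cond, 1.0), dtype=float), (n_srnas,))
        mu = base * fc
        for t in timepoints:
            if dispersion == 0:
                counts = rng.poisson(mu)
            else:
                size = 1.0 / dispersion
                p = size / (size + mu)
                counts = rng.negative_binomial(size, p)
            cols[f"{cond}_{t}h"] = counts
    return pd.DataFrame(cols, index=[f"sRNA{i+1}" for i in range(n_srnas)])


# ----------------------------------------------------------- network truth

@dataclass
class NetworkTruth:
    """Planted-enrichment fixture for the network stage."""

    predictions: pd.DataFrame  # srna_id, gene_id, free_energy, rank, strand
    pathway_map: pd.DataFrame  # gene_id, pathway_id
    transcriptome: pd.DataFrame  # genes x 18 samples
    srna_expression: pd.DataFrame  # sRNAs x 18 samples
    true_edges: list[tuple[str, str]] = field(default_factory=list)


def simulate_network_truth(
    srnas: list[str],
    genes: list[str],
    pathways: dict[str, list[str]],
    enriched_pairs: list[tuple[str, str]],
    seed: int = 0,
    n_true_targets: int = 5,
    n_decoys: int = 30,
    samples: list[str] | None = None,
) -> NetworkTruth:
    """Target predictions, pathway map and paired transcriptome in which the
    requested (sRNA, pathway) pairs are truly enriched.

    True targets of an enriched pair are drawn from that pathway, given
    favorable energies (<= -12 kcal/mol) and transcriptome profiles whose
    Pearson correlation with the sRNA exceeds 0.6 in magnitude; decoys get
    either unfavorable energies (> -10) or near-zero correlations (|r| < 0.2),
    so the dual filter should remove them.
    """
    rng = np.random.default_rng(seed)
    samples = samples or sample_ids()
    n_s = len(samples)
    pathway_genes = {g for gs in pathways.values() for g in gs}
    if not pathway_genes <= set(genes):
        missing = sorted(pathway_genes - set(genes))
        raise ValueError(f"pathway map names genes outside the universe: {missing[:5]}")
    for sid, pw in enriched_pairs:
        if pw not in pathways:
            raise ValueError(f"enriched pair names unknown pathway {pw!r}")
        if sid not in srnas:
            raise ValueError(f"enriched pair names unknown sRNA {sid!r}")

    srna_expr = pd.DataFrame(
        rng.lognormal(mean=4.0, sigma=0.6, size=(len(srnas), n_s)),
        index=srnas, columns=samples,
    )
    pathway_map = pd.DataFrame(
        [(g, pw) for pw, gs in pathways.items() for g in gs],
        columns=["gene_id", "pathway_id"],
    )

    def correlated_profile(x: np.ndarray, target_abs_r: float, below: bool) -> np.ndarray:
        # rejection-sample until the empirical |r| is on the requested side
        for _ in range(200):
            if below:
                y = rng.normal(size=n_s)
            else:
                sgn = -1.0 if rng.random() < 0.5 else 1.0
                noise = rng.normal(size=n_s)
                xs = (x - x.mean()) / (x.std() + 1e-12)
                y = sgn * 2.0 * xs + 0.9 * noise
            r = abs(np.corrcoef(x, y)[0, 1])
            if (below and r < target_abs_r) or (not below and r > target_abs_r):
                return 50 + 10 * y  # arbitrary positive-ish expression scale
        raise RuntimeError("could not achieve requested correlation")

    transcriptome_rows: dict[str, np.ndarray] = {}
    pred_rows = []
    enriched_by_srna: dict[str, list[str]] = {}
    for sid, pw in enriched_pairs:
        enriched_by_srna.setdefault(sid, []).append(pw)

    pinned: set[str] = set()  # true-target genes keep their correlated profiles
    for sid in srnas:
        x = srna_expr.loc[sid].to_numpy()
        used_genes: set[str] = set()
        entries = []  # (gene, energy, is_true_target)
        for pw in enriched_by_srna.get(sid, []):
            members = [g for g in pathways[pw] if g not in used_genes and g not in pinned]
            chosen = list(rng.choice(members, size=min(n_true_targets, len(members)),
                                     replace=False))
            for g in chosen:
                transcriptome_rows[g] = correlated_profile(x, 0.6, below=False)
                entries.append((g, float(rng.uniform(-25, -12)), True))
                used_genes.add(g)
                pinned.add(g)
        pool = [g for g in genes if g not in used_genes and g not in pinned]
        decoys = list(rng.choice(pool, size=min(n_decoys, len(pool)), replace=False))
        for j, g in enumerate(decoys):
            if j % 2 == 0:  # unfavorable energy, any correlation
                energy = float(rng.uniform(-9.5, -4.0))
                if g not in transcriptome_rows:
                    transcriptome_rows[g] = correlated_profile(x, 0.2, below=True)
            else:  # favorable energy, flat correlation w.r.t. this sRNA
                energy = float(rng.uniform(-20, -12))
                if g not in transcriptome_rows:
                    transcriptome_rows[g] = correlated_profile(x, 0.2, below=True)
            entries.append((g, energy, False))
            used_genes.add(g)
        entries.sort(key=lambda t: t[1])  # best energy first -> rank
        for rank, (g, energy, is_true) in enumerate(entries, start=1):
            pred_rows.append({
                "srna_id": sid, "gene_id": g, "free_energy": energy,
                "rank": rank, "strand": "+" if rng.random() < 0.5 else "-",
                "true_target": is_true,
            })

    for g in genes:  # genes never predicted still need transcriptome rows
        if g not in transcriptome_rows:
            transcriptome_rows[g] = 50 + 10 * rng.normal(size=n_s)
    transcriptome = pd.DataFrame.from_dict(transcriptome_rows, orient="index",
                                           columns=samples).loc[sorted(transcriptome_rows)]
    return NetworkTruth(
        predictions=pd.DataFrame(pred_rows),
        pathway_map=pathway_map,
        transcriptome=transcriptome,
        srna_expression=srna_expr,
        true_edges=list(enriched_pairs),
    )


def default_pathways(n_pathways: int = 20, genes_per_pathway: int = 10,
                     prefix: str = "path") -> tuple[list[str], dict[str, list[str]]]:
    """A disjoint pathway partition over a synthetic gene universe."""
    genes = [f"g{i+1:04d}" for i in range(n_pathways * genes_per_pathway)]
    pathways = {
        f"{prefix}{k+1:02d}": genes[k * genes_per_pathway : (k + 1) * genes_per_pathway]
        for k in range(n_pathways)
    }
    return genes, pathways


# -------------------------------------------------------------- whole study

@dataclass
class SyntheticStudy:
    genome: GenomeModel
    annotation: list[AnnotationRecord]
    planted: list[PlantedFeature]
    reads_by_sample: dict[str, list[FastqRead]]
    normalization_target: float
    seed: int

    @property
    def truth(self) -> pd.DataFrame:
        return ground_truth_table(self.planted)


def synthetic_study(
    seed: int = 0,
    plan: PlantPlan | None = None,
    background_depth: float = 1.0,
    corrupt_fraction: float = 0.1,
    sizes: dict[str, int] | None = None,
) -> SyntheticStudy:
    """Generate the full default study: genome, annotation, planted features
    and 18 read sets, bit-identically reproducible from the seed."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3 + 18)]
    genome = make_genome(sizes=sizes, seed=seeds[0])
    annotation = make_annotation(genome, seed=seeds[1])
    planted = plant_features(genome, annotation, plan=plan, seed=seeds[2])
    reads = {
        sid: simulate_reads(
            genome, planted, i, background_depth=background_depth,
            corrupt_fraction=corrupt_fraction, seed=seeds[3 + i],
        )
        for i, sid in enumerate(sample_ids())
    }
    target = expected_masked_total(genome, annotation, planted, background_depth)
    return SyntheticStudy(genome, annotation, planted, reads, target, seed)
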