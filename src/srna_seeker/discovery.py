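"""Multi-tier sRNA calling from normalized coverage.

The tiers, in pipeline order:

1. threshold segmentation — maximal runs with depth > 50x per sample;
2. reference-guided rescue of weakly expressed loci (inside mean must exceed
   ``rescue_ratio`` times each 50 bp flank's mean);
3. cross-sample support — candidates clustered over samples, clusters seen in
   >= 3 of the 18 samples survive, consensus = position-wise median of ends;
4. merge of near-adjacent candidates (gap < 50 bp) sharing an expression trend;
5. boundary refinement to the point of maximum single-step coverage decline;
6. location-based classification into ncRNA / asRNA / UTR;
7. repeat-region flagging by k-mer seeded, ungapped second-site search.

The library is unstranded: intervals carry no strand, and "asRNA" means the
candidate overlaps a gene body on either strand.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .core import AnnotationRecord, CoverageTrack, DetectionParams, GenomeModel, SrnaInterval

logger = logging.getLogger(__name__)

CATEGORY_PREFIX = {"ncRNA": "nc", "asRNA": "as", "UTR": "U"}


# --------------------------------------------------------- tier 1: segmentation

def segment_high_expression(track: CoverageTrack, threshold: float = 50.0) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with depth strictly above the
    threshold, as (start, end) 1-based inclusive.  Sub-50 bp runs are kept
    here; the final length filter happens after merging."""
    above = track.depth > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(int(s) + 1, int(e) + 1) for s, e in zip(run_starts, run_ends)]


# -------------------------------------------------------------- tier 2: rescue

def rescue_low_expression(
    track: CoverageTrack,
    reference_candidates: list[tuple[int, int]],
    flank: int = 50,
    ratio: float = 2.0,
) -> list[tuple[int, int]]:
    """Keep a previously reported interval iff its mean depth exceeds
    ``ratio`` times the mean of each ``flank``-bp flank (a clear coverage
    drop on both sides) and the inside mean is positive."""
    kept = []
    n = len(track)
    for start, end in reference_candidates:
        if not (1 <= start <= end <= n):
            raise ValueError(f"reference interval {start}..{end} outside replicon")
        inside = float(track.slice(start, end).mean())
        if inside <= 0:
            continue
        lo, hi = max(1, start - flank), start - 1
        left = float(track.slice(lo, hi).mean()) if hi >= lo else 0.0
        lo2, hi2 = end + 1, min(n, end + flank)
        right = float(track.slice(lo2, hi2).mean()) if hi2 >= lo2 else 0.0
        if inside >= ratio * left and inside >= ratio * right:
            kept.append((start, end))
    return kept


# ----------------------------------------------- tier 3: cross-sample support

def _jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def retain_by_support(
    per_sample_intervals: dict[str, dict[str, list[tuple[int, int]]]],
    min_support: int = 3,
    jaccard_support: float = 0.5,
) -> dict[str, list[tuple[int, int, int]]]:
    """Cluster per-sample detections and keep clusters supported by enough
    samples.

    ``per_sample_intervals`` maps sample_id -> replicon -> interval list.
    Clusters are connected components under positional overlap; the consensus
    interval is the position-wise median of member starts and ends, and a
    sample supports a cluster when one of its members has Jaccard overlap
    >= ``jaccard_support`` with that consensus.  Returns, per replicon, the
    surviving (start, end, support) triples sorted by start.
    """
    if not per_sample_intervals:
        raise ValueError("at least one sample required")
    by_rep: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for sample, reps in per_sample_intervals.items():
        for rep, ivals in reps.items():
            for s, e in ivals:
                by_rep[rep].append((s, e, sample))

    out: dict[str, list[tuple[int, int, int]]] = {}
    for rep, members in by_rep.items():
        members.sort()
        clusters: list[list[tuple[int, int, str]]] = []
        cur: list[tuple[int, int, str]] = []
        cur_end = -1
        for s, e, sample in members:  # single-linkage components under overlap
            if cur and s > cur_end:
                clusters.append(cur)
                cur = []
                cur_end = -1
            cur.append((s, e, sample))
            cur_end = max(cur_end, e)
        if cur:
            clusters.append(cur)

        survivors = []
        for cluster in clusters:
            cons_s = int(np.median([s for s, _, _ in cluster]))
            cons_e = int(np.median([e for _, e, _ in cluster]))
            supporting = {
                sample
                for s, e, sample in cluster
                if _jaccard((s, e), (cons_s, cons_e)) >= jaccard_support
            }
            if len(supporting) >= min_support:
                survivors.append((cons_s, cons_e, len(supporting)))
        out[rep] = sorted(survivors)
    return out


# ----------------------------------------------------------------- tier 4: merge

def merge_adjacent(
    candidates: list[tuple[int, int, int]],
    expression: dict[tuple[int, int], np.ndarray],
    merge_gap: int = 50,
    trend: str = "pearson",
) -> list[tuple[int, int, int]]:
    """Merge neighbours whose gap is < ``merge_gap`` bp and whose per-sample
    expression vectors share a trend, iterating to a fixpoint.

    ``expression`` maps each candidate's (start, end) to its per-sample
    expression vector.  Trend is positive Pearson correlation (r > 0) by
    default, or sign concordance of deviations from the mean with
    ``trend="sign"``.  Support of a merged pair is the max of the parts.
    """
    if trend not in ("pearson", "sign"):
        raise ValueError(f"unknown trend rule {trend!r}")
    work = sorted(candidates)
    expr = dict(expression)
    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int, int]] = []
        i = 0
        while i < len(work):
            if i + 1 < len(work):
                s1, e1, n1 = work[i]
                s2, e2, n2 = work[i + 1]
                gap = s2 - e1 - 1
                if gap < merge_gap and _same_trend(expr.get((s1, e1)), expr.get((s2, e2)), trend):
                    union = (min(s1, s2), max(e1, e2), max(n1, n2))
                    v1, v2 = expr.get((s1, e1)), expr.get((s2, e2))
                    if v1 is not None and v2 is not None:
                        l1, l2 = e1 - s1 + 1, e2 - s2 + 1
                        expr[union[:2]] = (v1 * l1 + v2 * l2) / (l1 + l2)
                    work[i + 1] = union
                    i += 1
                    changed = True
                    continue
            merged.append(work[i])
            i += 1
        work = merged
    return work


def _same_trend(v1, v2, rule: str) -> bool:
    if v1 is None or v2 is None:
        return True  # no expression evidence against merging
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if np.std(v1) == 0 or np.std(v2) == 0:
        return True
    if rule == "pearson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = np.corrcoef(v1, v2)[0, 1]
        return bool(r > 0)
    d1, d2 = np.sign(v1 - v1.mean()), np.sign(v2 - v2.mean())
    agree = float(np.mean(d1 == d2))
    return agree > 0.5


# ------------------------------------------------------ tier 5: boundary refine

def refine_boundaries(
    candidate: tuple[int, int], track: CoverageTrack, window: int = 20
) -> tuple[int, int]:
    """Move each boundary (within +/- ``window`` nt) to the position of the
    maximum single-step coverage decline; ties keep the position closest to
    the unrefined boundary.

    The 3' side uses drop[i] = depth[i] - depth[i+1]; the new end is the i
    maximizing the drop.  The 5' side mirrors this with rises."""
    start, end = candidate
    n = len(track)
    d = track.depth

    # 3' end: search i in [end-window, end+window], drop at i = d[i] - d[i+1]
    new_end = _argmax_step(d, end, window, n, side="end")
    # 5' start: rise entering i = d[i] - d[i-1]
    new_start = _argmax_step(d, start, window, n, side="start")
    if new_start > new_end:  # degenerate signal: keep the original span
        return start, end
    return new_start, new_end


def _argmax_step(d: np.ndarray, pos: int, window: int, n: int, side: str) -> int:
    lo, hi = max(1, pos - window), min(n, pos + window)
    best, best_step = pos, -np.inf
    for i in range(lo, hi + 1):
        if side == "end":
            nxt = d[i] if i < n else 0.0  # depth beyond the replicon is zero
            step = d[i - 1] - nxt
        else:
            prev = d[i - 2] if i > 1 else 0.0
            step = d[i - 1] - prev
        if step > best_step + 1e-12 or (
            abs(step - best_step) <= 1e-12 and abs(i - pos) < abs(best - pos)
        ):
            best, best_step = i, step
    return best


# -------------------------------------------------- tier 6: classify by location

def classify_by_location(
    candidate: SrnaInterval | tuple[str, int, int],
    annotation: list[AnnotationRecord],
    utr_upstream: int = 100,
    utr_downstream: int = 50,
) -> str:
    """ncRNA / asRNA / UTR assignment by position.

    Precedence: overlap with any gene body -> asRNA; else overlap with any
    gene's 100 nt-upstream or 50 nt-downstream window (placed by the gene's
    strand) -> UTR; else ncRNA.
    """
    if isinstance(candidate, SrnaInterval):
        rep, start, end = candidate.replicon, candidate.start, candidate.end
    else:
        rep, start, end = candidate
    genes = [a for a in annotation if a.replicon == rep]

    def ovl(a_start, a_end):
        return max(0, min(end, a_end) - max(start, a_start) + 1)

    if any(ovl(g.start, g.end) > 0 for g in genes):
        return "asRNA"
    for g in genes:
        if g.strand == "+":
            windows = [(g.start - utr_upstream, g.start - 1), (g.end + 1, g.end + utr_downstream)]
        else:
            windows = [(g.end + 1, g.end + utr_upstream), (g.start - utr_downstream, g.start - 1)]
        if any(ws <= we and ovl(ws, we) > 0 for ws, we in windows):
            return "UTR"
    return "ncRNA"


# ---------------------------------------------------- tier 7: repeat flagging

def flag_repeats(
    candidates: list[SrnaInterval],
    genome: GenomeModel,
    min_identity: float = 0.80,
    min_len: int = 50,
    seed_k: int = 20,
) -> list[SrnaInterval]:
    """Flag candidates whose sequence recurs elsewhere in the genome.

    A candidate is flagged iff a second site (outside the candidate's own
    locus) yields an ungapped alignment longer than ``min_len`` with identity
    above ``min_identity``.  Second sites are found by exact ``seed_k``-mer
    seeding on both strands followed by greedy ungapped extension.
    """
    from .coverage import revcomp

    out = []
    for c in candidates:
        seq = genome.sequence(c.replicon)[c.start - 1 : c.end]
        flagged = _has_second_site(seq, genome, (c.replicon, c.start, c.end),
                                   min_identity, min_len, seed_k)
        nc = c.replaced(repeat_flag=flagged)
        out.append(nc)
    return out


def _has_second_site(query, genome, self_locus, min_identity, min_len, seed_k):
    from .coverage import revcomp

    rep0, s0, e0 = self_locus
    for strand_query in (query, revcomp(query)):
        for qpos in range(0, max(1, len(strand_query) - seed_k + 1)):
            seed = strand_query[qpos : qpos + seed_k]
            if len(seed) < seed_k:
                break
            for rep, seq in genome.replicons:
                at = seq.find(seed)
                while at != -1:
                    g_start = at + 1
                    inside_self = (
                        rep == rep0
                        and strand_query is query
                        and g_start - qpos == s0  # the candidate's own placement
                    )
                    if not inside_self:
                        aln_len, ident = _extend_ungapped(strand_query, qpos, seq, at, seed_k)
                        if aln_len > min_len and ident > min_identity:
                            return True
                    at = seq.find(seed, at + 1)
    return False


def _extend_ungapped(query, qpos, subject, spos, seed_k):
    """Greedy ungapped extension around a seed; returns (length, identity) of
    the best window that keeps identity maximal under simple X-drop (X=5)."""
    matches = seed_k
    length = seed_k
    # extend right
    qi, si = qpos + seed_k, spos + seed_k
    run_mis = 0
    while qi < len(query) and si < len(subject) and run_mis < 5:
        if query[qi] == subject[si]:
            matches += 1
            run_mis = 0
        else:
            run_mis += 1
        length += 1
        qi += 1
        si += 1
    length -= run_mis  # trim trailing mismatches
    # extend left
    qi, si = qpos - 1, spos - 1
    run_mis = 0
    left_len = 0
    left_matches = 0
    while qi >= 0 and si >= 0 and run_mis < 5:
        if query[qi] == subject[si]:
            left_matches += 1
            run_mis = 0
        else:
            run_mis += 1
        left_len += 1
        qi -= 1
        si -= 1
    left_len -= run_mis
    total_len = length + left_len
    total_matches = matches + left_matches
    return total_len, total_matches / total_len if total_len else 0.0


# ------------------------------------------- external annotation ingestion

def ingest_external_annotations(
    candidates: list[SrnaInterval],
    tables: dict[str, pd.DataFrame],
    nr_evalue_cutoff: float = 1e-10,
) -> list[SrnaInterval]:
    """Attach externally produced labels (Nr / Rfam / ORF / RBS / terminator)
    keyed by candidate id.  Nr hits at E >= cutoff are ignored; rows naming
    unknown candidates warn and are skipped."""
    by_id = {c.id: c for c in candidates}
    out = {c.id: dict(c.annotations) for c in candidates}
    for label, df in tables.items():
        if "id" not in df.columns or "value" not in df.columns:
            raise ValueError(f"table {label!r} must have columns 'id' and 'value'")
        for _, row in df.iterrows():
            cid = str(row["id"])
            if cid not in by_id:
                logger.warning("external table %s names unknown candidate %s; skipped", label, cid)
                continue
            if label == "nr" and "evalue" in df.columns and float(row["evalue"]) >= nr_evalue_cutoff:
                continue
            out[cid][label] = str(row["value"])
    return [c.replaced(annotations=out[c.id]) for c in candidates]


# ------------------------------------------------------------- orchestration

def call_srnas(
    normalized_tracks: dict[str, list[CoverageTrack]],
    annotation: list[AnnotationRecord],
    genome: GenomeModel,
    params: DetectionParams | None = None,
    reference_candidates: dict[str, list[tuple[int, int]]] | None = None,
) -> list[SrnaInterval]:
    """Run the full multi-tier caller over all samples and return classified,
    repeat-flagged sRNA intervals with ids assigned per category.

    ``normalized_tracks`` maps sample_id -> per-replicon tracks; optional
    ``reference_candidates`` maps replicon -> previously reported intervals
    for the low-expression rescue tier.
    """
    params = params or DetectionParams()
    per_sample: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for sample, tracks in normalized_tracks.items():
        per_rep: dict[str, list[tuple[int, int]]] = {}
        for t in tracks:
            ivals = segment_high_expression(t, params.depth_threshold)
            if reference_candidates and t.replicon in reference_candidates:
                rescued = rescue_low_expression(
                    t, reference_candidates[t.replicon], params.rescue_flank,
                    params.rescue_ratio,
                )
                existing = set(ivals)
                ivals = sorted(existing | set(rescued))
            per_rep[t.replicon] = ivals
        per_sample[sample] = per_rep

    supported = retain_by_support(per_sample, params.min_support, params.jaccard_support)

    sample_order = sorted(normalized_tracks)
    mean_tracks = {
        rep: np.mean(
            [
                next(t for t in normalized_tracks[s] if t.replicon == rep).depth
                for s in sample_order
            ],
            axis=0,
        )
        for rep in {t.replicon for ts in normalized_tracks.values() for t in ts}
    }

    final: list[SrnaInterval] = []
    counters = {cat: 0 for cat in CATEGORY_PREFIX}
    for rep in sorted(supported):
        cands = supported[rep]
        expr = {
            (s, e): np.array(
                [
                    float(
                        next(t for t in normalized_tracks[smp] if t.replicon == rep)
                        .slice(s, e)
                        .mean()
                    )
                    for smp in sample_order
                ]
            )
            for s, e, _ in cands
        }
        merged = merge_adjacent(cands, expr, params.merge_gap)
        mean_track = CoverageTrack(rep, mean_tracks[rep], sample_id="mean", normalized=True)
        for s, e, support in merged:
            rs, re_ = refine_boundaries((s, e), mean_track, params.refine_window)
            if re_ - rs + 1 < params.min_length:
                continue
            category = classify_by_location(
                (rep, rs, re_), annotation, params.utr_upstream, params.utr_downstream
            )
            counters[category] += 1
            final.append(
                SrnaInterval(
                    id=f"{CATEGORY_PREFIX[category]}{counters[category]}",
                    replicon=rep, start=rs, end=re_,
                    category=category, support=support,
                )
            )
    return flag_repeats(final, genome, min_len=params.min_length)
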