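"""sRNA regulatory-network construction.

Ingested target predictions (CopraRNA-style rows of sRNA, gene, hybridization
free energy, rank) are filtered to the top 100 ranks at a free-energy cutoff
of -10 kcal/mol, then pruned by Pearson correlation between the sRNA's
expression profile and each candidate target's transcriptome profile over the
shared samples (|r| > 0.4 strictly, two-sided p < 0.05 via the Fisher
z-transform; both signs kept, as sRNAs can act positively or negatively).
Surviving targets feed a per-sRNA hypergeometric pathway enrichment (upper
tail, universe = pathway-annotated genes), and pathways with at least two hit
targets at P < 0.05 become edges of a bipartite sRNA–pathway graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats

logger = logging.getLogger(__name__)


# ------------------------------------------------------------ target filtering

def filter_targets(
    predictions: pd.DataFrame, max_rank: int = 100, energy_cutoff: float = -10.0
) -> pd.DataFrame:
    """Keep predictions with rank <= max_rank and free energy <= cutoff,
    per sRNA.  Requires columns srna_id, gene_id, free_energy, rank."""
    required = {"srna_id", "gene_id", "free_energy", "rank"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns {sorted(missing)}")
    if predictions.duplicated(["srna_id", "gene_id"]).any():
        dup = predictions[predictions.duplicated(["srna_id", "gene_id"])].iloc[0]
        raise ValueError(f"duplicate prediction row for ({dup['srna_id']}, {dup['gene_id']})")
    for sid, grp in predictions.groupby("srna_id"):
        if grp["rank"].duplicated().any():
            raise ValueError(f"ranks not unique for sRNA {sid}")
    keep = (predictions["rank"] <= max_rank) & (predictions["free_energy"] <= energy_cutoff)
    return predictions.loc[keep].reset_index(drop=True)


# -------------------------------------------------------- correlation filtering

def _fisher_z_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the Fisher z-transform."""
    if n < 4:
        return 1.0
    r = min(max(r, -0.9999999), 0.9999999)
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(2 * stats.norm.sf(abs(z)))


def correlation_filter(
    predictions: pd.DataFrame,
    srna_expression: pd.DataFrame,
    transcriptome: pd.DataFrame,
    r_cut: float = 0.4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson-correlation pruning of energy/rank-filtered predictions.

    Correlates each (sRNA, gene) pair across the sample columns shared by the
    sRNA expression matrix and the paired transcriptome matrix; keeps records
    with |r| > r_cut (strict) and p < alpha, recording the correlation sign.
    Pairs with a constant profile are dropped with a warning (r undefined).
    """
    shared = [c for c in srna_expression.columns if c in transcriptome.columns]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared sample columns for correlation")
    rows = []
    for _, pred in predictions.iterrows():
        sid, gid = pred["srna_id"], pred["gene_id"]
        if sid not in srna_expression.index or gid not in transcriptome.index:
            continue
        x = srna_expression.loc[sid, shared].to_numpy(dtype=float)
        y = transcriptome.loc[gid, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("constant profile for (%s, %s); correlation undefined, dropped", sid, gid)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        p = _fisher_z_p(r, len(shared))
        if abs(r) > r_cut and p < alpha:
            rows.append({"srna_id": sid, "gene_id": gid, "r": r, "p": p,
                         "sign": "positive" if r > 0 else "negative"})
    return pd.DataFrame(rows, columns=["srna_id", "gene_id", "r", "p", "sign"])


# ------------------------------------------------------- hypergeometric P

def hypergeom_p(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability of drawing >= m pathway genes.

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n), computed as the
    complement tail in log space (gammaln + logsumexp) for stability:
    universe N, pathway size M, draws n, observed hits m.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(f"invalid hypergeometric parameters N={N} M={M} n={n} m={m}")
    if m == 0:
        return 1.0
    lo = max(0, n - (N - M))
    hi = min(n, M)
    i = np.arange(max(m, lo), hi + 1)
    if len(i) == 0:
        return 0.0
    log_terms = (
        _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


# --------------------------------------------------------- pathway enrichment

def enrich_pathways(
    target_genes: list[str],
    pathway_map: pd.DataFrame,
    srna_id: str = "",
    min_hits: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of one sRNA's surviving targets.

    ``pathway_map`` has columns gene_id, pathway_id; the universe N is the
    set of genes carrying any pathway annotation.  Targets outside the
    universe reduce neither M nor m and do not count toward n.  Reported
    pathways have m >= min_hits and P < alpha.
    """
    if not {"gene_id", "pathway_id"} <= set(pathway_map.columns):
        raise ValueError("pathway map needs columns gene_id, pathway_id")
    universe = set(pathway_map["gene_id"])
    if not universe:
        raise ValueError("empty annotation universe")
    N = len(universe)
    targets_in_universe = set(target_genes) & universe
    n = len(targets_in_universe)
    rows = []
    for pathway_id, grp in pathway_map.groupby("pathway_id"):
        members = set(grp["gene_id"])
        M = len(members)
        m = len(targets_in_universe & members)
        if m < min_hits:
            continue
        P = hypergeom_p(N, M, n, m)
        if P < alpha:
            rows.append({"srna_id": srna_id, "pathway_id": pathway_id,
                         "N": N, "M": M, "n": n, "m": m, "P": P})
    return pd.DataFrame(rows, columns=["srna_id", "pathway_id", "N", "M", "n", "m", "P"])


# ----------------------------------------------------------- graph assembly

@dataclass
class RegulatoryNetwork:
    """Bipartite sRNA–pathway graph; every edge is an enrichment call."""

    graph: nx.Graph

    @property
    def srnas(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "sRNA")

    @property
    def pathways(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "pathway")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def assemble_network(
    enrichments: pd.DataFrame, correlations: pd.DataFrame | None = None
) -> RegulatoryNetwork:
    """Bipartite graph from passing enrichment results.

    Edge attributes carry P, m, and — when correlation records are supplied —
    the dominant correlation sign among the sRNA's supporting targets.  Node
    insertion order is deterministic (sorted)."""
    g = nx.Graph()
    if enrichments.empty:
        return RegulatoryNetwork(g)
    dominant_sign = {}
    if correlations is not None and not correlations.empty:
        for sid, grp in correlations.groupby("srna_id"):
            pos = (grp["sign"] == "positive").sum()
            neg = (grp["sign"] == "negative").sum()
            dominant_sign[sid] = "positive" if pos >= neg else "negative"
    rows = enrichments.sort_values(["srna_id", "pathway_id"])
    for sid in sorted(rows["srna_id"].unique()):
        g.add_node(sid, kind="sRNA")
    for pid in sorted(rows["pathway_id"].unique()):
        g.add_node(pid, kind="pathway")
    for _, row in rows.iterrows():
        g.add_edge(
            row["srna_id"], row["pathway_id"],
            P=float(row["P"]), m=int(row["m"]),
            sign=dominant_sign.get(row["srna_id"], "unknown"),
        )
    return RegulatoryNetwork(g)


# ------------------------------------------------------------------- export

def export_graph(network: RegulatoryNetwork, graphml_path, sif_path=None) -> None:
    """Write GraphML (attributes preserved) and optionally SIF (topology)."""
    nx.write_graphml(network.graph, str(graphml_path))
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v, d in sorted(network.graph.edges(data=True)):
                fh.write(f"{u}\tenriched_in\t{v}\n")


def read_graphml(path) -> RegulatoryNetwork:
    g = nx.read_graphml(str(path))
    # the parser injects empty default dicts; drop them so round trips are exact
    for key in ("node_default", "edge_default"):
        if g.graph.get(key) == {}:
            del g.graph[key]
    return RegulatoryNetwork(g)


# ------------------------------------------------------------ one-call driver

def build_network(
    predictions: pd.DataFrame,
    srna_expression: pd.DataFrame,
    transcriptome: pd.DataFrame,
    pathway_map: pd.DataFrame,
    max_rank: int = 100,
    energy_cutoff: float = -10.0,
    r_cut: float = 0.4,
    corr_alpha: float = 0.05,
    enrich_alpha: float = 0.05,
    min_hits: int = 2,
) -> tuple[RegulatoryNetwork, pd.DataFrame, pd.DataFrame]:
    """Full chain: energy/rank filter -> correlation filter -> per-sRNA
    enrichment -> bipartite assembly.  Returns (network, enrichment table,
    correlation table)."""
    filtered = filter_targets(predictions, max_rank, energy_cutoff)
    corr = correlation_filter(filtered, srna_expression, transcriptome, r_cut, corr_alpha)
    frames = []
    for sid, grp in corr.groupby("srna_id"):
        res = enrich_pathways(list(grp["gene_id"]), pathway_map, srna_id=sid,
                              min_hits=min_hits, alpha=enrich_alpha)
        if not res.empty:
            frames.append(res)
    enrichments = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["srna_id", "pathway_id", "N", "M", "n", "m", "P"])
    )
    return assemble_network(enrichments, corr), enrichments, corr
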