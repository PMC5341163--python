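"""Expression quantification, differential expression and ordination.

Expression of an sRNA in a sample is the mean normalized coverage depth over
its interval (summed per-nucleotide depth divided by the length j).

Differential expression is a negative-binomial stand-in for DESeq, kept
pluggable behind ``nb_test``: median-of-ratios size factors, method-of-moments
dispersion pooled across sRNAs, a sum-conditioned NB exact-style two-sided
test, Benjamini–Hochberg adjustment, and the strict fold-change > 1.5 /
adjusted p < 0.05 significance rule.

Correspondence analysis is computed directly: divide the matrix by its grand
total, form standardized residuals from the row and column masses, take the
SVD, and report principal coordinates with per-dimension inertia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CONDITIONS, CoverageTrack, SrnaInterval, TIMEPOINTS


# ----------------------------------------------------------- quantification

def quantify(srna: SrnaInterval, track: CoverageTrack) -> float:
    """Mean depth over the sRNA's interval: sum(s_i) / j with j = end-start+1."""
    if srna.length < 1:
        raise ValueError("zero-length interval")
    return float(track.slice(srna.start, srna.end).mean())


def expression_matrix(
    srnas: list[SrnaInterval], tracks_by_sample: dict[str, list[CoverageTrack]]
) -> pd.DataFrame:
    """sRNA x sample matrix of mean normalized depths."""
    samples = list(tracks_by_sample)
    data = {}
    for sample in samples:
        by_rep = {t.replicon: t for t in tracks_by_sample[sample]}
        data[sample] = [quantify(s, by_rep[s.replicon]) for s in srnas]
    return pd.DataFrame(data, index=[s.id for s in srnas])


# ------------------------------------------------------------- size factors

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization over sRNAs with all-positive counts.

    The reference is the per-sRNA geometric mean across samples; a sample's
    factor is the median of its ratios to that reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no sRNA has positive counts in every sample")
    log_ref = np.log(positive).mean(axis=1)
    factors = np.exp(np.log(positive).sub(log_ref, axis=0).median(axis=0))
    return factors


# --------------------------------------------------------- dispersion + test

def estimate_dispersion(
    counts: pd.DataFrame, groups: dict[str, list[str]], factors: pd.Series | None = None
) -> float:
    """Pooled method-of-moments NB dispersion across all sRNAs.

    For each sRNA and replicate group, alpha solves var = mu + alpha mu^2 on
    size-factor-normalized counts; group estimates are averaged with weights
    proportional to (n_g - 1) and pooled over sRNAs by their plain mean,
    clipped at zero.  Per-sRNA moment estimates at small n are individually
    very noisy but roughly unbiased, so the pooled mean converges to the
    common dispersion; trimming or medians would bias it low because the
    sampling distribution is right-skewed.
    """
    if factors is None:
        factors = size_factors(counts)
    norm = counts / factors
    per_gene = []
    for _, row in norm.iterrows():
        g_alphas, g_w = [], []
        for members in groups.values():
            x = row[members].to_numpy(dtype=float)
            if len(x) < 2:
                continue
            m = x.mean()
            if m <= 0:
                continue
            v = x.var(ddof=1)
            g_alphas.append((v - m) / m**2)
            g_w.append(len(x) - 1)
        if g_alphas:
            per_gene.append(np.average(g_alphas, weights=g_w))
    if not per_gene:
        return 0.0
    return float(max(0.0, np.mean(per_gene)))


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    """NB log-pmf parameterized by mean and dispersion (var = mean + alpha mean^2)."""
    if alpha <= 1e-12:
        return stats.poisson.logpmf(k, mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return stats.nbinom.logpmf(k, size, p)


def nb_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    dispersion: float,
    factors_a: np.ndarray | None = None,
    factors_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Two-sided NB exact-style test of equal expression between conditions.

    Conditions the observed per-condition totals (k_A, k_B) on their sum: the
    p value adds the probabilities of all splits a + b = k_A + k_B at least
    as extreme (no more probable) than the observed one, where the totals are
    NB with the pooled mean and the dispersion of a sum of replicates.
    Returns (fold_change, p) with fold_change = (mean_B + 0.5)/(mean_A + 0.5)
    on size-factor-normalized counts.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be nonnegative")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    fa = np.ones(len(a)) if factors_a is None else np.asarray(factors_a, dtype=float)
    fb = np.ones(len(b)) if factors_b is None else np.asarray(factors_b, dtype=float)

    mean_a = (a / fa).mean()
    mean_b = (b / fb).mean()
    fold_change = (mean_b + 0.5) / (mean_a + 0.5)

    k_a = int(round(a.sum()))
    k_b = int(round(b.sum()))
    k_s = k_a + k_b
    if k_s == 0:
        return 1.0, 1.0

    # pooled per-unit expression, allocated by each condition's total size factor
    q = (a.sum() + b.sum()) / (fa.sum() + fb.sum())
    mu_a = q * fa.sum()
    mu_b = q * fb.sum()
    # dispersion of a sum of n i.i.d. NB replicates scales as alpha / n
    alpha_a = dispersion / len(a)
    alpha_b = dispersion / len(b)

    grid = np.arange(k_s + 1)
    logp = _nb_logpmf(grid, mu_a, alpha_a) + _nb_logpmf(grid[::-1], mu_b, alpha_b)
    obs = logp[k_a]
    w = np.exp(logp - logp.max())
    p = float(w[logp <= obs + 1e-12].sum() / w.sum())
    return fold_change, min(1.0, max(p, np.finfo(float).tiny))


# ------------------------------------------------------------ BH + DE filter

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_filter(results: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the strict significance rule: fold change > threshold in either
    direction AND adjusted p < alpha; records direction (up/down)."""
    out = results.copy()
    fc = out["fold_change"].to_numpy(dtype=float)
    magnitude = np.maximum(fc, 1.0 / np.where(fc > 0, fc, np.inf))
    out["significant"] = (magnitude > fc_threshold) & (out["p_adj"].to_numpy() < alpha)
    out["direction"] = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
    return out


def de_conditions(
    counts: pd.DataFrame,
    reference: str = "control",
    conditions: tuple[str, ...] = CONDITIONS,
    timepoints: tuple[int, ...] = TIMEPOINTS,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    mode: str = "condition",
) -> pd.DataFrame:
    """Differential expression of every condition against the reference.

    ``mode="condition"`` treats the time points of each condition as
    replicates (n = 3 vs 3); ``mode="timepoint"`` compares single samples per
    time point (n = 1 vs 1, low power, provided for early-response profiling).
    Sample columns must be named ``{condition}_{time}h``.  BH adjustment is
    applied within each comparison.
    """
    if mode not in ("condition", "timepoint"):
        raise ValueError(f"unknown mode {mode!r}")
    factors = size_factors(counts)
    groups = {c: [f"{c}_{t}h" for t in timepoints] for c in conditions}
    alpha_disp = estimate_dispersion(counts, groups, factors)

    frames = []
    comparisons: list[tuple[str, list[str], list[str]]] = []
    for cond in conditions:
        if cond == reference:
            continue
        if mode == "condition":
            comparisons.append((cond, groups[reference], groups[cond]))
        else:
            for t in timepoints:
                comparisons.append(
                    (f"{cond}_{t}h", [f"{reference}_{t}h"], [f"{cond}_{t}h"])
                )
    for label, ref_cols, cond_cols in comparisons:
        rows = []
        for srna_id, row in counts.iterrows():
            fc, p = nb_test(
                row[ref_cols].to_numpy(), row[cond_cols].to_numpy(), alpha_disp,
                factors[ref_cols].to_numpy(), factors[cond_cols].to_numpy(),
            )
            rows.append({"srna_id": srna_id, "comparison": label,
                         "fold_change": fc, "p": p})
        df = pd.DataFrame(rows)
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        frames.append(de_filter(df, fc_threshold, alpha))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["srna_id", "comparison", "fold_change", "p", "p_adj",
                 "significant", "direction"]
    )


# ----------------------------------------------------- correspondence analysis

@dataclass
class CaResult:
    """Principal coordinates and inertia decomposition of a CA."""

    row_coords: pd.DataFrame  # rows x dimensions
    col_coords: pd.DataFrame
    inertia: np.ndarray  # per retained dimension, nonincreasing
    total_inertia: float


def correspondence_analysis(matrix: pd.DataFrame, n_dims: int | None = None) -> CaResult:
    """Classical CA of a nonnegative matrix.

    The matrix is scaled by its grand total; standardized residuals
    D_r^{-1/2} (P - r c^T) D_c^{-1/2} are decomposed by SVD; principal
    coordinates are the mass-rescaled singular vectors weighted by the
    singular values, ordered by inertia (squared singular value).
    """
    X = matrix.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("matrix entries must be nonnegative")
    total = X.sum()
    if total <= 0:
        raise ValueError("grand total must be positive")
    row_sums = X.sum(axis=1)
    col_sums = X.sum(axis=0)
    for i in np.flatnonzero(row_sums == 0):
        raise ValueError(f"all-zero row: {matrix.index[i]!r}")
    for j in np.flatnonzero(col_sums == 0):
        raise ValueError(f"all-zero column: {matrix.columns[j]!r}")

    P = X / total
    r = row_sums / total
    c = col_sums / total
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    total_inertia = float((sv**2).sum())
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep, :]
    if n_dims is not None:
        U, sv, Vt = U[:, :n_dims], sv[:n_dims], Vt[:n_dims, :]

    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None]
    dims = [f"dim{i+1}" for i in range(len(sv))]
    return CaResult(
        row_coords=pd.DataFrame(row_coords, index=matrix.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=matrix.columns, columns=dims),
        inertia=sv**2,
        total_inertia=total_inertia,
    )
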