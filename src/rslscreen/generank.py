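"""Gene-level aggregation: mean SSMD, robust rank aggregation, permutation FDR.

A screen's guide-level ranking is collapsed to genes with the
alpha-truncated robust rank aggregation (RRA) score: for a gene with k
guides at normalized ranks u_(1) <= ... <= u_(k) (u = rank / n_total),

    rho = min over j with u_(j) <= alpha of  P(Beta(j, k - j + 1) <= u_(j)),

i.e. the smallest order-statistic Beta tail probability among guides in the
top alpha fraction; rho = 1 when no guide reaches it.  Significance comes
from a permutation null (the gene's k ranks redrawn uniformly without
replacement), with the add-one estimator to avoid zero p-values, and
Benjamini-Hochberg FDR across genes.  Depletion and enrichment are two
separate one-sided runs on the ascending and descending guide ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.25
DEFAULT_N_PERM = 10_000

GENE_COLUMNS = ["gene", "n_guides", "mean_ssmd", "rho", "p_perm", "fdr", "rank", "direction"]


def mean_gene_score(guide_scores: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Arithmetic mean SSMD over each gene's guides with a defined SSMD.

    Genes whose guides all have undefined SSMD get NaN.  Every scored guide
    must appear in the (gene, guide_id) map.
    """
    scores = guide_scores.drop(columns=["gene"], errors="ignore")
    merged = scores.merge(gene_map[["gene", "guide_id"]], on="guide_id", how="left")
    unmapped = merged.loc[merged["gene"].isna(), "guide_id"].unique()
    if len(unmapped):
        raise ValueError(f"guides missing from gene map: {list(unmapped[:5])}")
    return merged.groupby("gene")["ssmd"].mean()


def _rho_from_sorted_u(u_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized rho over rows of sorted normalized ranks (n_rows, k)."""
    n_rows, k = u_sorted.shape
    j = np.arange(1, k + 1)
    cdf = stats.beta.cdf(u_sorted, j, k - j + 1)
    cdf = np.where(u_sorted <= alpha, cdf, np.inf)
    rho = cdf.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def rra_rho(gene_guide_ranks, n_total_guides: int, alpha: float = DEFAULT_ALPHA) -> float:
    """RRA rho score for one gene's guide ranks within a list of n_total_guides."""
    ranks = np.asarray(gene_guide_ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("gene has no guide ranks")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if np.any(ranks != np.round(ranks)) or np.any(ranks < 1) or np.any(ranks > n_total_guides):
        raise ValueError(f"ranks must be integers in [1, {n_total_guides}]")
    if len(np.unique(ranks)) != ranks.size:
        raise ValueError("duplicate guide ranks")
    u = np.sort(ranks / n_total_guides)[None, :]
    return float(_rho_from_sorted_u(u, alpha)[0])


def _sample_rank_sets(rng: np.random.Generator, n_perm: int, k: int, n_total: int) -> np.ndarray:
    """(n_perm, k) rank draws without replacement from 1..n_total."""
    draws = rng.integers(1, n_total + 1, size=(n_perm, k))
    while True:
        sorted_rows = np.sort(draws, axis=1)
        dup = (np.diff(sorted_rows, axis=1) == 0).any(axis=1) if k > 1 else np.zeros(n_perm, bool)
        if not dup.any():
            return draws
        draws[dup] = rng.integers(1, n_total + 1, size=(int(dup.sum()), k))


def null_rho_distribution(
    k: int, n_total: int, alpha: float, n_perm: int, seed: int
) -> np.ndarray:
    """Permutation null: rho of k uniform-random distinct ranks, n_perm times."""
    if k > n_total:
        raise ValueError("a gene cannot have more guides than the ranked list")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    draws = _sample_rank_sets(rng, n_perm, k, n_total)
    u = np.sort(draws / n_total, axis=1)
    return _rho_from_sorted_u(u, alpha)


def rra_permutation_p(
    rho_observed: float,
    k: int,
    n_total: int,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> float:
    """Add-one permutation p-value: (1 + #{rho_null <= rho_obs}) / (1 + n_perm)."""
    null = null_rho_distribution(k, n_total, alpha, n_perm, seed)
    return (1 + int(np.sum(null <= rho_observed))) / (1 + n_perm)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in the p-value order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_guides(
    guide_scores: pd.DataFrame, score_col: str, direction: str = "depletion"
) -> pd.DataFrame:
    """Assign integer ranks 1..n to guides by score.

    Depletion ranks ascending (most negative first), enrichment descending.
    NaN scores sort last; ties break lexicographically on guide_id.
    """
    if direction not in ("depletion", "enrichment"):
        raise ValueError("direction must be 'depletion' or 'enrichment'")
    df = guide_scores.copy()
    key = df[score_col] if direction == "depletion" else -df[score_col]
    df["_key"] = key.fillna(np.inf)
    df = df.sort_values(["_key", "guide_id"], kind="mergesort").reset_index(drop=True)
    df["guide_rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_key")


def rank_genes(
    guide_scores: pd.DataFrame,
    gene_map: pd.DataFrame,
    score_col: str = "score",
    direction: str = "depletion",
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> pd.DataFrame:
    """Full gene-ranking stage over a guide-level score table.

    Guides are ranked (see :func:`rank_guides`) across the *whole* scored
    list, including non-targeting guides if present; genes come from
    ``gene_map`` (gene, guide_id).  Returns one row per gene with rho,
    permutation p, BH FDR and the final rank (ascending rho, ties broken by
    gene name).  Permutation nulls are shared across genes with the same
    guide count, with one seeded substream per count.
    """
    ranked = rank_guides(guide_scores, score_col, direction)
    n_total = len(ranked)
    merged = gene_map[["gene", "guide_id"]].merge(
        ranked[["guide_id", "guide_rank"]], on="guide_id", how="inner"
    )
    if merged.empty:
        raise ValueError("no gene-mapped guides in the scored table")

    mapped = ranked[ranked["guide_id"].isin(gene_map["guide_id"])]
    mean_ssmd = (
        mean_gene_score(mapped, gene_map)
        if "ssmd" in ranked.columns
        else pd.Series(np.nan, index=pd.Index(sorted(merged["gene"].unique()), name="gene"))
    )

    rows = []
    for gene, group in merged.groupby("gene", sort=True):
        rho = rra_rho(group["guide_rank"].to_numpy(), n_total, alpha)
        rows.append((gene, len(group), rho))
    genes = pd.DataFrame(rows, columns=["gene", "n_guides", "rho"])

    ss = np.random.SeedSequence(seed)
    nulls: dict[int, np.ndarray] = {}
    for k, child in zip(sorted(genes["n_guides"].unique()), ss.spawn(genes["n_guides"].nunique())):
        nulls[k] = null_rho_distribution(k, n_total, alpha, n_perm, child.generate_state(1)[0] % 2**31)
    genes["p_perm"] = [
        (1 + int(np.sum(nulls[k] <= rho))) / (1 + n_perm)
        for k, rho in zip(genes["n_guides"], genes["rho"])
    ]
    genes["fdr"] = bh_fdr(genes["p_perm"].to_numpy())
    genes["mean_ssmd"] = genes["gene"].map(mean_ssmd)
    genes = genes.sort_values(["rho", "gene"], kind="mergesort").reset_index(drop=True)
    genes["rank"] = np.arange(1, len(genes) + 1)
    genes["direction"] = direction
    return genes[GENE_COLUMNS]
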