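"""Accuracy / precision / power metrics and the method-comparison harness.

Three metrics summarize how well a ranked gene list recovers truth and how
well two replicates agree:

* **accuracy** -- ranks (and their median) of known positive-control genes
  in the depletion ranking;
* **precision** -- percent overlap of the top-ranked 5% of genes between
  two replicates;
* **power** -- number and overlap of hit genes below an FDR cutoff
  (default 1%).

:func:`run_comparison` applies the full pipeline (subsample -> filter ->
normalize -> [bin] -> score -> gene rank) for each analysis mode (TCA,
IRA/SSMD, LDA) and screen size (full, quarter = RSLs starting A/C/G/T,
sixteenth = AA/AC/AG/AT) and tabulates all three metrics in tidy form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rslscreen.dropout import lda_guide_scores
from rslscreen.generank import rank_genes
from rslscreen.library import GuideLibrary
from rslscreen.scoring import ira_guide_scores, tca_guide_scores
from rslscreen.tables import (
    DEFAULT_MIN_PAIR_TOTAL,
    bin_by_prefix,
    filter_low_counts,
    normalize,
    subsample_by_prefix,
)

METHODS = ("tca", "ira", "lda")

#: Screen-size tag -> (subsample prefix length, selected prefixes).
SCREEN_SIZES: dict[str, tuple[int, list[str]] | None] = {
    "full": None,
    "quarter": (1, ["A", "C", "G", "T"]),
    "sixteenth": (2, ["AA", "AC", "AG", "AT"]),
}

#: Binning depth per screen size: chosen so each subsample still yields
#: multiple internal replicates (prefix positions inside the subsample
#: prefix carry no information).
BIN_PREFIX_BY_SIZE = {"full": 2, "quarter": 3, "sixteenth": 3}


def control_ranks(ranked_genes: pd.DataFrame, positives: set[str]) -> tuple[pd.Series, float]:
    """Ranks of the positive-control genes and their median.

    ``ranked_genes`` needs columns gene and rank; every positive must be
    present in the list.
    """
    missing = set(positives) - set(ranked_genes["gene"])
    if missing:
        raise ValueError(f"positive controls absent from ranking: {sorted(missing)[:5]}")
    sub = ranked_genes.loc[ranked_genes["gene"].isin(positives)]
    ranks = sub.set_index("gene")["rank"]
    return ranks, float(np.median(ranks))


def top_fraction_overlap(
    list_a: pd.DataFrame, list_b: pd.DataFrame, fraction: float = 0.05
) -> float:
    """Percent overlap of the top-ranked fraction of genes of two lists.

    k = floor(fraction * n_genes) genes are compared (5% of 2,325 genes is
    116).  Both lists must rank the same gene universe.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if set(list_a["gene"]) != set(list_b["gene"]):
        raise ValueError("gene universes differ between the two rankings")
    k = math.floor(fraction * len(list_a))
    if k == 0:
        raise ValueError("fraction too small: top set is empty")
    top_a = set(list_a.nsmallest(k, "rank")["gene"])
    top_b = set(list_b.nsmallest(k, "rank")["gene"])
    return 100.0 * len(top_a & top_b) / k


def fdr_hit_overlap(
    results_a: pd.DataFrame, results_b: pd.DataFrame, fdr_cut: float = 0.01
) -> tuple[int, int, int]:
    """(hits in a, hits in b, overlap) at an FDR cutoff, depletion direction."""

    def hits(df: pd.DataFrame) -> set[str]:
        mask = df["fdr"] < fdr_cut
        if "direction" in df.columns:
            mask &= df["direction"] == "depletion"
        return set(df.loc[mask, "gene"])

    a, b = hits(results_a), hits(results_b)
    return len(a), len(b), len(a & b)


@dataclass(frozen=True)
class ComparisonConfig:
    """Pipeline knobs for :func:`run_comparison` (see module docstring)."""

    min_pair_total: int = DEFAULT_MIN_PAIR_TOTAL
    fraction: float = 0.05
    fdr_cut: float = 0.01
    alpha: float = 0.25
    # at a 1% FDR over a few hundred genes the permutation p floor
    # 1/(n_perm+1) must sit well below fdr_cut; 10k matches the gene-ranking
    # stage default
    n_perm: int = 10_000
    seed: int = 0


def rank_genes_for_method(
    matrix: pd.DataFrame,
    library: GuideLibrary,
    method: str,
    bin_prefix_len: int = 2,
    config: ComparisonConfig = ComparisonConfig(),
) -> pd.DataFrame:
    """Run one analysis mode on a raw (already subsampled) matrix.

    Filtering, normalization and (for IRA) binning happen inside, so the
    caller passes raw counts.  Returns the depletion gene ranking.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    filtered = filter_low_counts(matrix, config.min_pair_total)
    gene_map = library.gene_map
    if method == "tca":
        scores = tca_guide_scores(filtered)
        score_col = "es"
    elif method == "ira":
        binned = bin_by_prefix(normalize(filtered), bin_prefix_len)
        scores = ira_guide_scores(binned, library)
        score_col = "score"
    else:  # lda
        scores = lda_guide_scores(filtered)
        score_col = "es_lineages"
        gene_map = gene_map[gene_map["guide_id"].isin(scores["guide_id"])]
    return rank_genes(
        scores,
        gene_map,
        score_col=score_col,
        direction="depletion",
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
    )


def run_comparison(
    replicate_matrices: dict[str, pd.DataFrame],
    library: GuideLibrary,
    positives: set[str],
    methods=METHODS,
    screen_sizes=("full", "quarter", "sixteenth"),
    config: ComparisonConfig = ComparisonConfig(),
) -> pd.DataFrame:
    """Tabulate accuracy, precision and power per method and screen size.

    For each subsample group of a screen size, every replicate matrix is
    re-analyzed from raw counts.  Accuracy rows carry the median positive-
    control rank per replicate (averaged over groups); precision/power rows
    compare the same group across replicate pairs.  Returns tidy rows:
    method, size, group, comparison, metric, value.
    """
    if len(replicate_matrices) < 2:
        raise ValueError("need at least two replicate matrices")
    rep_names = list(replicate_matrices)
    rows: list[tuple] = []
    for size in screen_sizes:
        if size not in SCREEN_SIZES:
            raise ValueError(f"unknown screen size {size!r}")
        split = SCREEN_SIZES[size]
        groups = [None] if split is None else [(split[0], [p]) for p in split[1]]
        bin_len = BIN_PREFIX_BY_SIZE[size]
        for method in methods:
            rankings: dict[tuple[str, str], pd.DataFrame] = {}
            for rep in rep_names:
                for group in groups:
                    label = "all" if group is None else group[1][0]
                    sub = (
                        replicate_matrices[rep]
                        if group is None
                        else subsample_by_prefix(replicate_matrices[rep], group[0], group[1])
                    )
                    rankings[(rep, label)] = rank_genes_for_method(
                        sub, library, method, bin_prefix_len=bin_len, config=config
                    )
            for (rep, label), ranking in rankings.items():
                present = positives & set(ranking["gene"])
                _, med = control_ranks(ranking, present)
                rows.append((method, size, label, rep, "median_control_rank", med))
            labels = sorted({lbl for _, lbl in rankings})
            for label in labels:
                a, b = rankings[(rep_names[0], label)], rankings[(rep_names[1], label)]
                pair = f"{rep_names[0]}|{rep_names[1]}"
                rows.append(
                    (method, size, label, pair, "top_fraction_overlap_pct",
                     top_fraction_overlap(a, b, config.fraction))
                )
                n_a, n_b, n_both = fdr_hit_overlap(a, b, config.fdr_cut)
                rows.append((method, size, label, pair, "n_hits_a", float(n_a)))
                rows.append((method, size, label, pair, "n_hits_b", float(n_b)))
                rows.append((method, size, label, pair, "hit_overlap", float(n_both)))
    return pd.DataFrame(
        rows, columns=["method", "size", "group", "comparison", "metric", "value"]
    )
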