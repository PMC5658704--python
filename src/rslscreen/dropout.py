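"""Lineage dropout analysis (LDA).

The most direct readout of a guide's effect on viability is how many of
its RSL-labelled cell lineages vanish between the control (Day 4) and
treatment (Day 28) time points.  An RSL-guide is a *dropout* when it has
fewer than two raw reads at the treatment time point; symmetrically, a
lineage counts as *present at Day 4* only with at least two control reads,
since a single read is indistinguishable from a sequencing artifact.

Per guide we report the number of Day-4 lineages, survivors, the fraction
lost, and a lineage-count effect size es_lineages =
log2((n_day28 + 1)/(n_day4 + 1)) (pseudo-count 1 handles total loss).
Guides are ranked by es_lineages ascending (most loss first).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN_PRESENT = 2

SUMMARY_COLUMNS = [
    "guide_id",
    "n_day4",
    "n_day28",
    "n_lost",
    "fraction_lost",
    "n_late",
    "es_lineages",
]


def call_dropouts(matrix: pd.DataFrame, min_present: int = DEFAULT_MIN_PRESENT) -> pd.DataFrame:
    """Flag each lineage row of a raw, filtered matrix.

    Adds boolean columns: ``present_day4`` (control >= min_present),
    ``present_day28`` (treatment >= min_present) and ``dropout``
    (present at Day 4 but not at Day 28).
    """
    if min_present < 1:
        raise ValueError("min_present must be >= 1")
    out = matrix.copy()
    out["present_day4"] = out["control"] >= min_present
    out["present_day28"] = out["treatment"] >= min_present
    out["dropout"] = out["present_day4"] & ~out["present_day28"]
    return out


def guide_dropout_summary(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-guide lineage tallies from :func:`call_dropouts` output.

    ``n_day4``/``n_day28`` count lineages present at each time point among
    those present at Day 4; late-appearing lineages (present only at Day
    28) are reported separately as ``n_late`` and never inflate survival.
    Guides with no Day-4 lineage are excluded (their fraction is undefined)
    but still appear with n_day4 = 0 and NaN fraction so callers can report
    them.
    """
    required = {"present_day4", "present_day28", "dropout"}
    if not required <= set(flags.columns):
        raise ValueError("run call_dropouts first")
    grouped = flags.groupby("guide_id", sort=True)
    summary = pd.DataFrame(
        {
            "n_day4": grouped["present_day4"].sum(),
            "n_lost": grouped["dropout"].sum(),
            "n_late": grouped.apply(
                lambda g: int((~g["present_day4"] & g["present_day28"]).sum()),
                include_groups=False,
            ),
        }
    ).reset_index()
    summary["n_day28"] = summary["n_day4"] - summary["n_lost"]
    with np.errstate(invalid="ignore", divide="ignore"):
        summary["fraction_lost"] = np.where(
            summary["n_day4"] > 0, summary["n_lost"] / summary["n_day4"], np.nan
        )
    summary["es_lineages"] = np.log2((summary["n_day28"] + 1) / (summary["n_day4"] + 1))
    return summary[SUMMARY_COLUMNS]


def lda_guide_scores(
    matrix: pd.DataFrame, min_present: int = DEFAULT_MIN_PRESENT
) -> pd.DataFrame:
    """Dropout summary ranked for hit calling: es_lineages ascending.

    Guides without any Day-4 lineage are dropped from the ranking (there
    is nothing to lose); ties break lexicographically on guide_id.
    """
    summary = guide_dropout_summary(call_dropouts(matrix, min_present=min_present))
    ranked = summary[summary["n_day4"] > 0].copy()
    return ranked.sort_values(["es_lineages", "guide_id"], kind="mergesort").reset_index(drop=True)


def gene_dropout_fraction(summaries: pd.DataFrame, gene_map: pd.DataFrame) -> pd.Series:
    """Mean fraction of lineages lost per gene, over guides with Day-4 lineages.

    ``gene_map`` is a two-column (gene, guide_id) table; every summarized
    guide must map to exactly one gene.  Genes whose guides all lack Day-4
    lineages get NaN.
    """
    if gene_map["guide_id"].duplicated().any():
        dup = gene_map.loc[gene_map["guide_id"].duplicated(), "guide_id"].unique()
        raise ValueError(f"guides mapped to multiple genes: {list(dup[:5])}")
    merged = summaries.merge(gene_map[["gene", "guide_id"]], on="guide_id", how="left")
    unmapped = merged.loc[merged["gene"].isna(), "guide_id"].unique()
    if len(unmapped):
        raise ValueError(f"guides missing from gene map: {list(unmapped[:5])}")
    eligible = merged[merged["n_day4"] > 0]
    fractions = eligible.groupby("gene")["fraction_lost"].mean()
    all_genes = pd.Index(sorted(merged["gene"].unique()), name="gene")
    return fractions.reindex(all_genes)
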