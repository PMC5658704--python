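"""Effect sizes and robust guide-set statistics (IRA/SSMD) plus the TCA baseline.

Per unit j (an RSL lineage or an internal-replicate bin) of guide-set i the
effect size is the pseudo-counted log2 fold change

    ES_ij = log2((t'_ij + 1) / (c'_ij + 1)).

Guide-set i is summarized robustly by its median effect size
MES_i = median_j ES_ij and scaled median absolute deviation
MAD_i = 1.4826 * median_j |ES_ij - MES_i| (1.4826 = 1/Phi^-1(3/4) makes the
MAD consistent for the SD under normality).  Against the pooled
non-targeting null (MES_CON, MAD_CON) the strictly standardized mean
difference is

    SSMD_i = (MES_i - MES_CON) / sqrt(MAD_i^2 + MAD_CON^2),

and the ranking score Score_i = MES_i * |SSMD_i| re-weights toward effect
size; it is negative for depleted and positive for enriched guide-sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rslscreen.library import GuideLibrary
from rslscreen.tables import normalize, unit_column

#: 1 / Phi^-1(0.75): scales the MAD to estimate the SD under normality.
MAD_SCALE = 1.4826

DEFAULT_PSEUDOCOUNT = 1.0

#: Guides with fewer surviving units than this are flagged low-confidence.
DEFAULT_MIN_UNITS = 5

#: Default |z| cutoff (vs non-targeting score distribution) for hit flags.
DEFAULT_Z_THRESHOLD = 3.0


@dataclass(frozen=True)
class ControlStats:
    """Pooled non-targeting null: a single MES/MAD over all control units."""

    mes_con: float
    mad_con: float
    n_control_units: int
    score_mean: float = float("nan")
    score_sd: float = float("nan")


def effect_sizes(matrix: pd.DataFrame, pseudo: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Add an ``es`` column: log2((treatment + pseudo)/(control + pseudo))."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    if (matrix["control"] < 0).any() or (matrix["treatment"] < 0).any():
        raise ValueError("counts must be non-negative")
    out = matrix.copy()
    out["es"] = np.log2((out["treatment"] + pseudo) / (out["control"] + pseudo))
    return out


def guide_stats(es_values) -> tuple[float, float]:
    """(MES, MAD) of one guide-set's effect sizes.

    Median of an even number of units is the mean of the two central order
    statistics; MAD is scaled by 1.4826.
    """
    values = np.asarray(es_values, dtype=float)
    if values.size == 0:
        raise ValueError("guide-set has no units")
    mes = float(np.median(values))
    mad = MAD_SCALE * float(np.median(np.abs(values - mes)))
    return mes, mad


def control_stats(
    control_es,
    control_scores=None,
) -> ControlStats:
    """Null statistics over the *pooled* non-targeting units.

    MES_CON and MAD_CON are computed over all control units pooled across
    control guide-sets (not per-guide then aggregated).  If per-control-
    guide ranking scores are supplied their mean and SD are recorded for
    guide-level z-scores.
    """
    values = np.asarray(control_es, dtype=float)
    if values.size == 0:
        raise ValueError(
            "no non-targeting control units: supply an external null or a library with controls"
        )
    mes_con, mad_con = guide_stats(values)
    score_mean = score_sd = float("nan")
    if control_scores is not None:
        scores = np.asarray(control_scores, dtype=float)
        scores = scores[np.isfinite(scores)]
        if scores.size:
            score_mean = float(np.mean(scores))
            score_sd = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    return ControlStats(mes_con, mad_con, values.size, score_mean, score_sd)


def ssmd(mes_i: float, mad_i: float, controls: ControlStats) -> float:
    """SSMD of one guide-set vs the control null; NaN when both MADs are 0."""
    denom = math.sqrt(mad_i**2 + controls.mad_con**2)
    if denom == 0.0:
        return 0.0 if mes_i == controls.mes_con else float("nan")
    return (mes_i - controls.mes_con) / denom


def ranking_score(mes_i: float, ssmd_i: float) -> float:
    """Score = MES * |SSMD|; NaN propagates from an undefined SSMD."""
    return mes_i * abs(ssmd_i)


def ira_guide_scores(
    matrix: pd.DataFrame,
    library: GuideLibrary,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    min_units: int = DEFAULT_MIN_UNITS,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Score every guide-set of a normalized (usually binned) matrix.

    Returns one row per guide: gene, n_units, mes, mad, ssmd, score, z and
    flags.  Guides with undefined SSMD (both MADs zero, MES differing from
    the null) keep score = NaN and are flagged ``undefined_ssmd``; they
    remain rankable by MES.  ``z`` standardizes the score against the mean
    and SD of the non-targeting guide-sets' scores.
    """
    unit = unit_column(matrix)
    es = effect_sizes(matrix, pseudo=pseudo)
    es = es.merge(library.entries[["guide_id", "gene", "is_control"]], on="guide_id", how="left")
    unknown = es.loc[es["gene"].isna(), "guide_id"].unique()
    if len(unknown):
        raise ValueError(f"guides absent from library: {list(unknown[:5])}")

    control_units = es.loc[es["is_control"], "es"]
    rows = []
    for gid, group in es.groupby("guide_id", sort=True):
        mes, mad = guide_stats(group["es"].to_numpy())
        rows.append((gid, group["gene"].iloc[0], bool(group["is_control"].iloc[0]), len(group), mes, mad))
    scores = pd.DataFrame(rows, columns=["guide_id", "gene", "is_control", "n_units", "mes", "mad"])

    null = control_stats(control_units.to_numpy())
    scores["ssmd"] = [ssmd(m, s, null) for m, s in zip(scores["mes"], scores["mad"])]
    scores["score"] = scores["mes"] * scores["ssmd"].abs()

    ctrl_scores = scores.loc[scores["is_control"], "score"]
    null = control_stats(control_units.to_numpy(), ctrl_scores.to_numpy())
    if null.score_sd and null.score_sd > 0:
        scores["z"] = (scores["score"] - null.score_mean) / null.score_sd
    else:
        scores["z"] = float("nan")

    flags = []
    for _, row in scores.iterrows():
        f = []
        if not np.isfinite(row["ssmd"]):
            f.append("undefined_ssmd")
        if row["n_units"] < min_units:
            f.append("low_units")
        if np.isfinite(row["z"]) and abs(row["z"]) >= z_threshold:
            f.append("hit")
        flags.append(",".join(f))
    scores["flags"] = flags
    scores.attrs["control_stats"] = null
    scores.attrs["unit"] = unit
    return scores


def tca_guide_scores(matrix: pd.DataFrame, pseudo: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Total-count baseline: per-guide read sums, normalized, pseudo-counted ES.

    RSL information is discarded; counts are summed over all lineages of a
    guide, guide-level totals are normalized with the same total-read-count
    formula, and the log2 fold change uses pseudo-count 1.  The returned
    frame is sorted by ES ascending (strongest depletion first), ties broken
    by guide_id.
    """
    totals = (
        matrix.groupby("guide_id", as_index=False, sort=True)[["control", "treatment"]].sum()
    )
    totals["rsl"] = "total"  # satisfy normalize()'s matrix contract
    normed = normalize(totals)
    normed = effect_sizes(normed, pseudo=pseudo)
    out = normed[["guide_id", "control", "treatment", "es"]].copy()
    return out.sort_values(["es", "guide_id"], kind="mergesort").reset_index(drop=True)
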