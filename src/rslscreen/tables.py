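"""Count-matrix construction, filtering, normalization, binning, subsampling.

The central object is a long-format count matrix: one row per (guide, RSL)
lineage with a control-time-point count ``control`` (Day 4 after
transduction) and a treatment count ``treatment`` (Day 28).  Binning by RSL
prefix turns lineages into internal pseudo-replicates (4, 16 or 64 bins
for prefix lengths 1-3); subsampling by RSL prefix emulates a smaller
screen run at lower sequencing depth.

Pipeline order: filter raw pair totals first, then normalize to total read
count, then bin.
"""

from __future__ import annotations

import pandas as pd

from rslscreen.counting import COUNT_COLUMNS

MATRIX_COLUMNS = ["guide_id", "rsl", "control", "treatment"]
BINNED_COLUMNS = ["guide_id", "bin", "control", "treatment"]

#: Pair-total filter below which a lineage is removed before analysis.
DEFAULT_MIN_PAIR_TOTAL = 5

NORMALIZATION_RTOL = 1e-9


def unit_column(matrix: pd.DataFrame) -> str:
    """Name of the per-guide unit key: 'rsl' for lineages, 'bin' after binning."""
    if "rsl" in matrix.columns:
        return "rsl"
    if "bin" in matrix.columns:
        return "bin"
    raise ValueError("matrix has neither an 'rsl' nor a 'bin' column")


def _sorted(matrix: pd.DataFrame) -> pd.DataFrame:
    unit = unit_column(matrix)
    return matrix.sort_values(["guide_id", unit], kind="mergesort").reset_index(drop=True)


def build_matrix(
    records: pd.DataFrame, control_sample: str, treatment_sample: str
) -> pd.DataFrame:
    """Pivot count records into a (guide, rsl) x {control, treatment} matrix.

    Full outer join on (guide, rsl): a lineage seen in only one sample gets
    a zero in the other column.
    """
    if control_sample == treatment_sample:
        raise ValueError("control and treatment sample names must differ")
    missing = [c for c in COUNT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"count records missing columns: {missing}")
    subset = records[records["sample"].isin([control_sample, treatment_sample])]
    if len(subset) == 0:
        return pd.DataFrame(columns=MATRIX_COLUMNS).astype({"control": int, "treatment": int})
    wide = subset.pivot_table(
        index=["guide_id", "rsl"], columns="sample", values="count", fill_value=0, aggfunc="sum"
    )
    for name in (control_sample, treatment_sample):
        if name not in wide.columns:
            wide[name] = 0
    wide = wide.rename(columns={control_sample: "control", treatment_sample: "treatment"})
    out = wide.reset_index()[MATRIX_COLUMNS]
    out.columns.name = None
    return _sorted(out.astype({"control": int, "treatment": int}))


def filter_low_counts(matrix: pd.DataFrame, min_pair_total: int = DEFAULT_MIN_PAIR_TOTAL) -> pd.DataFrame:
    """Drop rows whose control + treatment sum is below ``min_pair_total``.

    The default 5 removes lineages whose pair total is less than five;
    a row summing to exactly 5 is retained.
    """
    if min_pair_total < 0:
        raise ValueError("min_pair_total must be non-negative")
    keep = (matrix["control"] + matrix["treatment"]) >= min_pair_total
    return matrix.loc[keep].reset_index(drop=True)


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale both columns to the common target total (sum of both halves)/2.

    c' = c * [Σ(c+t)/2] / Σc and t' = t * [Σ(c+t)/2] / Σt, so that after
    normalization Σc' == Σt'.  Zero counts stay zero.
    """
    total_c = float(matrix["control"].sum())
    total_t = float(matrix["treatment"].sum())
    for name, total in (("control", total_c), ("treatment", total_t)):
        if total <= 0:
            raise ValueError(f"cannot normalize: column '{name}' has zero total reads")
    target = (total_c + total_t) / 2.0
    out = matrix.copy()
    out["control"] = matrix["control"] * (target / total_c)
    out["treatment"] = matrix["treatment"] * (target / total_t)
    return out


def bin_by_prefix(matrix: pd.DataFrame, prefix_len: int) -> pd.DataFrame:
    """Sum counts within (guide, RSL prefix) to form internal replicates.

    Prefix lengths 1/2/3 give at most 4/16/64 bins per guide.  Bins with no
    surviving member lineage are absent rather than materialized as zeros.
    """
    if prefix_len not in (1, 2, 3):
        raise ValueError("prefix_len must be 1, 2 or 3")
    if "rsl" not in matrix.columns:
        raise ValueError("bin_by_prefix requires an RSL-level matrix")
    if len(matrix) == 0:
        return pd.DataFrame(columns=BINNED_COLUMNS)
    out = matrix.copy()
    out["bin"] = out["rsl"].str[:prefix_len]
    out = (
        out.groupby(["guide_id", "bin"], as_index=False, sort=True)[["control", "treatment"]]
        .sum()
    )
    return out[BINNED_COLUMNS]


def subsample_by_prefix(
    matrix: pd.DataFrame, prefix_len: int, selected_prefixes: set[str] | list[str]
) -> pd.DataFrame:
    """Keep only rows whose RSL starts with one of the selected prefixes.

    Raw counts are unchanged; downstream normalization must be recomputed
    within the subsample.  Splitting on all prefixes of a given length
    partitions the matrix (e.g. {A},{C},{G},{T} for quarter-size screens,
    {AA,AC,AG,AT} for sixteenth-size).
    """
    selected = set(selected_prefixes)
    if not selected:
        raise ValueError("selected_prefixes must be non-empty")
    if any(len(p) != prefix_len for p in selected):
        raise ValueError(f"all selected prefixes must have length {prefix_len}")
    if "rsl" not in matrix.columns:
        raise ValueError("subsample_by_prefix requires an RSL-level matrix")
    keep = matrix["rsl"].str[:prefix_len].isin(selected)
    return matrix.loc[keep].reset_index(drop=True)


def matrix_to_records(
    matrix: pd.DataFrame, control_sample: str, treatment_sample: str
) -> pd.DataFrame:
    """Inverse of :func:`build_matrix`: long count records, zero rows dropped."""
    frames = []
    for col, name in (("control", control_sample), ("treatment", treatment_sample)):
        part = matrix.loc[matrix[col] > 0, ["guide_id", "rsl", col]].copy()
        part["sample"] = name
        part = part.rename(columns={col: "count"})
        frames.append(part[COUNT_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out["count"] = out["count"].astype(int)
    return out.sort_values(["guide_id", "rsl", "sample"], kind="mergesort").reset_index(drop=True)
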