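"""Counting (guide, RSL) lineages from raw sequencing reads.

The sequencing recipe produces, for every cluster, a 20-cycle guide read
from a custom primer plus two 6-cycle index reads: the sample index (i5)
and the RSL (i7).  Counting therefore consumes three positionally
synchronized FASTQ streams and emits one count record per observed
(guide, RSL, sample) triple, alongside QC tallies for every excluded read.

Guide matching is exact by default; an opt-in Hamming-distance-1 mode
assigns a read to the unique library guide within distance 1 and rejects
ambiguous reads (two or more guides within distance 1).
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from rslscreen.library import DNA_ALPHABET, GUIDE_LENGTH, RSL_LENGTH, GuideLibrary

COUNT_COLUMNS = ["guide_id", "rsl", "sample", "count"]

#: Sentinel returned by the matcher for reads near two or more guides.
AMBIGUOUS = "__ambiguous__"


@dataclass
class CountingQC:
    """Read-level tallies; the exclusion categories partition all reads.

    Precedence when a read fails several checks: N in guide/RSL, then
    unmatched sample index, then guide matching (unmatched or ambiguous).
    """

    total_reads: int = 0
    matched: int = 0
    unmatched_index: int = 0
    unmatched_guide: int = 0
    ambiguous_guide: int = 0
    discarded_N: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        parts = (
            self.matched
            + self.unmatched_index
            + self.unmatched_guide
            + self.ambiguous_guide
            + self.discarded_N
        )
        if parts != self.total_reads:
            raise ValueError(f"QC tallies {parts} do not sum to total_reads {self.total_reads}")
        if sum(self.per_sample.values()) != self.matched:
            raise ValueError("per-sample tallies do not sum to matched reads")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


class GuideMatcher:
    """Exact or Hamming-1 lookup from a 20-mer read to a guide_id."""

    def __init__(self, library: GuideLibrary, max_mismatch: int = 0):
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        self.max_mismatch = max_mismatch
        self._exact = library.sequence_index()
        self._neighbors: dict[str, str] | None = None
        if max_mismatch == 1:
            self._neighbors = self._build_neighbors()

    def _build_neighbors(self) -> dict[str, str]:
        # Map every sequence within Hamming distance <=1 of a guide to that
        # guide, or to AMBIGUOUS if it is near two different guides.
        table: dict[str, str] = {}
        for seq, gid in self._exact.items():
            for variant in _hamming1_neighborhood(seq):
                prev = table.get(variant)
                if prev is None:
                    table[variant] = gid
                elif prev != gid:
                    table[variant] = AMBIGUOUS
        return table

    def match(self, guide_read: str) -> str | None:
        """Return the guide_id, or None for no-match/ambiguous reads."""
        if self.max_mismatch == 0:
            return self._exact.get(guide_read)
        hit = self._neighbors.get(guide_read)
        return None if hit == AMBIGUOUS else hit

    def classify(self, guide_read: str) -> tuple[str | None, bool]:
        """Return (guide_id or None, ambiguous flag)."""
        if self.max_mismatch == 0:
            return self._exact.get(guide_read), False
        hit = self._neighbors.get(guide_read)
        if hit == AMBIGUOUS:
            return None, True
        return hit, False


def _hamming1_neighborhood(seq: str) -> Iterator[str]:
    yield seq
    for i, base in enumerate(seq):
        for other in "ACGT":
            if other != base:
                yield seq[:i] + other + seq[i + 1 :]


def match_guide(guide_read: str, library: GuideLibrary, max_mismatch: int = 0) -> str | None:
    """Match one 20-base read against the library; None if no unique match.

    With ``max_mismatch=1`` a read within Hamming distance 1 of two or more
    guides is ambiguous and returns None.  Reads containing characters
    outside ACGT never match.
    """
    if len(guide_read) != GUIDE_LENGTH:
        raise ValueError(f"guide read must be {GUIDE_LENGTH} nt, got {len(guide_read)}")
    return GuideMatcher(library, max_mismatch).match(guide_read.upper())


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id(header: str) -> str:
    # Compare the id up to the first whitespace, dropping a /1-style suffix.
    token = header.split(None, 1)[0]
    if len(token) > 2 and token[-2] == "/":
        token = token[:-2]
    return token


def count_rsl_guides(
    guide_fastq,
    rsl_fastq,
    library: GuideLibrary,
    index_fastq=None,
    sample_map: dict[str, str] | None = None,
    sample: str | None = None,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, CountingQC]:
    """Count (guide, RSL, sample) read triplets into count records.

    Parameters
    ----------
    guide_fastq, rsl_fastq
        FASTQ paths (optionally .gz) or open text handles for the 20-base
        guide read and the 6-base RSL index read, in the same read order.
    index_fastq, sample_map
        The 6-base sample-index read plus an exact index->sample mapping.
        Omit both for pre-demultiplexed input and pass ``sample`` instead.
    max_mismatch
        0 (exact, default) or 1 (unique Hamming-1 match, ambiguity rejected).

    Returns
    -------
    (records, qc)
        ``records`` is a DataFrame with columns guide_id, rsl, sample,
        count, sorted lexicographically; every emitted count is >= 1.
    """
    if len(library) == 0:
        raise ValueError("empty guide library")
    if index_fastq is None:
        if sample is None:
            raise ValueError("pre-demultiplexed input requires a sample name")
    else:
        if not sample_map:
            raise ValueError("index_fastq given without a sample_map")
        if len(set(sample_map)) != len(sample_map):
            raise ValueError("sample_map indices not unique")

    matcher = GuideMatcher(library, max_mismatch)
    qc = CountingQC()
    tallies: Counter[tuple[str, str, str]] = Counter()

    guide_iter = FastqGeneralIterator(_open_text(guide_fastq))
    rsl_iter = FastqGeneralIterator(_open_text(rsl_fastq))
    idx_iter = FastqGeneralIterator(_open_text(index_fastq)) if index_fastq is not None else None

    sentinel = object()
    streams = [guide_iter, rsl_iter] + ([idx_iter] if idx_iter is not None else [])
    while True:
        rows = [next(s, sentinel) for s in streams]
        if all(r is sentinel for r in rows):
            break
        if any(r is sentinel for r in rows):
            raise ValueError("desynchronized FASTQ streams: unequal read counts")
        ids = {_read_id(r[0]) for r in rows}
        if len(ids) != 1:
            raise ValueError(f"desynchronized FASTQ streams: read ids differ ({sorted(ids)})")
        qc.total_reads += 1

        guide_read = rows[0][1].upper()
        rsl_read = rows[1][1].upper()
        if set(guide_read) - DNA_ALPHABET or set(rsl_read) - DNA_ALPHABET:
            qc.discarded_N += 1
            continue
        if len(rsl_read) != RSL_LENGTH:
            raise ValueError(f"RSL read of length {len(rsl_read)}, expected {RSL_LENGTH}")

        if idx_iter is not None:
            sample_name = sample_map.get(rows[2][1].upper())
            if sample_name is None:
                qc.unmatched_index += 1
                continue
        else:
            sample_name = sample

        gid, ambiguous = matcher.classify(guide_read)
        if gid is None:
            if ambiguous:
                qc.ambiguous_guide += 1
            else:
                qc.unmatched_guide += 1
            continue

        qc.matched += 1
        qc.per_sample[sample_name] = qc.per_sample.get(sample_name, 0) + 1
        tallies[(gid, rsl_read, sample_name)] += 1

    records = records_from_counter(tallies)
    qc.validate()
    return records, qc


def records_from_counter(tallies: Counter | dict) -> pd.DataFrame:
    """Build a normalized count-record frame from {(guide, rsl, sample): n}."""
    if not tallies:
        return pd.DataFrame(columns=COUNT_COLUMNS).astype({"count": int})
    records = pd.DataFrame(
        [(g, r, s, n) for (g, r, s), n in tallies.items()], columns=COUNT_COLUMNS
    )
    return sort_records(records)


def sort_records(records: pd.DataFrame) -> pd.DataFrame:
    return records.sort_values(["guide_id", "rsl", "sample"], kind="mergesort").reset_index(
        drop=True
    )


def write_counts(path, records: pd.DataFrame) -> None:
    """Write count records as TSV (guide_id, rsl, sample, count), sorted."""
    missing = [c for c in COUNT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"count records missing columns: {missing}")
    sort_records(records.loc[:, COUNT_COLUMNS]).to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_counts`; raises with the line number on bad rows."""
    df = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "rsl": str, "sample": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != counts.round())]
    if len(bad):
        # +2: one for the header, one for 1-based numbering.
        raise ValueError(f"{path}: malformed count at line {bad[0] + 2}")
    df["count"] = counts.astype(int)
    return sort_records(df)
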