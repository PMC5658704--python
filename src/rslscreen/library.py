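"""Guide library container and I/O.

A guide library is the table of sgRNA sequences used in the screen: one row
per guide with its 20-mer protospacer, target gene, and a flag marking
non-targeting negative controls.  Control guides carry a reserved gene
label (default ``"NonTargeting"``) so that gene-level stages can exclude
them from the gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GUIDE_LENGTH = 20
RSL_LENGTH = 6
DNA_ALPHABET = frozenset("ACGT")

#: Reserved gene label for non-targeting control guides.
CONTROL_GENE = "NonTargeting"

LIBRARY_COLUMNS = ["guide_id", "sequence", "gene", "is_control"]


@dataclass(frozen=True)
class GuideLibrary:
    """Validated table of guides: guide_id, 20-mer sequence, gene, is_control."""

    entries: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"guide library missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("guide library is empty")
        df = df.loc[:, LIBRARY_COLUMNS].reset_index(drop=True)
        df["sequence"] = df["sequence"].str.upper()
        df["is_control"] = df["is_control"].astype(bool)
        bad_len = df.loc[df["sequence"].str.len() != GUIDE_LENGTH, "guide_id"]
        if len(bad_len):
            raise ValueError(f"guide sequences not {GUIDE_LENGTH} nt: {list(bad_len[:5])}")
        bad_chr = df.loc[~df["sequence"].str.fullmatch("[ACGT]+"), "guide_id"]
        if len(bad_chr):
            raise ValueError(f"guide sequences with non-ACGT characters: {list(bad_chr[:5])}")
        if df["guide_id"].duplicated().any():
            dup = df.loc[df["guide_id"].duplicated(), "guide_id"].unique()
            raise ValueError(f"duplicate guide_ids: {list(dup[:5])}")
        if df["sequence"].duplicated().any():
            dup = df.loc[df["sequence"].duplicated(), "sequence"].unique()
            raise ValueError(f"duplicate guide sequences: {list(dup[:5])}")
        object.__setattr__(self, "entries", df)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def guide_ids(self) -> pd.Series:
        return self.entries["guide_id"]

    @property
    def control_ids(self) -> set[str]:
        df = self.entries
        return set(df.loc[df["is_control"], "guide_id"])

    @property
    def gene_map(self) -> pd.DataFrame:
        """Two-column (gene, guide_id) mapping, targeting guides only."""
        df = self.entries.loc[~self.entries["is_control"], ["gene", "guide_id"]]
        return df.reset_index(drop=True)

    def sequence_index(self) -> dict[str, str]:
        """Mapping sequence -> guide_id for exact-match lookup."""
        return dict(zip(self.entries["sequence"], self.entries["guide_id"]))

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str, bool]]) -> "GuideLibrary":
        return cls(pd.DataFrame.from_records(records, columns=LIBRARY_COLUMNS))

    @classmethod
    def read_table(cls, path) -> "GuideLibrary":
        """Read a TSV/CSV guide table with columns guide_id, sequence, gene, is_control."""
        sep = "," if str(path).endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, dtype={"guide_id": str, "sequence": str, "gene": str})
        return cls(df)

    def to_table(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)
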