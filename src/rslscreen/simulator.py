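"""Lineage-resolved pooled-screen simulator with ground truth.

The model follows the lineage picture of an RSL screen: every transduced
founder cell carries one guide and one 6-bp RSL, and its clonal progeny is
tracked from transduction to the Day-4 (control) and Day-28 (treatment)
harvests.  Generations are discrete divisions grouped into passages:

* **Transduction** -- founders per (guide, RSL) are Poisson with mean
  ``cells_per_guide / rsl_space``, so most observed RSL-guides represent a
  single cell lineage.
* **Editing kinetics** -- each lineage is edited after a geometric number
  of divisions (``p_edit_per_division``); the repair outcome destroys gene
  function with probability ``guide_efficiency x q_null``.  An effective
  ("null") edit in an essential gene arrests the lineage, which then decays
  by ``survival_after_null`` per division -- early edits produce dropout,
  late edits depletion.
* **Growth variability** -- each lineage keeps a constant per-division
  multiplier ``2 * exp(N(0, sigma_lineage))``, compounding into the broad
  clone-size heterogeneity seen in long cultures.
* **Passaging** -- every ``divisions_per_passage`` divisions the culture is
  reseeded to ``bottleneck_cells`` by Poisson thinning, so small lineages
  can be lost to undersampling at either time point.
* **Sequencing** -- read counts per time point are multinomial over lineage
  cell abundances with ``depth_per_guide x n_guides`` total reads.

All randomness descends from one integer seed through named substreams, so
the library, each replicate screen, and FASTQ emission are independently
reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO

import gzip
import zlib

import numpy as np
import pandas as pd
import yaml

from rslscreen.library import CONTROL_GENE, GuideLibrary
from rslscreen.tables import MATRIX_COLUMNS

_BASES = "ACGT"
_ALL_RSLS = ["".join(p) for p in itertools.product(_BASES, repeat=6)]


@dataclass(frozen=True)
class SimConfig:
    """Screen-simulation parameters (desk-scale defaults; see docs/methods.md)."""

    n_genes: int = 200
    guides_per_gene: int = 10
    n_control_guides: int = 20
    frac_essential: float = 0.1
    cells_per_guide: float = 400.0  # screen size: transduced cells per guide
    rsl_space: int = 256  # distinct RSLs circulating in the library
    p_edit_per_division: float = 0.3
    guide_efficiency_alpha: float = 8.0  # Beta prior on per-guide cutting efficiency
    guide_efficiency_beta: float = 2.0
    q_null: float = 0.7  # P(a cut destroys gene function)
    sigma_lineage: float = 0.04  # per-division log growth-rate SD
    survival_after_null: float = 0.5  # per-division survival of arrested lineages
    n_passages: int = 8
    divisions_per_passage: int = 3
    day4_passage: int = 1  # control harvest taken after this passage
    bottleneck_cells: int | None = None  # default: 4 x total founders
    depth_per_guide: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rsl_space < 1 or self.rsl_space > 4096:
            raise ValueError("rsl_space must be in [1, 4096]")
        for name in ("frac_essential", "p_edit_per_division", "q_null", "survival_after_null"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_genes", "guides_per_gene", "n_control_guides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_genes + self.n_control_guides == 0:
            raise ValueError("library would be empty")
        for name in ("cells_per_guide", "depth_per_guide"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_lineage < 0:
            raise ValueError("sigma_lineage must be non-negative")
        if not (1 <= self.day4_passage < self.n_passages):
            raise ValueError("day4_passage must lie in [1, n_passages)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_guides_total(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_control_guides

    @property
    def effective_bottleneck(self) -> int:
        if self.bottleneck_cells is not None:
            return self.bottleneck_cells
        return int(round(4 * self.cells_per_guide * self.n_guides_total))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class SimLibrary:
    """A simulated guide library plus the per-gene/per-guide ground truth."""

    library: GuideLibrary
    gene_essential: pd.Series = field(repr=False)  # gene -> bool
    guide_efficiency: pd.Series = field(repr=False)  # guide_id -> [0, 1]
    rsl_pool: np.ndarray = field(repr=False)  # distinct 6-mers in circulation


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated screen replicate."""

    genes: pd.DataFrame = field(repr=False)  # gene, essential
    guides: pd.DataFrame = field(repr=False)  # guide_id, gene, is_control, efficiency
    lineages: pd.DataFrame = field(repr=False)  # one row per founder lineage

    @property
    def essential_genes(self) -> set[str]:
        return set(self.genes.loc[self.genes["essential"], "gene"])


def _substream(seed: int, label: str) -> np.random.Generator:
    # crc32 keeps the substream key stable across processes (str hash is salted)
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    return np.random.default_rng(ss)


def _random_unique_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = ["".join(row) for row in rng.choice(list(_BASES), size=(n - len(out), k))]
        for s in draw:
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def simulate_library(config: SimConfig) -> SimLibrary:
    """Draw the guide library, essential-gene set and per-guide efficiencies.

    Deterministic under ``config.seed``: gene/guide names are systematic
    (GENE0001, GENE0001_g01, ...), sequences are unique random 20-mers, and
    ``round(frac_essential * n_genes)`` genes are flagged essential.
    Non-targeting controls have cutting efficiency 0.
    """
    rng = _substream(config.seed, "library")
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    n_essential = int(round(config.frac_essential * config.n_genes))
    essential_genes = set(rng.choice(genes, size=n_essential, replace=False)) if n_essential else set()

    records = []
    for gene in genes:
        for g in range(config.guides_per_gene):
            records.append((f"{gene}_g{g + 1:02d}", gene, False))
    for c in range(config.n_control_guides):
        records.append((f"CTRL_g{c + 1:03d}", CONTROL_GENE, True))
    sequences = _random_unique_kmers(rng, len(records), 20)

    entries = pd.DataFrame(
        {
            "guide_id": [r[0] for r in records],
            "sequence": sequences,
            "gene": [r[1] for r in records],
            "is_control": [r[2] for r in records],
        }
    )
    library = GuideLibrary(entries)

    eff = rng.beta(config.guide_efficiency_alpha, config.guide_efficiency_beta, size=len(entries))
    eff[entries["is_control"].to_numpy()] = 0.0
    efficiency = pd.Series(eff, index=entries["guide_id"], name="efficiency")
    gene_essential = pd.Series(
        {g: g in essential_genes for g in genes} | {CONTROL_GENE: False}, name="essential"
    )
    rsl_pool = np.array(
        sorted(rng.choice(len(_ALL_RSLS), size=config.rsl_space, replace=False))
    )
    rsl_pool = np.array([_ALL_RSLS[i] for i in rsl_pool])
    return SimLibrary(library, gene_essential, efficiency, rsl_pool)


def simulate_screen(
    sim_library: SimLibrary, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Run one screen replicate: transduction, growth, passaging, sequencing.

    Returns a raw count matrix (guide_id, rsl, control=Day4, treatment=Day28;
    rows with zero reads at both time points are dropped) and the
    :class:`SimTruth` with per-lineage fates.  ``seed`` defaults to a
    substream of ``config.seed``; pass distinct seeds for replicates (or use
    :func:`simulate_replicates`).
    """
    rng = np.random.default_rng(seed if seed is not None else _substream(config.seed, "screen"))
    entries = sim_library.library.entries
    n_guides = len(entries)
    n_rsl = len(sim_library.rsl_pool)

    # Transduction: independent Poisson founders per (guide, RSL).
    lam = config.cells_per_guide / n_rsl
    founder_counts = rng.poisson(lam, size=(n_guides, n_rsl))
    guide_idx, rsl_idx = np.nonzero(founder_counts)
    reps = founder_counts[guide_idx, rsl_idx]
    guide_idx = np.repeat(guide_idx, reps)
    rsl_idx = np.repeat(rsl_idx, reps)
    n_founders = len(guide_idx)

    total_divisions = config.n_passages * config.divisions_per_passage
    eff = sim_library.guide_efficiency.to_numpy()[guide_idx]
    essential_gene = (
        entries["gene"].map(sim_library.gene_essential).to_numpy(dtype=bool)[guide_idx]
    )

    # Editing time (divisions completed before the edit) and outcome.
    if config.p_edit_per_division > 0:
        edit_division = rng.geometric(config.p_edit_per_division, size=n_founders) - 1
    else:
        edit_division = np.full(n_founders, total_divisions, dtype=int)
    edited = edit_division < total_divisions
    null_allele = edited & (rng.random(n_founders) < eff * config.q_null)
    lethal = null_allele & essential_gene

    multiplier = 2.0 * np.exp(rng.normal(0.0, config.sigma_lineage, size=n_founders))
    survival = config.survival_after_null

    cells = np.ones(n_founders)
    cells_day4 = np.zeros(n_founders)
    dpp = config.divisions_per_passage
    for passage in range(1, config.n_passages + 1):
        t0 = (passage - 1) * dpp
        grow_divs = np.where(lethal, np.clip(edit_division - t0, 0, dpp), dpp)
        decay_divs = np.where(lethal, dpp - grow_divs, 0)
        cells = cells * multiplier**grow_divs * survival**decay_divs
        total = cells.sum()
        if total > 0:
            keep = min(1.0, config.effective_bottleneck / total)
            cells = rng.poisson(cells * keep).astype(float)
        if passage == config.day4_passage:
            cells_day4 = cells.copy()
    cells_day28 = cells

    total_reads = int(round(config.depth_per_guide * n_guides))
    reads_day4 = _sequence(rng, cells_day4, total_reads)
    reads_day28 = _sequence(rng, cells_day28, total_reads)

    lineages = pd.DataFrame(
        {
            "guide_id": entries["guide_id"].to_numpy()[guide_idx],
            "rsl": sim_library.rsl_pool[rsl_idx],
            "edit_division": np.where(edited, edit_division, -1),
            "outcome": np.select(
                [~edited, null_allele], ["unedited", "null"], default="neutral"
            ),
            "growth_multiplier": multiplier,
            "cells_day4": cells_day4.astype(int),
            "cells_day28": cells_day28.astype(int),
            "reads_day4": reads_day4,
            "reads_day28": reads_day28,
        }
    )
    lineages.insert(2, "founder_id", np.arange(n_founders))

    per_rsl = (
        lineages.groupby(["guide_id", "rsl"], as_index=False)[["reads_day4", "reads_day28"]]
        .sum()
        .rename(columns={"reads_day4": "control", "reads_day28": "treatment"})
    )
    per_rsl = per_rsl[(per_rsl["control"] > 0) | (per_rsl["treatment"] > 0)]
    matrix = per_rsl[MATRIX_COLUMNS].sort_values(
        ["guide_id", "rsl"], kind="mergesort"
    ).reset_index(drop=True)

    genes = (
        sim_library.gene_essential.drop(CONTROL_GENE)
        .rename_axis("gene")
        .reset_index()
    )
    guides = entries[["guide_id", "gene", "is_control"]].copy()
    guides["efficiency"] = sim_library.guide_efficiency.to_numpy()
    return matrix, SimTruth(genes, guides, lineages)


def _sequence(rng: np.random.Generator, cells: np.ndarray, total_reads: int) -> np.ndarray:
    """Multinomial read sampling proportional to lineage cell abundance."""
    total = cells.sum()
    if total <= 0:
        return np.zeros(len(cells), dtype=int)
    return rng.multinomial(total_reads, cells / total)


def simulate_replicates(
    config: SimConfig, n_replicates: int = 2
) -> tuple[SimLibrary, list[tuple[pd.DataFrame, SimTruth]]]:
    """One library, ``n_replicates`` independent transduction/screen runs."""
    sim_library = simulate_library(config)
    ss = np.random.SeedSequence(config.seed, spawn_key=(7919,))
    children = ss.spawn(n_replicates)
    screens = [
        simulate_screen(sim_library, config, seed=int(child.generate_state(1)[0] % 2**31))
        for child in children
    ]
    return sim_library, screens


def _open_write(path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "wt")


def emit_fastq(
    records: pd.DataFrame,
    library: GuideLibrary,
    sample_index_map: dict[str, str],
    guide_out,
    index_out,
    rsl_out,
    seed: int = 0,
) -> int:
    """Write count records as three synchronized FASTQ streams.

    Emits exactly ``count`` read triplets per record -- a 20-base guide
    read, a 6-base sample index read and a 6-base RSL read sharing one read
    id -- in a deterministic shuffled order, with constant Phred qualities.
    ``sample_index_map`` maps sample name -> 6-mer i5 index.  Returns the
    number of reads written.  Counting the output with max_mismatch=0
    restores the records exactly.
    """
    seq_of = library.sequence_index()
    guide_seq = {gid: seq for seq, gid in seq_of.items()}
    missing = set(records["sample"].unique()) - set(sample_index_map)
    if missing:
        raise ValueError(f"samples missing from index map: {sorted(missing)}")
    unknown = set(records["guide_id"].unique()) - set(guide_seq)
    if unknown:
        raise ValueError(f"guides missing from library: {sorted(unknown)[:5]}")

    counts = records["count"].to_numpy(dtype=int)
    order = np.repeat(np.arange(len(records)), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)

    guides = records["guide_id"].to_numpy()
    rsls = records["rsl"].to_numpy()
    samples = records["sample"].to_numpy()

    handles = [_open_write(p) if not hasattr(p, "write") else p for p in (guide_out, index_out, rsl_out)]
    try:
        for n, row in enumerate(order):
            rid = f"read{n + 1:09d}"
            gseq = guide_seq[guides[row]]
            iseq = sample_index_map[samples[row]]
            rseq = rsls[row]
            handles[0].write(f"@{rid}\n{gseq}\n+\n{'I' * len(gseq)}\n")
            handles[1].write(f"@{rid}\n{iseq}\n+\n{'I' * len(iseq)}\n")
            handles[2].write(f"@{rid}\n{rseq}\n+\n{'I' * len(rseq)}\n")
    finally:
        for p, h in zip((guide_out, index_out, rsl_out), handles):
            if not hasattr(p, "write"):
                h.close()
    return len(order)
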