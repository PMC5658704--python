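"""Simulator: reproducibility, transduction statistics, forced kinetic limits,
FASTQ emission round trip."""

import io

import numpy as np
import pandas as pd
import pytest

from rslscreen.counting import count_rsl_guides
from rslscreen.dropout import call_dropouts, guide_dropout_summary
from rslscreen.scoring import effect_sizes
from rslscreen.simulator import (
    SimConfig,
    emit_fastq,
    simulate_library,
    simulate_replicates,
    simulate_screen,
)
from rslscreen.tables import matrix_to_records


def small_config(**overrides) -> SimConfig:
    base = dict(
        n_genes=30,
        guides_per_gene=4,
        n_control_guides=8,
        frac_essential=0.2,
        cells_per_guide=50.0,
        rsl_space=64,
        depth_per_guide=500.0,
        seed=17,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestSimulateLibrary:
    def test_same_seed_identical_library(self):
        a = simulate_library(small_config())
        b = simulate_library(small_config())
        pd.testing.assert_frame_equal(a.library.entries, b.library.entries)
        pd.testing.assert_series_equal(a.guide_efficiency, b.guide_efficiency)
        assert list(a.rsl_pool) == list(b.rsl_pool)

    def test_no_essentials_when_fraction_zero(self):
        sim = simulate_library(small_config(frac_essential=0.0))
        assert not sim.gene_essential.drop("NonTargeting").any()

    def test_controls_have_zero_efficiency(self):
        sim = simulate_library(small_config())
        ctrl = sim.library.entries.loc[sim.library.entries["is_control"], "guide_id"]
        assert (sim.guide_efficiency[ctrl] == 0).all()

    def test_rsl_space_bounds(self):
        with pytest.raises(ValueError, match="rsl_space"):
            SimConfig(rsl_space=5000, seed=1)


class TestSimulateScreen:
    def test_same_seed_identical_matrices(self):
        cfg = small_config()
        lib = simulate_library(cfg)
        m1, _ = simulate_screen(lib, cfg, seed=99)
        m2, _ = simulate_screen(lib, cfg, seed=99)
        pd.testing.assert_frame_equal(m1, m2)

    def test_founder_poisson_mean(self):
        # founders per (guide, RSL) ~ Poisson(cells_per_guide / rsl_space)
        cfg = small_config(cells_per_guide=100.0, rsl_space=64)
        lib = simulate_library(cfg)
        _, truth = simulate_screen(lib, cfg, seed=5)
        n_cells = len(truth.lineages)
        expected = cfg.cells_per_guide * len(lib.library)
        assert abs(n_cells - expected) < 3 * np.sqrt(expected)

    def test_forced_lethal_limit_gives_total_dropout(self):
        # Perfect editing before the first division of a fully effective
        # null allele: every lineage of an essential-gene guide must have
        # zero treatment reads.
        cfg = small_config(
            p_edit_per_division=1.0,
            q_null=1.0,
            guide_efficiency_alpha=1e6,  # Beta -> 1
            guide_efficiency_beta=1e-3,
            sigma_lineage=0.0,
        )
        lib = simulate_library(cfg)
        matrix, truth = simulate_screen(lib, cfg, seed=11)
        essential_guides = set(
            truth.guides.loc[truth.guides["gene"].isin(truth.essential_genes), "guide_id"]
        )
        rows = matrix[matrix["guide_id"].isin(essential_guides)]
        assert len(rows) > 0
        assert (rows["treatment"] == 0).all()

    def test_neutral_screen_es_centered_at_zero(self):
        # sequencing-noise neutrality in isolation: no growth variability,
        # no essentials, and a bottleneck far above the population so no
        # lineage is lost to passaging drift
        cfg = small_config(
            frac_essential=0.0,
            sigma_lineage=0.0,
            depth_per_guide=10_000.0,
            bottleneck_cells=10**9,
        )
        lib = simulate_library(cfg)
        matrix, _ = simulate_screen(lib, cfg, seed=2)
        es = effect_sizes(matrix[(matrix["control"] + matrix["treatment"]) >= 5])["es"]
        assert abs(np.median(es)) < 0.1

    def test_early_editing_extinguishes_more_lineages_than_late(self):
        # the dropout-vs-depletion dichotomy at the ground-truth level:
        # early edits extinguish essential-gene lineages outright, late
        # edits deplete them while leaving more of them alive at Day 28
        extinct = {}
        for label, p_edit in (("early", 0.9), ("late", 0.05)):
            cfg = small_config(p_edit_per_division=p_edit, frac_essential=0.5)
            lib = simulate_library(cfg)
            _, truth = simulate_screen(lib, cfg, seed=23)
            merged = truth.lineages.merge(truth.guides, on="guide_id")
            essential = merged[merged["gene"].isin(truth.essential_genes)]
            extinct[label] = (essential["cells_day28"] == 0).mean()
        assert extinct["early"] > extinct["late"]

    def test_dropout_fraction_monotone_in_efficiency_and_null_prob(self):
        losses = []
        for a, b, q in [(1e-3, 1e6, 0.1), (8.0, 2.0, 0.5), (1e6, 1e-3, 1.0)]:
            cfg = small_config(
                guide_efficiency_alpha=a, guide_efficiency_beta=b, q_null=q, frac_essential=0.5
            )
            lib = simulate_library(cfg)
            matrix, truth = simulate_screen(lib, cfg, seed=31)
            filtered = matrix[(matrix["control"] + matrix["treatment"]) >= 5]
            summary = guide_dropout_summary(call_dropouts(filtered))
            merged = summary.merge(truth.guides, on="guide_id")
            essential = merged[merged["gene"].isin(truth.essential_genes) & (merged["n_day4"] > 0)]
            losses.append(essential["fraction_lost"].mean())
        assert losses[0] < losses[1] < losses[2]

    def test_aggressive_bottleneck_strands_lineages_in_one_time_point(self):
        cfg = small_config(bottleneck_cells=300)  # far below founder count
        lib = simulate_library(cfg)
        matrix, _ = simulate_screen(lib, cfg, seed=3)
        one_sided = ((matrix["control"] == 0) | (matrix["treatment"] == 0)).mean()
        assert one_sided > 0


class TestEmitFastq:
    def records(self, rng, n_rows=100):
        bases = np.array(list("ACGT"))
        rows = set()
        while len(rows) < n_rows:
            rows.add(
                (
                    f"g{rng.integers(30):02d}",
                    "".join(rng.choice(bases, size=6)),
                    rng.choice(["day4", "day28"]),
                )
            )
        return pd.DataFrame(
            [(g, r, s, int(rng.integers(1, 20))) for g, r, s in sorted(rows)],
            columns=["guide_id", "rsl", "sample", "count"],
        )

    def library_for(self, records, rng):
        from rslscreen.library import GuideLibrary

        gids = sorted(records["guide_id"].unique())
        bases = np.array(list("ACGT"))
        seqs = set()
        while len(seqs) < len(gids):
            seqs.add("".join(rng.choice(bases, size=20)))
        return GuideLibrary.from_records(
            [(g, s, "GENEX", False) for g, s in zip(gids, sorted(seqs))]
        )

    def test_round_trip_restores_counts_exactly(self, rng):
        records = self.records(rng)
        library = self.library_for(records, rng)
        index_map = {"day4": "AAAAAA", "day28": "CCCCCC"}
        g, i, r = io.StringIO(), io.StringIO(), io.StringIO()
        n = emit_fastq(records, library, index_map, g, i, r, seed=7)
        assert n == records["count"].sum()
        for h in (g, i, r):
            h.seek(0)
        back, qc = count_rsl_guides(
            g, r, library, index_fastq=i, sample_map={v: k for k, v in index_map.items()}
        )
        pd.testing.assert_frame_equal(
            back, records.sort_values(["guide_id", "rsl", "sample"]).reset_index(drop=True)
        )
        assert qc.matched == n

    def test_single_record_count_three(self, toy_library):
        records = pd.DataFrame(
            [("guideA", "AAAAAA", "S1", 3)], columns=["guide_id", "rsl", "sample", "count"]
        )
        g, i, r = io.StringIO(), io.StringIO(), io.StringIO()
        n = emit_fastq(records, toy_library, {"S1": "GGGGGG"}, g, i, r, seed=1)
        assert n == 3
        assert g.getvalue().count("@read") == 3

    def test_empty_records_empty_streams(self, toy_library):
        records = pd.DataFrame(columns=["guide_id", "rsl", "sample", "count"])
        g, i, r = io.StringIO(), io.StringIO(), io.StringIO()
        assert emit_fastq(records, toy_library, {}, g, i, r, seed=1) == 0
        assert g.getvalue() == ""

    def test_missing_sample_index_rejected(self, toy_library):
        records = pd.DataFrame(
            [("guideA", "AAAAAA", "S1", 1)], columns=["guide_id", "rsl", "sample", "count"]
        )
        with pytest.raises(ValueError, match="index map"):
            emit_fastq(records, toy_library, {}, io.StringIO(), io.StringIO(), io.StringIO())


def test_simulate_replicates_are_distinct_but_share_library():
    cfg = small_config()
    lib, screens = simulate_replicates(cfg, 2)
    (m1, t1), (m2, t2) = screens
    pd.testing.assert_frame_equal(t1.guides, t2.guides)
    assert not m1.equals(m2)


def test_full_matrix_round_trip_through_fastq(rng):
    # simulator counts -> FASTQ -> counting module -> identical matrix
    cfg = small_config(n_genes=5, guides_per_gene=2, n_control_guides=2, cells_per_guide=20.0)
    lib = simulate_library(cfg)
    matrix, _ = simulate_screen(lib, cfg, seed=41)
    matrix = matrix.head(100)
    records = matrix_to_records(matrix, "day4", "day28")
    index_map = {"day4": "AAAAAA", "day28": "CCCCCC"}
    g, i, r = io.StringIO(), io.StringIO(), io.StringIO()
    emit_fastq(records, lib.library, index_map, g, i, r, seed=13)
    for h in (g, i, r):
        h.seek(0)
    back, _ = count_rsl_guides(
        g, r, lib.library, index_fastq=i, sample_map={v: k for k, v in index_map.items()}
    )
    from rslscreen.tables import build_matrix

    pd.testing.assert_frame_equal(build_matrix(back, "day4", "day28"), matrix)
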