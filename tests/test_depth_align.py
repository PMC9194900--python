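"""Depth ratios, subgenome recovery and alignment-table integrity."""

import numpy as np
import pytest

from wgdkit import collinearity as col
from wgdkit import depth_align as da
from wgdkit import simulate as sim


def blocks_between(res, a, b, **kw):
    return col.chain_blocks(
        res.hit_pairs(a, b), res.annotation(a), res.annotation(b), **kw
    )


class TestDepthRatio:
    def test_self_one_wgd_is_1_1(self, biased_tetraploid):
        res = biased_tetraploid
        ann = res.annotation("Q")
        blocks = blocks_between(res, "Q", "Q")
        profile = da.depth_ratio(blocks, ann, ann)
        assert profile.ratio == (1, 1)

    def test_tetraploid_vs_hexaploid_2_3(self, hexa_vs_tetra):
        res = hexa_vs_tetra
        blocks = blocks_between(res, "T", "H")
        profile = da.depth_ratio(blocks, res.annotation("T"), res.annotation("H"))
        assert profile.ratio == (2, 3)

    def test_ratio_symmetry(self, hexa_vs_tetra):
        res = hexa_vs_tetra
        blocks = blocks_between(res, "T", "H")
        fwd = da.depth_ratio(blocks, res.annotation("T"), res.annotation("H"))
        rev = da.depth_ratio(blocks, res.annotation("H"), res.annotation("T"))
        assert fwd.ratio == rev.ratio[::-1]

    def test_double_tetraploid_2_4(self):
        sc = sim.Scenario(
            species_tree="(A:40,P:40);",
            wgd_events=[
                sim.WgdEvent("RCT", 2, "A", loss_prob=(0.15, 0.25), run_p=0.6),
                sim.WgdEvent("RCT2", 2, "P", loss_prob=(0.1, 0.15), run_p=0.6),
                sim.WgdEvent("PST", 2, "P", loss_prob=(0.1, 0.2), run_p=0.6),
            ],
            n_chromosomes=2, genes_per_chromosome=300, codons_per_gene=3,
            ks_per_myr=0.004, seed=31,
        )
        res = sim.simulate_scenario(sc)
        blocks = blocks_between(res, "A", "P")
        profile = da.depth_ratio(blocks, res.annotation("A"), res.annotation("P"))
        assert profile.ratio == (2, 4)

    def test_no_blocks_undefined(self):
        g = sim.generate_ancestor(1, 20, 3, seed=1)
        ann = g.annotation
        assert da.depth_ratio([], ann, ann).ratio is None


class TestAssignSubgenomes:
    def test_biased_loss_dominance_recovered(self, biased_tetraploid):
        """Dominant/sensitive calls match truth on >= 95% of anchored genes."""
        res = biased_tetraploid
        blocks = blocks_between(res, "R", "Q")
        assignment = da.assign_subgenomes(
            blocks, res.annotation("Q"), res.annotation("R"), multiplicity=2
        )
        rank_of = {
            (row.ref_chrom, row.group): row.dominance
            for row in assignment.groups.itertuples()
        }
        ok = bad = 0
        for b in blocks:
            entry = assignment.block_group.get(b.block_id)
            if entry is None:
                continue
            dominance = rank_of[entry]
            for _, _, _, gq in b.anchors:
                # truth: subgenome 'a' had loss 0.2 (dominant), 'b' 0.5
                chrom, _ = res.annotation("Q").locate(gq)
                true_dom = "dominant" if chrom.endswith("a") else "sensitive"
                if dominance == true_dom:
                    ok += 1
                else:
                    bad += 1
        assert ok / (ok + bad) >= 0.95

    def test_hexaploid_three_groups(self, hexa_vs_tetra):
        res = hexa_vs_tetra
        blocks = blocks_between(res, "T", "H")
        assignment = da.assign_subgenomes(
            blocks, res.annotation("H"), res.annotation("T"), multiplicity=3
        )
        for _, sub in assignment.groups.groupby("ref_chrom"):
            assert set(sub["group"]) == {0, 1, 2}
        assert assignment.overflow_fraction <= 0.05

    def test_lossless_tie_flagged(self):
        sc = sim.Scenario(
            species_tree="(R:30,Q:30);",
            wgd_events=[sim.WgdEvent("T", 2, "Q")],
            n_chromosomes=1, genes_per_chromosome=120, codons_per_gene=3, seed=9,
        )
        res = sim.simulate_scenario(sc)
        blocks = blocks_between(res, "R", "Q")
        assignment = da.assign_subgenomes(
            blocks, res.annotation("Q"), res.annotation("R"), multiplicity=2
        )
        assert assignment.groups["tied"].all()


class TestAlignmentTable:
    def test_lossless_no_absences(self):
        sc = sim.Scenario(
            species_tree="(R:30,Q:30);",
            wgd_events=[sim.WgdEvent("T", 2, "Q")],
            n_chromosomes=1, genes_per_chromosome=150, codons_per_gene=3, seed=13,
        )
        res = sim.simulate_scenario(sc)
        blocks = blocks_between(res, "R", "Q")
        table = da.build_alignment_table(
            res.annotation("R"), [(res.annotation("Q"), 2, blocks)], ref_depth=1
        )
        assert int(table.absence_counts().sum()) == 0
        n_rows = len(res.annotation("R"))
        cols = [c for c in table.data.columns if c != "chrom"]
        assert n_rows * len(cols) == table.n_columns * n_rows

    def test_absences_equal_truth_losses(self, biased_tetraploid):
        """Absence marks per query genome equal the truth ledger's losses."""
        res = biased_tetraploid
        blocks = blocks_between(res, "R", "Q")
        table = da.build_alignment_table(
            res.annotation("R"), [(res.annotation("Q"), 2, blocks)], ref_depth=1
        )
        absences = table.absence_counts()
        fates = res.truth.fates
        lost = fates[(fates["species"] == "Q") & (fates["descendant_id"] == sim.LOST)]
        # pooled over both columns (group labels are per-chromosome positional)
        assert absences["Q.1"] + absences["Q.2"] == len(lost)

    def test_observed_run_spectrum_matches_truth(self, biased_tetraploid):
        from wgdkit import fractionation as fr

        res = biased_tetraploid
        blocks = blocks_between(res, "R", "Q")
        table = da.build_alignment_table(
            res.annotation("R"), [(res.annotation("Q"), 2, blocks)], ref_depth=1
        )
        observed = {}
        for colname in ("Q.1", "Q.2"):
            for length, c in fr.loss_runs(table, colname).counts.items():
                observed[length] = observed.get(length, 0) + c
        truth = {}
        for sub in ("WGD.a", "WGD.b"):
            for length, c in res.truth.observed_loss_spectrum("Q", sub).items():
                truth[length] = truth.get(length, 0) + c
        assert observed == truth

    def test_header_arithmetic_19_columns(self):
        """Seven-genome layout reproduces the 19 = (3+2+2+2+2+4+4) header."""
        sc = sim.Scenario(
            species_tree="(((V:10)ce:20,(N:25,M:25)pro:5)core:5,((A:12,I:12)aq:15,(P:20,T:20)pt:7)ran:8);",
            wgd_events=[
                sim.WgdEvent("ECH", 3, "V", loss_prob=(0.1, 0.1, 0.1), run_p=0.7),
                sim.WgdEvent("NST", 2, "N", loss_prob=(0.1, 0.1), run_p=0.7),
                sim.WgdEvent("MST", 2, "M", loss_prob=(0.1, 0.1), run_p=0.7),
                sim.WgdEvent("RCT", 2, "ran", loss_prob=(0.1, 0.1), run_p=0.7),
                sim.WgdEvent("PST", 2, "P", loss_prob=(0.1, 0.1), run_p=0.7),
                sim.WgdEvent("TRT", 2, "T", loss_prob=(0.1, 0.1), run_p=0.7),
            ],
            n_chromosomes=1, genes_per_chromosome=120, codons_per_gene=3,
            ks_per_myr=0.002, seed=23,
        )
        res = sim.simulate_scenario(sc)
        ref = res.annotation("V")
        queries = []
        for name, depth in (("N", 2), ("M", 2), ("A", 2), ("I", 2), ("P", 4), ("T", 4)):
            queries.append((res.annotation(name), depth, blocks_between(res, "V", name)))
        self_blocks = blocks_between(res, "V", "V")
        table = da.build_alignment_table(ref, queries, ref_self_blocks=self_blocks,
                                         ref_depth=3)
        assert table.header == "19 = (3+2+2+2+2+4+4)"
        assert table.n_columns == 19
        cols = [c for c in table.data.columns if c != "chrom"]
        assert len(cols) == 19

    def test_view_smoke(self, tmp_path, biased_tetraploid):
        res = biased_tetraploid
        blocks = blocks_between(res, "R", "Q")
        table = da.build_alignment_table(
            res.annotation("R"), [(res.annotation("Q"), 2, blocks)], ref_depth=1
        )
        out = tmp_path / "view.png"
        da.local_alignment_view(table, table.data["chrom"].iloc[0], str(out), 0, 80)
        assert out.exists() and out.stat().st_size > 0

    def test_csv_roundtrip_header(self, tmp_path, biased_tetraploid):
        res = biased_tetraploid
        blocks = blocks_between(res, "R", "Q")
        table = da.build_alignment_table(
            res.annotation("R"), [(res.annotation("Q"), 2, blocks)], ref_depth=1
        )
        out = tmp_path / "table.csv"
        table.to_csv(str(out))
        first = out.read_text().splitlines()[0]
        assert first.startswith("# columns: 3 = (1+2)")
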