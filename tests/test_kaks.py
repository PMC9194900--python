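"""Nei-Gojobori estimator against hand counts, brute-force and Biopython."""

import math
import random
import warnings

import numpy as np
import pytest

from _oracles import ng_estimate
from wgdkit import kaks
from wgdkit.collinearity import CollinearBlock

SAFE_CODONS = [
    c for c in kaks._CODONS
    if c not in ("TAA", "TAG", "TGA")
]
random.seed(0)


def random_cds(n_codons, rng):
    return "".join(rng.choice(SAFE_CODONS) for _ in range(n_codons))


def _any_path_hits_stop(a, b):
    from itertools import permutations

    stops = {"TAA", "TAG", "TGA"}
    for i in range(0, len(a), 3):
        c1, c2 = a[i : i + 3], b[i : i + 3]
        diff = [p for p in range(3) if c1[p] != c2[p]]
        for path in permutations(diff):
            cur = c1
            for pos in path:
                cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if cur in stops:
                    return True
    return False


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        aln = [("GCT", "GCT")] * 10
        est = kaks.nei_gojobori(aln)
        assert est.ks == 0.0 and est.ka == 0.0

    def test_hand_example_single_synonymous_change(self):
        # GGA GGA GGA GGA vs GGA GGA GGA GGG: S=4, N=8, sd=1, ps=1/4
        aln = [("GGA", "GGA")] * 3 + [("GGA", "GGG")]
        est = kaks.nei_gojobori(aln)
        assert est.syn_sites == pytest.approx(4.0)
        assert est.nonsyn_sites == pytest.approx(8.0)
        assert est.syn_diffs == pytest.approx(1.0)
        assert est.ps == pytest.approx(0.25)
        assert est.ks == pytest.approx(-0.75 * math.log(1 - 1 / 3))
        assert est.ks == pytest.approx(0.304, abs=5e-4)
        assert est.ka == 0.0

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        """Implementation equals path enumeration on 100 random 50-codon pairs."""
        rng = random.Random(7)
        for _ in range(100):
            a = random_cds(50, rng)
            b = random_cds(50, rng)
            est = kaks.nei_gojobori(kaks.align_codons(a, b))
            ref = ng_estimate(a, b)
            assert est.syn_sites == pytest.approx(ref["S"], abs=1e-9)
            assert est.nonsyn_sites == pytest.approx(ref["N"], abs=1e-9)
            assert est.syn_diffs == pytest.approx(ref["sd"], abs=1e-9)
            assert est.nonsyn_diffs == pytest.approx(ref["nd"], abs=1e-9)

    def test_matches_biopython_ng86(self):
        """Cross-check Ka/Ks against Biopython's independent NG86 implementation.

        Restricted to codon pairs whose substitution paths never pass through
        a stop codon: Biopython scores a (stop, stop) path step as synonymous
        while this package scores every stop-involved step as nonsynonymous,
        a convention difference outside the comparable domain.
        """
        Bio = pytest.importorskip("Bio.codonalign.codonseq")
        rng = random.Random(12)
        compared = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            while compared < 20:
                a = random_cds(40, rng)
                b = random_cds(40, rng)
                if _any_path_hits_stop(a, b):
                    continue
                dn, ds = Bio.cal_dn_ds(
                    Bio.CodonSeq(a), Bio.CodonSeq(b), method="NG86"
                )
                est = kaks.nei_gojobori(kaks.align_codons(a, b))
                if est.ks is not kaks.SATURATED and ds >= 0:
                    assert est.ks == pytest.approx(ds, abs=1e-4)
                if est.ka is not kaks.SATURATED and dn >= 0:
                    assert est.ka == pytest.approx(dn, abs=1e-4)
                compared += 1

    def test_symmetry_exact(self):
        rng = random.Random(5)
        for _ in range(20):
            a, b = random_cds(30, rng), random_cds(30, rng)
            e1 = kaks.nei_gojobori(kaks.align_codons(a, b))
            e2 = kaks.nei_gojobori(kaks.align_codons(b, a))
            assert e1.syn_diffs == e2.syn_diffs
            assert e1.syn_sites == e2.syn_sites
            assert e1.nonsyn_diffs == e2.nonsyn_diffs

    def test_site_conservation(self):
        rng = random.Random(6)
        for _ in range(20):
            a, b = random_cds(25, rng), random_cds(25, rng)
            est = kaks.nei_gojobori(kaks.align_codons(a, b))
            assert est.syn_sites + est.nonsyn_sites == pytest.approx(
                3 * est.n_codons, abs=1e-9
            )

    def test_jc_limit_small_ps(self):
        # as ps -> 0, ks/ps -> 1
        ps = 1e-4
        ks = kaks.jukes_cantor(ps)
        assert abs(ks / ps - 1.0) < 1e-3

    def test_saturation_marker(self):
        assert kaks.jukes_cantor(0.75) is kaks.SATURATED
        assert kaks.jukes_cantor(0.9) is kaks.SATURATED

    def test_vectorized_equals_scalar(self):
        rng = random.Random(8)
        a, b = random_cds(60, rng), random_cds(60, rng)
        ev = kaks.ks_vectorized(a, b)
        es = kaks.nei_gojobori(kaks.align_codons(a, b))
        assert ev.syn_diffs == pytest.approx(es.syn_diffs)
        assert ev.syn_sites == pytest.approx(es.syn_sites)


class TestAlignCodons:
    def test_identical_no_gaps(self):
        s = "ATGGCTACTCCT"
        aln = kaks.align_codons(s, s)
        assert all(kaks.GAP_CODON not in pair for pair in aln)
        assert len(aln) == 4

    def test_inserted_codon_gives_one_gap(self):
        a = "ATGGCTCCTGATTGGAAA"
        b = "ATGGCTTACCCTGATTGGAAA"  # TAC inserted after codon 2
        aln = kaks.align_codons(a, b, protein_guided=True)
        gaps_a = sum(1 for ca, _ in aln if ca == kaks.GAP_CODON)
        gaps_b = sum(1 for _, cb in aln if cb == kaks.GAP_CODON)
        assert (gaps_a, gaps_b) == (1, 0)
        # ungapped columns must pair the original codons
        est = kaks.nei_gojobori(aln)
        assert est.n_codons == 6
        assert est.ks == 0.0

    def test_trailing_bases_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="trailing"):
            aln = kaks.align_codons("GCTGCTGC", "GCTGCTGC")
        assert len(aln) == 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kaks.align_codons("GC", "GCT")


class TestBlockKs:
    def _block(self, genes):
        return CollinearBlock(0, "A", "B", "c1", "c2", "+",
                             [(i, i, f"a{i}", f"b{i}") for i in range(len(genes))])

    def test_median_of_finite_values(self):
        # ks values 0.4 / 0.5 / 0.6 via crafted sequences would be fragile;
        # instead check the median logic through saturated exclusion
        cds = {
            "a0": "GGAGGAGGAGGA", "b0": "GGAGGAGGAGGG",   # ks ~ 0.304
            "a1": "GGAGGAGGAGGA", "b1": "GGAGGAGGAGGA",   # ks = 0
            "a2": "TTTTTCTTATTG", "b2": "CTCCTGCTACTT",   # heavily diverged
        }
        block = self._block(["x"] * 3)
        kaks.block_ks(block, cds)
        finite = [v for v in block.ks_values if v is not kaks.SATURATED]
        assert block.ks_median == pytest.approx(float(np.median(finite)))

    def test_all_saturated_flagged(self):
        # force saturation with a fully synonymous-divergent pair
        a = "GGA" * 4
        b = "GGG" * 4  # every codon differs synonymously: ps = 1 per site
        block = self._block(["x"])
        kaks.block_ks(block, {"a0": a, "b0": b})
        assert block.ks_median is None
        assert block.n_saturated == 1

    def test_simulated_block_medians_near_true_peak(self, nst_like):
        """Ks medians of WGD paralog blocks concentrate at the planted peak."""
        from wgdkit import collinearity as col

        res = nst_like
        ann = res.annotation("S")
        hits = res.hit_pairs("S", "S", seed=1)
        blocks = col.chain_blocks(hits, ann, ann, max_gap=50, min_anchors=4)
        assert blocks
        cds = res.cds("S")
        medians = []
        for b in blocks:
            kaks.block_ks(b, cds)
            if b.ks_median is not None and b.n_anchors >= 20:
                medians.append(b.ks_median)
        med = np.array(medians)
        assert len(med) >= 2
        se = med.std(ddof=1) / np.sqrt(len(med)) if len(med) > 1 else 0.02
        assert abs(med.mean() - 0.49) <= max(3 * se, 0.02)
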