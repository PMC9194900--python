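"""Ka/Ks estimation for homologous gene pairs (Nei-Gojobori 1986).

Implements the unweighted-pathway variant: synonymous and nonsynonymous site
fractions are counted per codon from the three possible changes at each
position (mutations to stop codons count as nonsynonymous, so every codon
contributes exactly three sites), and codon differences at 2-3 positions are
averaged over all minimal substitution paths with equal weights (steps through
stop codons count as nonsynonymous).  Proportions are corrected with the
Jukes-Cantor formula; a proportion >= 3/4 is reported as saturated.

All per-codon-pair quantities are precomputed into 64x64 tables, so estimating
Ks for thousands of anchor pairs is a vectorised lookup.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

_BASES = "ACGT"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

GAP_CODON = "---"


class KsSaturated:
    """Sentinel for a saturated (uncorrectable) rate estimate."""

    def __repr__(self):
        return "SATURATED"


SATURATED = KsSaturated()


@dataclass
class KsEstimate:
    """Nei-Gojobori site/difference counts and corrected rates for one pair."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
    excluded_codons: int = 0

    @property
    def ps(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites > 0 else 0.0

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites > 0 else 0.0

    @property
    def ks(self):
        return jukes_cantor(self.ps)

    @property
    def ka(self):
        return jukes_cantor(self.pn)


def jukes_cantor(p: float):
    """JC correction -(3/4) ln(1 - 4p/3); SATURATED when p >= 3/4."""
    if p >= 0.75:
        return SATURATED
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _step_is_syn(c1: str, c2: str) -> bool:
    if c1 in _STOPS or c2 in _STOPS:
        return False
    return _CODON_TABLE[c1] == _CODON_TABLE[c2]


@lru_cache(maxsize=1)
def _tables():
    """Precompute per-codon site counts and per-pair path-averaged differences."""
    syn_sites = np.zeros(64)
    for ci, codon in enumerate(_CODONS):
        if codon in _STOPS:
            syn_sites[ci] = np.nan
            continue
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if _step_is_syn(codon, mut):
                    s += 1.0
        syn_sites[ci] = s / 3.0

    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(_CODONS):
        if c1 in _STOPS:
            continue
        for j, c2 in enumerate(_CODONS):
            if c2 in _STOPS or i == j:
                continue
            diff = [p for p in range(3) if c1[p] != c2[p]]
            paths = list(permutations(diff))
            s_tot = n_tot = 0.0
            for path in paths:
                cur = c1
                for pos in path:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if _step_is_syn(cur, nxt):
                        s_tot += 1.0
                    else:
                        n_tot += 1.0
                    cur = nxt
            sd[i, j] = s_tot / len(paths)
            nd[i, j] = n_tot / len(paths)
    return syn_sites, sd, nd


def _encode_codons(seq: str) -> np.ndarray:
    """Codon indices 0..63 of an in-frame sequence; -1 for codons with non-ACGT."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for k, b in enumerate(_BASES):
        lut[ord(b)] = k
    nt = lut[arr]
    n = len(nt) // 3
    cod = nt[: 3 * n].reshape(n, 3)
    out = cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]
    out[(cod < 0).any(axis=1)] = -1
    return out


_STOP_IDX = {_CODONS.index(s) for s in _STOPS}


def align_codons(cds_a: str, cds_b: str, protein_guided: bool = True):
    """Pairwise alignment in codon units.

    Returns a list of ``(codon_a, codon_b)`` string pairs, with ``---`` as the
    gap codon.  When ``protein_guided`` and lengths differ, a global protein
    alignment (BLOSUM62, affine gaps) is back-translated to codons; for
    equal-length sequences the identity alignment is returned.  Sequences not
    a multiple of 3 lose trailing bases with a warning.
    """
    seqs = []
    for name, s in (("a", cds_a), ("b", cds_b)):
        if len(s) < 3:
            raise ValueError(f"sequence {name} shorter than one codon")
        if len(s) % 3:
            warnings.warn(f"sequence {name} not a multiple of 3; trailing bases dropped")
            s = s[: len(s) - len(s) % 3]
        seqs.append(s.upper())
    sa, sb = seqs
    if len(sa) == len(sb) or not protein_guided:
        if len(sa) != len(sb):
            raise ValueError("unguided alignment requires equal-length sequences")
        return [(sa[i : i + 3], sb[i : i + 3]) for i in range(0, len(sa), 3)]

    from Bio import Align
    from Bio.Align import substitution_matrices
    from Bio.Seq import Seq

    def translate(s):
        return "".join(
            "X" if _CODON_TABLE.get(s[i : i + 3], "X") == "*"
            else _CODON_TABLE.get(s[i : i + 3], "X")
            for i in range(0, len(s), 3)
        )

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    pa, pb = translate(sa), translate(sb)
    aln = aligner.align(Seq(pa), Seq(pb))[0]
    out = []
    ia = ib = 0
    for col in range(aln.length):
        ca = str(aln[0, col])
        cb = str(aln[1, col])
        codon_a = GAP_CODON if ca == "-" else sa[3 * ia : 3 * ia + 3]
        codon_b = GAP_CODON if cb == "-" else sb[3 * ib : 3 * ib + 3]
        ia += ca != "-"
        ib += cb != "-"
        out.append((codon_a, codon_b))
    return out


def nei_gojobori(alignment) -> KsEstimate:
    """Nei-Gojobori estimate from a codon alignment (list of codon pairs).

    Gap columns and columns containing a stop codon are excluded from
    counting (the exclusion count is reported).  Symmetric in its arguments.
    """
    syn_sites, sd_t, nd_t = _tables()
    S = N = sd = nd = 0.0
    n_codons = excluded = 0
    warned_stop = False
    for codon_a, codon_b in alignment:
        if GAP_CODON in (codon_a, codon_b):
            excluded += 1
            continue
        try:
            ia = _CODONS.index(codon_a)
            ib = _CODONS.index(codon_b)
        except ValueError:
            excluded += 1  # ambiguous bases
            continue
        if ia in _STOP_IDX or ib in _STOP_IDX:
            if not warned_stop:
                warnings.warn("internal stop codon excluded from Ks counting")
                warned_stop = True
            excluded += 1
            continue
        s_sites = 0.5 * (syn_sites[ia] + syn_sites[ib])
        S += s_sites
        N += 3.0 - s_sites
        sd += sd_t[ia, ib]
        nd += nd_t[ia, ib]
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons in alignment")
    return KsEstimate(S, N, sd, nd, n_codons, excluded)


def ks_vectorized(cds_a: str, cds_b: str) -> KsEstimate:
    """Fast Nei-Gojobori for equal-length, gapless, in-frame sequences."""
    ca = _encode_codons(cds_a)
    cb = _encode_codons(cds_b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in codon count")
    syn_sites, sd_t, nd_t = _tables()
    stop_idx = np.array(sorted(_STOP_IDX))
    ok = (ca >= 0) & (cb >= 0) & ~np.isin(ca, stop_idx) & ~np.isin(cb, stop_idx)
    ca, cb = ca[ok], cb[ok]
    if len(ca) == 0:
        raise ValueError("no comparable codons")
    s_sites = 0.5 * (syn_sites[ca] + syn_sites[cb])
    S = float(s_sites.sum())
    N = float((3.0 - s_sites).sum())
    return KsEstimate(
        S, N, float(sd_t[ca, cb].sum()), float(nd_t[ca, cb].sum()),
        len(ca), int((~ok).sum()),
    )


def pair_ks(cds_a: str, cds_b: str, protein_guided: bool = True) -> KsEstimate:
    """Estimate Ka/Ks for one gene pair, aligning first if lengths differ."""
    a = cds_a[: len(cds_a) - len(cds_a) % 3]
    b = cds_b[: len(cds_b) - len(cds_b) % 3]
    if len(a) == len(b):
        return ks_vectorized(a, b)
    return nei_gojobori(align_codons(cds_a, cds_b, protein_guided=protein_guided))


def block_ks(block, cds: dict[str, str]):
    """Fill a CollinearBlock's ks_values / ks_median from anchor-pair CDS.

    Saturated estimates are excluded from the median and counted; a block
    whose anchors are all saturated keeps ``ks_median = None``.
    """
    values = []
    n_saturated = 0
    for _, _, gene_a, gene_b in block.anchors:
        est = pair_ks(cds[gene_a], cds[gene_b])
        ks = est.ks
        if ks is SATURATED:
            n_saturated += 1
            values.append(SATURATED)
        else:
            values.append(ks)
    finite = [v for v in values if v is not SATURATED]
    block.ks_values = values
    block.n_saturated = n_saturated
    block.ks_median = float(np.median(finite)) if finite else None
    return block


def pairwise_ks_table(pairs, cds: dict[str, str]):
    """Per-pair Ks TSV frame: gene_a, gene_b, ka, ks, S, N.

    ``pairs`` is an iterable of (gene_a, gene_b).  Saturated rates are NaN.
    This frame is the unit all downstream peak/dating modules consume.
    """
    import pandas as pd

    rows = []
    for ga, gb in pairs:
        est = pair_ks(cds[ga], cds[gb])
        ks = est.ks
        ka = est.ka
        rows.append(
            (ga, gb,
             math.nan if ka is SATURATED else ka,
             math.nan if ks is SATURATED else ks,
             est.syn_sites, est.nonsyn_sites)
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "ka", "ks", "S", "N"])
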