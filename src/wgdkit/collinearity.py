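"""Colinear (synteny) block detection by max-gap chaining.

Homolog hits between two annotated genomes are chained, per chromosome pair
and orientation, into runs of anchor pairs whose ordinals increase strictly
on both chromosomes (or increase/decrease for antiparallel blocks) with at
most ``max_gap`` intervening genes between consecutive anchors on either
chromosome.  Chains are extracted greedily: the best chain (most anchors,
ties broken by smaller total gap, then by lexicographically smallest anchor
sequence) is found by dynamic programming, reported, removed, and the search
repeats until no chain of ``min_anchors`` anchors remains.  Within-genome
comparisons drop self-hits and mask the identity diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wgdkit.annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 50
DEFAULT_MIN_ANCHORS = 4
DEFAULT_EVALUE = 1e-5

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class CollinearBlock:
    """A chained run of anchor gene pairs between two chromosomal regions."""

    block_id: int
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' or '-'
    anchors: list[tuple[int, int, str, str]]  # (ordinal_a, ordinal_b, gene_a, gene_b)
    ks_values: list = field(default_factory=list)
    ks_median: float | None = None
    n_saturated: int = 0

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def span_a(self) -> tuple[int, int]:
        oa = [a[0] for a in self.anchors]
        return min(oa), max(oa)

    def span_b(self) -> tuple[int, int]:
        ob = [a[1] for a in self.anchors]
        return min(ob), max(ob)


def read_hits(
    path: str,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    evalue_cutoff: float = DEFAULT_EVALUE,
    best_n: int = 5,
) -> pd.DataFrame:
    """Read BLAST 12-column tabular hits and filter them.

    Hits with E-value >= ``evalue_cutoff`` are dropped (the conventional
    E < 1e-5 homology screen), self-hits removed, unresolvable gene ids
    skipped with a logged count, and at most ``best_n`` hits kept per query
    gene by bit score.  Returns a frame with gene_a, gene_b, score, evalue.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed BLAST tabular file {path}: {exc}") from None
    return filter_hits(df, annot_a, annot_b, evalue_cutoff, best_n)


def filter_hits(
    df: pd.DataFrame,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    evalue_cutoff: float = DEFAULT_EVALUE,
    best_n: int = 5,
) -> pd.DataFrame:
    """Apply the homolog-hit filters to an outfmt6-style frame."""
    df = df.rename(columns={"qseqid": "gene_a", "sseqid": "gene_b", "bitscore": "score"})
    n0 = len(df)
    df = df[df["evalue"] < evalue_cutoff]
    df = df[df["gene_a"] != df["gene_b"]]
    resolvable = df["gene_a"].isin(annot_a.genes["gene_id"]) & df["gene_b"].isin(
        annot_b.genes["gene_id"]
    )
    n_bad = int((~resolvable).sum())
    if n_bad:
        logger.warning("skipped %d hits with unresolvable gene ids", n_bad)
    df = df[resolvable]
    df = (
        df.sort_values(["gene_a", "score"], ascending=[True, False], kind="stable")
        .groupby("gene_a", sort=False)
        .head(best_n)
    )
    logger.info("hits: %d read, %d kept", n0, len(df))
    return df[["gene_a", "gene_b", "score", "evalue"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _best_chain(points: list[tuple[int, int]], max_gap: int, sign: int):
    """Best chain over ordinal points for one orientation.

    ``sign`` is +1 (ordinal_b strictly increasing) or -1 (strictly
    decreasing).  Returns the list of points of the single best chain:
    maximum length, then minimum total gap (sum of intervening genes on both
    chromosomes over consecutive steps), then lexicographically smallest
    sequence of (ordinal_a, ordinal_b).
    """
    if not points:
        return []
    pts = sorted(points)
    n = len(pts)
    A = np.array([p[0] for p in pts], dtype=np.int64)
    B = np.array([sign * p[1] for p in pts], dtype=np.int64)

    best_len = np.ones(n, dtype=np.int64)
    best_gap = np.zeros(n, dtype=np.int64)
    # successors of i lie in an A-window of width max_gap+1 (points are
    # sorted by A, and a valid step increases A), so the DP is O(n * window)
    for i in range(n - 1, -1, -1):
        lo = int(np.searchsorted(A, A[i] + 1, side="left"))
        hi = int(np.searchsorted(A, A[i] + max_gap + 1, side="right"))
        if lo >= hi:
            continue
        db = B[lo:hi] - B[i]
        ok = (db >= 1) & (db <= max_gap + 1)
        if not ok.any():
            continue
        js = np.arange(lo, hi)[ok]
        cand_len = best_len[js] + 1
        cand_gap = best_gap[js] + (A[js] - A[i] - 1) + (B[js] - B[i] - 1)
        top = cand_len.max()
        sel = cand_len == top
        best_len[i] = top
        best_gap[i] = cand_gap[sel].min()

    L = int(best_len.max())
    on_best = best_len == L
    G = int(best_gap[on_best].min())
    start = int(np.flatnonzero(on_best & (best_gap == G))[0])  # lexicographic min

    chain = [start]
    cur, rem_len, rem_gap = start, L, G
    while rem_len > 1:
        lo = int(np.searchsorted(A, A[cur] + 1, side="left"))
        hi = int(np.searchsorted(A, A[cur] + max_gap + 1, side="right"))
        js = np.arange(lo, hi)
        db = B[js] - B[cur]
        step = (A[js] - A[cur] - 1) + db - 1
        ok = (
            (db >= 1) & (db <= max_gap + 1)
            & (best_len[js] == rem_len - 1)
            & (best_gap[js] + step == rem_gap)
        )
        nxt = int(js[ok][0])  # ascending order = lexicographically smallest
        chain.append(nxt)
        rem_gap -= int((A[nxt] - A[cur] - 1) + (B[nxt] - B[cur] - 1))
        rem_len -= 1
        cur = nxt
    return [pts[i] for i in chain]


def chain_blocks(
    hits: pd.DataFrame,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> list[CollinearBlock]:
    """Chain homolog hits into colinear blocks (max-gap criterion).

    Runs the greedy best-chain extraction separately for + and - orientations
    within every chromosome pair.  For a genome compared against itself the
    trivial identity diagonal is masked: self-hits are dropped, only the
    upper triangle of same-chromosome hits is kept, and same-chromosome
    anchors with |ordinal_a - ordinal_b| <= max_gap are removed.
    """
    if hits is None or len(hits) == 0:
        return []
    self_cmp = annot_a.name == annot_b.name
    rows = []
    for ga, gb in zip(hits["gene_a"], hits["gene_b"]):
        if ga not in annot_a or gb not in annot_b:
            continue
        ca, oa = annot_a.locate(ga)
        cb, ob = annot_b.locate(gb)
        if self_cmp:
            if ga == gb:
                continue
            if ca == cb:
                if oa >= ob or ob - oa <= max_gap:  # triangle + diagonal mask
                    continue
            elif ca > cb:  # hits come in both orders; keep one canonical side
                continue
        rows.append((ca, cb, oa, ob, ga, gb))
    by_pair: dict[tuple[str, str], dict[tuple[int, int], tuple[str, str]]] = {}
    for ca, cb, oa, ob, ga, gb in rows:
        by_pair.setdefault((ca, cb), {})[(oa, ob)] = (ga, gb)

    blocks: list[CollinearBlock] = []
    bid = 0
    for (ca, cb) in sorted(by_pair):
        genes = by_pair[(ca, cb)]
        for orientation, sign in (("+", 1), ("-", -1)):
            remaining = set(genes)
            while True:
                chain = _best_chain(list(remaining), max_gap, sign)
                if len(chain) < min_anchors:
                    break
                anchors = [(oa, ob, *genes[(oa, ob)]) for oa, ob in chain]
                blocks.append(
                    CollinearBlock(
                        block_id=bid,
                        genome_a=annot_a.name,
                        genome_b=annot_b.name,
                        chrom_a=ca,
                        chrom_b=cb,
                        orientation=orientation,
                        anchors=anchors,
                    )
                )
                bid += 1
                remaining -= set(chain)
                if len(remaining) < min_anchors:
                    break
    return blocks


def block_coverage(blocks: list[CollinearBlock], annotation: GenomeAnnotation) -> float:
    """Fraction of the genome's genes that anchor at least one block."""
    if len(annotation) == 0:
        return 0.0
    covered = set()
    for b in blocks:
        if b.genome_a == annotation.name:
            covered.update(a[2] for a in b.anchors)
        if b.genome_b == annotation.name:
            covered.update(a[3] for a in b.anchors)
    covered &= set(annotation.genes["gene_id"])
    return len(covered) / len(annotation)


def blocks_to_frame(blocks: list[CollinearBlock]) -> pd.DataFrame:
    """Block summary TSV frame (one row per block, anchor list packed)."""
    rows = []
    for b in blocks:
        rows.append(
            {
                "block_id": b.block_id,
                "genome_a": b.genome_a,
                "genome_b": b.genome_b,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "orientation": b.orientation,
                "n_anchors": b.n_anchors,
                "ks_median": np.nan if b.ks_median is None else b.ks_median,
                "anchors": ";".join(f"{a[2]},{a[3]}" for a in b.anchors),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["block_id", "genome_a", "genome_b", "chrom_a", "chrom_b",
                 "orientation", "n_anchors", "ks_median", "anchors"],
    )


def dotplot(
    blocks_or_hits,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    path: str,
    mixture=None,
) -> None:
    """Dot plot of homolog ordinals by chromosome pair.

    Accepts either a hits frame or a block list; with a fitted Ks mixture
    model, anchors are coloured by the mixture component closest to their
    block's Ks median.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    offs_a = _chrom_offsets(annot_a)
    offs_b = _chrom_offsets(annot_b)
    fig, ax = plt.subplots(figsize=(6, 6))
    if isinstance(blocks_or_hits, pd.DataFrame):
        xs, ys = [], []
        for ga, gb in zip(blocks_or_hits["gene_a"], blocks_or_hits["gene_b"]):
            if ga in annot_a and gb in annot_b:
                ca, oa = annot_a.locate(ga)
                cb, ob = annot_b.locate(gb)
                xs.append(offs_a[ca] + oa)
                ys.append(offs_b[cb] + ob)
        ax.scatter(xs, ys, s=2, c="0.4", linewidths=0)
    else:
        cmap = plt.get_cmap("tab10")
        for b in blocks_or_hits:
            xs = [offs_a[b.chrom_a] + a[0] for a in b.anchors]
            ys = [offs_b[b.chrom_b] + a[1] for a in b.anchors]
            color = "0.3"
            if mixture is not None and b.ks_median is not None:
                comp = int(
                    np.argmin([abs(b.ks_median - c.mean) for c in mixture.components])
                )
                color = cmap(comp % 10)
            ax.scatter(xs, ys, s=3, color=color, linewidths=0)
    for off in list(offs_a.values())[1:]:
        ax.axvline(off - 0.5, lw=0.3, c="0.8")
    for off in list(offs_b.values())[1:]:
        ax.axhline(off - 0.5, lw=0.3, c="0.8")
    ax.set_xlabel(f"{annot_a.name} gene ordinal")
    ax.set_ylabel(f"{annot_b.name} gene ordinal")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _chrom_offsets(annotation: GenomeAnnotation) -> dict[str, int]:
    offsets, off = {}, 0
    for chrom in annotation.chromosomes:
        offsets[chrom] = off
        off += annotation.chrom_size(chrom)
    return offsets
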