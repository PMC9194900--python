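"""Colinear depth ratios, subgenome assignment, and the multi-genome table.

The colinear depth of a gene is the number of distinct blocks of the other
genome covering its position; the modal depths in the two directions estimate
the two genomes' polyploidy multiplicities relative to their common ancestor
(e.g. 2:3 for a tetraploid descendant compared against a hexaploid one).
Query fragments covering a reference chromosome are partitioned into the
event's expected number of subgenome groups (no group may self-overlap on the
reference) and ranked by retained-gene count into dominant vs sensitive
subgenomes.  The event-related alignment table then stores, for every
reference gene in order, the colinear gene of each expected subgenome of each
query genome, with an absence mark where the expected gene is missing (gene
loss, translocation, or assembly gaps are not distinguished).

Subgenome group labels are positional per reference chromosome: column k of a
query genome need not correspond to the same parental subgenome on different
reference chromosomes (the true phase across chromosomes is not observable
from pairwise collinearity alone).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import gcd  # noqa: F401  (kept for depth-ratio experimentation)

import numpy as np
import pandas as pd

from wgdkit.annotation import GenomeAnnotation
from wgdkit.collinearity import CollinearBlock

logger = logging.getLogger(__name__)

ABSENT = "."


class IntegrityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# depth ratios
# ---------------------------------------------------------------------------


@dataclass
class DepthProfile:
    """Per-gene colinear depths in both directions and the modal-depth ratio.

    ``ratio`` is ``(modal depth over query genes, modal depth over reference
    genes)``; the first number estimates the reference genome's multiplicity,
    the second the query's (a reference region produced by a tetraploidy
    matches 2 regions in the query direction, etc.).  The ratio is reported
    as the raw pair of modal depths, not reduced (a 2:4 comparison is
    informative precisely because it is not 1:2).  ``None`` when no blocks.
    """

    ref_name: str
    query_name: str
    ref_depth: dict[str, np.ndarray]
    query_depth: dict[str, np.ndarray]
    ratio: tuple[int, int] | None

    def modal_depth(self, side: str) -> int | None:
        depths = self.ref_depth if side == "ref" else self.query_depth
        pooled = np.concatenate(list(depths.values())) if depths else np.array([])
        pooled = pooled[pooled >= 1]
        if len(pooled) == 0:
            return None
        vals, counts = np.unique(pooled, return_counts=True)
        return int(vals[np.argmax(counts)])


def depth_ratio(
    blocks: list[CollinearBlock],
    ref: GenomeAnnotation,
    query: GenomeAnnotation,
    min_anchors: int = 4,
) -> DepthProfile:
    """Colinear depth profile between a reference and a query genome.

    Per reference gene, depth = number of blocks (with >= ``min_anchors``
    anchors) whose reference-side span covers its ordinal; likewise for the
    query direction.  Modal depths are taken over genes with depth >= 1
    (zeros would bias ratios under heavy fractionation).
    """
    ref_depth = {c: np.zeros(ref.chrom_size(c), dtype=int) for c in ref.chromosomes}
    query_depth = {c: np.zeros(query.chrom_size(c), dtype=int) for c in query.chromosomes}
    self_cmp = ref.name == query.name
    used = 0
    for b in blocks:
        if b.n_anchors < min_anchors:
            continue
        if self_cmp:
            # both regions of a within-genome block act as ref and as query
            sides = [("ref", b.chrom_a, b.span_a()), ("ref", b.chrom_b, b.span_b()),
                     ("query", b.chrom_a, b.span_a()), ("query", b.chrom_b, b.span_b())]
        else:
            sides = []
            if b.genome_a == ref.name:
                sides.append(("ref", b.chrom_a, b.span_a()))
            if b.genome_b == ref.name:
                sides.append(("ref", b.chrom_b, b.span_b()))
            if b.genome_a == query.name:
                sides.append(("query", b.chrom_a, b.span_a()))
            if b.genome_b == query.name:
                sides.append(("query", b.chrom_b, b.span_b()))
        for side, chrom, (lo, hi) in sides:
            target = ref_depth if side == "ref" else query_depth
            if chrom in target:
                target[chrom][lo : hi + 1] += 1
        used += 1
    profile = DepthProfile(ref.name, query.name, ref_depth, query_depth, None)
    if used:
        mq = profile.modal_depth("query")
        mr = profile.modal_depth("ref")
        if mq is not None and mr is not None:
            profile.ratio = (mq, mr)
    return profile


# ---------------------------------------------------------------------------
# subgenome assignment
# ---------------------------------------------------------------------------


@dataclass
class SubgenomeAssignment:
    """Partition of query fragments into subgenome groups per ref chromosome."""

    query_name: str
    ref_name: str
    multiplicity: int
    block_group: dict[int, tuple[str, int]]  # block_id -> (ref_chrom, group index)
    groups: pd.DataFrame  # ref_chrom, group, n_anchors, retention, rank, dominance, tied
    overflow_fraction: float = 0.0

    def column_of(self, block_id: int) -> int | None:
        entry = self.block_group.get(block_id)
        return None if entry is None else entry[1]


def assign_subgenomes(
    blocks: list[CollinearBlock],
    query: GenomeAnnotation,
    ref: GenomeAnnotation,
    multiplicity: int,
    min_anchors: int = 4,
) -> SubgenomeAssignment:
    """Partition query fragments covering each reference chromosome.

    The reference must itself be unaffected by the event under study (the
    caller chooses it so).  Fragments are assigned greedily in reference
    order to the first of ``multiplicity`` groups whose fragments they do not
    overlap on the reference; groups are then ranked by retained anchor count
    (rank 0 = dominant, last = sensitive; ties get arbitrary order and are
    flagged).  A warning is logged when more than 5% of covered reference
    genes exceed the expected multiplicity - the event multiplicity is then
    likely wrong.
    """
    per_chrom: dict[str, list[CollinearBlock]] = {}
    for b in blocks:
        if b.n_anchors < min_anchors:
            continue
        if b.genome_a == ref.name and b.genome_b == query.name:
            per_chrom.setdefault(b.chrom_a, []).append(b)
        elif b.genome_b == ref.name and b.genome_a == query.name:
            per_chrom.setdefault(b.chrom_b, []).append(b)

    block_group: dict[int, tuple[str, int]] = {}
    rows = []
    overflow_genes = 0
    covered_genes = 0
    for chrom in sorted(per_chrom):
        frags = per_chrom[chrom]

        def ref_span(b):
            return b.span_a() if b.genome_a == ref.name else b.span_b()

        frags.sort(key=lambda b: (ref_span(b)[0], -b.n_anchors, b.block_id))
        group_end = [-1] * multiplicity
        group_anchors = [0] * multiplicity
        group_span = [0] * multiplicity
        depth = np.zeros(ref.chrom_size(chrom), dtype=int)
        for b in frags:
            lo, hi = ref_span(b)
            depth[lo : hi + 1] += 1
            free = [g for g in range(multiplicity) if group_end[g] < lo]
            g = free[0] if free else int(np.argmin(group_end))
            block_group[b.block_id] = (chrom, g)
            group_end[g] = max(group_end[g], hi)
            group_anchors[g] += b.n_anchors
            group_span[g] += hi - lo + 1
        covered_genes += int((depth >= 1).sum())
        overflow_genes += int((depth > multiplicity).sum())
        order = sorted(range(multiplicity), key=lambda g: -group_anchors[g])
        tied = len({group_anchors[g] for g in order}) < len(order)
        for rank, g in enumerate(order):
            dominance = (
                "dominant" if rank == 0
                else "sensitive" if rank == multiplicity - 1
                else "intermediate"
            )
            retention = group_anchors[g] / group_span[g] if group_span[g] else 0.0
            rows.append((chrom, g, group_anchors[g], retention, rank, dominance, tied))
    overflow = overflow_genes / covered_genes if covered_genes else 0.0
    if overflow > 0.05:
        logger.warning(
            "%.1f%% of reference genes exceed depth %d: event multiplicity likely wrong",
            100 * overflow, multiplicity,
        )
    groups = pd.DataFrame(
        rows, columns=["ref_chrom", "group", "n_anchors", "retention", "rank",
                       "dominance", "tied"],
    )
    return SubgenomeAssignment(query.name, ref.name, multiplicity, block_group, groups, overflow)


# ---------------------------------------------------------------------------
# alignment table
# ---------------------------------------------------------------------------


@dataclass
class AlignmentTable:
    """Event-related multi-genome alignment keyed by reference gene order.

    ``data`` has one row per reference gene (reference order preserved) and
    one column per expected subgenome: first the reference's own paralog
    columns, then each query genome's columns.  Cells hold a gene id or the
    absence mark ``.``.
    """

    ref_name: str
    expected: list[tuple[str, int]]  # (genome, expected depth), reference first
    data: pd.DataFrame  # index: ref gene ids; extra column 'chrom' leads
    assignments: dict[str, SubgenomeAssignment] = field(default_factory=dict)

    @property
    def header(self) -> str:
        depths = [d for _, d in self.expected]
        return f"{sum(depths)} = ({'+'.join(str(d) for d in depths)})"

    @property
    def n_columns(self) -> int:
        return sum(d for _, d in self.expected)

    def columns_of(self, genome: str) -> list[str]:
        return [c for c in self.data.columns if c.split(".")[0] == genome]

    def absence_counts(self) -> pd.Series:
        cols = [c for c in self.data.columns if c != "chrom"]
        return (self.data[cols] == ABSENT).sum()

    def to_csv(self, path: str) -> None:
        out = self.data.copy()
        out.insert(0, "ref_gene", out.index)
        with open(path, "w") as fh:
            fh.write(f"# columns: {self.header}\n")
            out.to_csv(fh, index=False)


def build_alignment_table(
    ref: GenomeAnnotation,
    queries: list[tuple[GenomeAnnotation, int, list[CollinearBlock]]],
    ref_self_blocks: list[CollinearBlock] | None = None,
    ref_depth: int = 1,
    min_anchors: int = 4,
) -> AlignmentTable:
    """Build the multi-genome alignment table on the reference gene order.

    ``queries`` holds (annotation, expected depth, ref-vs-query blocks); the
    reference's own paralog columns (when ``ref_depth`` > 1) are filled from
    ``ref_self_blocks``.  Blocks are consumed best-first (anchor count); a
    query gene landing in two different columns on one reference chromosome
    violates table integrity and raises.
    """
    index = list(ref.genes["gene_id"])
    chrom_series = pd.Series(list(ref.genes["chrom"]), index=index)
    data = pd.DataFrame({"chrom": chrom_series})
    assignments: dict[str, SubgenomeAssignment] = {}
    expected: list[tuple[str, int]] = [(ref.name, ref_depth)]

    data[f"{ref.name}.1"] = pd.Series(index, index=index)

    def fill(query: GenomeAnnotation, blocks, depth: int, first_col: int, self_cmp: bool):
        n_groups = depth - 1 if self_cmp else depth
        if n_groups < 1:
            return
        if self_cmp:
            # duplicate each block mirrored so both sides act as reference
            mirrored = []
            for b in blocks:
                mirrored.append(b)
                mirrored.append(
                    CollinearBlock(
                        block_id=-b.block_id - 1,
                        genome_a=b.genome_b, genome_b=b.genome_a,
                        chrom_a=b.chrom_b, chrom_b=b.chrom_a,
                        orientation=b.orientation,
                        anchors=[(ob, oa, gb, ga) for oa, ob, ga, gb in b.anchors],
                    )
                )
            blocks = mirrored
        assignment = assign_subgenomes(blocks, query, ref, n_groups, min_anchors)
        assignments[query.name if not self_cmp else ref.name] = assignment
        cols = [f"{query.name}.{first_col + g}" for g in range(n_groups)]
        for c in cols:
            data[c] = ABSENT
        seen: dict[tuple[str, str], str] = {}  # (ref_chrom, gene) -> column
        for b in sorted(blocks, key=lambda b: (-b.n_anchors, b.block_id)):
            entry = assignment.block_group.get(b.block_id)
            if entry is None:
                continue
            ref_chrom, g = entry
            col = cols[g]
            ref_side_a = b.genome_a == ref.name and b.chrom_a == ref_chrom
            for oa, ob, ga, gb in b.anchors:
                ref_gene, q_gene = (ga, gb) if ref_side_a else (gb, ga)
                if ref_gene not in data.index:
                    continue
                key = (ref_chrom, q_gene)
                prev = seen.get(key)
                if prev is not None and prev != col:
                    raise IntegrityError(
                        f"gene {q_gene!r} maps to columns {prev} and {col} "
                        f"on reference chromosome {ref_chrom}"
                    )
                if data.at[ref_gene, col] == ABSENT:
                    data.at[ref_gene, col] = q_gene
                    seen[key] = col

    if ref_depth > 1:
        fill(ref, ref_self_blocks or [], ref_depth, first_col=2, self_cmp=True)
    for query, depth, blocks in queries:
        expected.append((query.name, depth))
        fill(query, blocks, depth, first_col=1, self_cmp=False)

    return AlignmentTable(ref_name=ref.name, expected=expected, data=data,
                          assignments=assignments)


def local_alignment_view(table: AlignmentTable, chrom: str, path: str,
                         start: int = 0, end: int | None = None) -> None:
    """Stacked gene-track rendering of a reference region with homolog links."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = table.data[table.data["chrom"] == chrom]
    if end is None:
        end = len(sub)
    sub = sub.iloc[start:end]
    cols = [c for c in table.data.columns if c != "chrom"]
    fig, ax = plt.subplots(figsize=(10, 0.6 * len(cols) + 1))
    for y, col in enumerate(cols):
        present = (sub[col] != ABSENT).to_numpy()
        for i, p in enumerate(present):
            if p:
                ax.add_patch(plt.Rectangle((i, y - 0.3), 0.9, 0.6,
                                           color="steelblue", lw=0))
        if y > 0:
            prev = (sub[cols[y - 1]] != ABSENT).to_numpy()
            for i, (p, q) in enumerate(zip(prev, present)):
                if p and q:
                    ax.plot([i + 0.45, i + 0.45], [y - 1 + 0.3, y - 0.3],
                            c="0.7", lw=0.4)
    ax.set_yticks(range(len(cols)))
    ax.set_yticklabels(cols, fontsize=7)
    ax.set_xlim(-1, len(sub) + 1)
    ax.set_ylim(-1, len(cols))
    ax.set_xlabel(f"{table.ref_name} {chrom} gene ordinal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
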