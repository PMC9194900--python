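"""Gene-tree topology classification for WGD placement.

To decide whether a WGD is lineage-specific or shared, orthogroups are pulled
from the alignment table (one paralog pair of the genome under test plus the
required ortholog copies of other genomes), a tree is built (or supplied as
newick with bootstrap labels on internal nodes), and the topology at the key
node is classified: a paralog pair forming an exclusive clade supports a
lineage-specific WGD, while each paralog grouping with a different ortholog
copy of the putatively sharing genome supports a shared WGD.  A tree counts
as support only when the bootstrap of the key node reaches the threshold
(50% by default); trees below threshold are unresolved.

A neighbor-joining + bootstrap tree builder is included purely as a
lightweight stand-in so simulations run end to end; externally inferred
maximum-likelihood trees are first-class input via newick.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from wgdkit.depth_align import ABSENT, AlignmentTable

LINEAGE_SPECIFIC = "lineage_specific_wgd"
SHARED = "shared_wgd"
UNRESOLVED = "unresolved"
DEFAULT_BS_THRESHOLD = 50


@dataclass
class TopologyCall:
    """Classification of one gene tree at its key node."""

    tree_id: str
    label: str
    key_node_support: int
    passes: bool


# ---------------------------------------------------------------------------
# orthogroup selection
# ---------------------------------------------------------------------------


def select_orthogroups(
    table: AlignmentTable, pattern: dict[str, int]
) -> list[dict[str, list[str]]]:
    """Rows of the alignment table matching per-genome minimum copy counts.

    ``pattern`` maps genome name -> required number of non-absent copies
    among that genome's columns (at-least semantics, matching selections like
    "one pair of paralogous genes ... at least three orthologous genes").
    Returns one dict per selected row: genome -> list of gene ids.
    """
    for genome, need in pattern.items():
        cols = table.columns_of(genome)
        if not cols:
            raise ValueError(f"genome {genome!r} not in table")
        if need > len(cols):
            raise ValueError(
                f"pattern requires {need} copies of {genome!r} but the table "
                f"expects depth {len(cols)}"
            )
    groups = []
    col_map = {g: table.columns_of(g) for g in pattern}
    data = table.data
    masks = []
    for genome, need in pattern.items():
        count = (data[col_map[genome]] != ABSENT).sum(axis=1)
        masks.append(count >= need)
    selected = np.logical_and.reduce(masks) if masks else np.zeros(len(data), bool)
    for ref_gene in data.index[selected]:
        row = data.loc[ref_gene]
        groups.append(
            {g: [row[c] for c in col_map[g] if row[c] != ABSENT] for g in pattern}
        )
    return groups


# ---------------------------------------------------------------------------
# topology classification
# ---------------------------------------------------------------------------


def _support_of(node) -> int:
    label = node.label
    if label is None:
        return 0
    try:
        return int(round(float(label)))
    except ValueError:
        return 0


def classify_topology(
    newick: str,
    tags: dict[str, str],
    paralog_pair: tuple[str, str],
    sharing_genome: str | None = None,
    outgroup: str | None = None,
    threshold: int = DEFAULT_BS_THRESHOLD,
    tree_id: str = "",
) -> TopologyCall:
    """Classify one gene tree's topology at its key node.

    ``tags`` maps gene id -> genome label.  The tree supports a
    lineage-specific WGD when the paralog pair forms an exclusive clade (no
    other genome's genes inside) whose bootstrap reaches ``threshold``; it
    supports a shared WGD when each paralog groups with a different ortholog
    copy of ``sharing_genome`` (key support = the weaker of the two
    groupings).  Below-threshold or other topologies are unresolved.

    Classification works on bipartitions, so it is independent of tip order,
    branch lengths and rooting; ``outgroup``, when given, must be present
    (it anchors which side of a split is read as a clade, which only matters
    for trees whose root-side split is ambiguous).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    sides: list[tuple[frozenset, int]] = []  # (leafset of one side, support)
    all_leaves = frozenset(
        lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()
    )
    for node in tree.preorder_internal_node_iter():
        ls = frozenset(lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter())
        if 0 < len(ls) < len(all_leaves):
            sides.append((ls, _support_of(node)))

    p1, p2 = paralog_pair
    for g in paralog_pair:
        if g not in all_leaves:
            raise ValueError(f"paralog {g!r} not in tree")
    if outgroup is not None:
        if not any(tags.get(n) == outgroup for n in all_leaves):
            raise ValueError(f"outgroup genome {outgroup!r} absent from tree")

    pair_genome = tags.get(p1)

    def clades_with(pred):
        """Bipartition sides satisfying a predicate.

        The node's own (rooted-reading) side is preferred; the complement
        orientation is only used when no direct side matches, so the support
        label attached to a clade is not confused with its sibling's.
        """
        direct = [(ls, sup) for ls, sup in sides if pred(ls)]
        if direct:
            return direct
        return [(all_leaves - ls, sup) for ls, sup in sides if pred(all_leaves - ls)]

    # lineage-specific: a split isolating the pair (plus at most more genes
    # of the same genome) from every other genome
    exclusive = clades_with(
        lambda s: p1 in s and p2 in s and {tags.get(n) for n in s} <= {pair_genome}
    )
    if exclusive:
        support = max(sup for _, sup in exclusive)
        if support >= threshold:
            return TopologyCall(tree_id, LINEAGE_SPECIFIC, support, True)
        return TopologyCall(tree_id, UNRESOLVED, support, False)

    if sharing_genome is not None:
        partners = []
        for p, other in ((p1, p2), (p2, p1)):
            candidates = clades_with(
                lambda s: p in s
                and other not in s
                and any(tags.get(n) == sharing_genome for n in s)
            )
            if candidates:
                side, sup = min(candidates, key=lambda c: (len(c[0]), sorted(c[0])))
                share = {n for n in side if tags.get(n) == sharing_genome}
                partners.append((share, sup))
            else:
                partners.append(None)
        if all(p is not None for p in partners):
            (share1, s1), (share2, s2) = partners
            if share1.isdisjoint(share2):
                support = min(s1, s2)
                if support >= threshold:
                    return TopologyCall(tree_id, SHARED, support, True)
                return TopologyCall(tree_id, UNRESOLVED, support, False)

    return TopologyCall(tree_id, UNRESOLVED, 0, False)


def count_support(calls: list[TopologyCall], denominator: str = "all") -> pd.DataFrame:
    """Frequency table per topology label.

    ``denominator`` is 'all' (percentages over every tree) or 'passing'
    (over trees whose key node met the bootstrap threshold).  Percentages
    are reported at two decimals, in the usual "45.96% (91/198)" style.
    """
    if not calls:
        return pd.DataFrame(columns=["label", "count", "total", "percent"])
    if denominator == "passing":
        total = sum(1 for c in calls if c.passes) or 1
        counted = [c for c in calls if c.passes]
    else:
        total = len(calls)
        counted = calls
    counts = Counter(c.label for c in counted)
    rows = [
        (label, n, total, round(100.0 * n / total, 2))
        for label, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["label", "count", "total", "percent"])


# ---------------------------------------------------------------------------
# NJ + bootstrap stand-in
# ---------------------------------------------------------------------------


def _jc_distance_matrix(seqs: dict[str, str], cols: np.ndarray | None = None) -> np.ndarray:
    names = list(seqs)
    mat = np.array(
        [np.frombuffer(seqs[n].encode(), dtype=np.uint8) for n in names]
    )
    if cols is not None:
        mat = mat[:, cols]
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        diff = (mat[i] != mat[i + 1 :]).mean(axis=1)
        d = np.where(diff < 0.745, -0.75 * np.log1p(-4.0 * np.minimum(diff, 0.7449) / 3.0), 3.0)
        dm[i, i + 1 :] = d
        dm[i + 1 :, i] = d
    return dm


def _bipartitions(newick: str, taxa: frozenset) -> set[frozenset]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = set()
    for node in tree.preorder_internal_node_iter():
        ls = frozenset(lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter())
        if 1 < len(ls) < len(taxa):
            out.add(min(ls, taxa - ls, key=sorted))
    return out


def nj_tree(seqs: dict[str, str], bootstrap_reps: int = 100, seed: int = 0) -> str:
    """Neighbor-joining tree with bootstrap support, as a newick string.

    Distances are Jukes-Cantor on the (equal-length) concatenated alignment;
    supports are column-resampling bootstrap proportions written as internal
    node labels.  A deliberately lightweight stand-in for external
    maximum-likelihood trees, which remain the preferred input.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(seqs) < 4:
        raise ValueError("need >= 4 sequences for a supported NJ tree")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    names = list(seqs)
    taxa = frozenset(names)
    rng = np.random.default_rng(seed)
    L = lengths.pop()

    def build(cols=None):
        dm = _jc_distance_matrix(seqs, cols)
        dm = 0.5 * (dm + dm.T)
        tree = nj(DistanceMatrix(dm, names))
        return str(tree)

    main = build()
    main_parts = _bipartitions(main, taxa)
    hits = Counter()
    for _ in range(bootstrap_reps):
        cols = rng.integers(0, L, size=L)
        for part in _bipartitions(build(cols), taxa):
            hits[part] += 1

    tree = dendropy.Tree.get(data=main, schema="newick")
    for node in tree.preorder_internal_node_iter():
        ls = frozenset(lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter())
        if 1 < len(ls) < len(taxa):
            part = min(ls, taxa - ls, key=sorted)
            node.label = str(int(round(100.0 * hits[part] / bootstrap_reps)))
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
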