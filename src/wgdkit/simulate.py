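"""Genome-evolution simulator with an exact truth ledger.

The simulator evolves an ancestral genome along a species tree (branch
lengths in Myr), placing whole-genome duplications (WGDs) on chosen branches
and fractionating the duplicated copies by runs of consecutive gene losses
with geometric run lengths.  Every downstream statistic the package computes
(colinear blocks, Ks peaks, depth ratios, alignment tables, retention
windows, P-index, gene-tree topologies) can therefore be checked against
known truth.

Sequence model
--------------
Ancestral coding sequences are built from codons of the Ala/Thr/Pro/Ser
families (``NCN`` with a fixed C in second position), preceded by an ATG
start.  Each such codon has one fully fourfold-degenerate third position, so
synonymous divergence is an exact Jukes-Cantor process on third positions:
per-branch substitution draws compose exactly along any path, and the
Nei-Gojobori estimator applied to a pair of descendants is a consistent
estimator of the summed path length (in Ks units) between them.  This is a
deliberate idealisation: real codon usage mixes two- and fourfold-degenerate
sites, for which Nei-Gojobori is only approximately self-consistent.

Gene loss is drawn as runs: a uniformly random retained gene of the target
subgenome starts a deletion of L consecutive retained genes, L ~
geometric(run_p), until the per-subgenome loss budget is met (the last run is
trimmed).  Adjacent runs may merge in reference order, so observed loss-run
spectra are longer-tailed than the drawn ones; the truth ledger records both
the drawn run lengths and the per-gene fates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wgdkit.annotation import GenomeAnnotation

LOST = "LOST"
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_ATG = np.array([0, 3, 2], dtype=np.int8)  # A, T, G
_C = 1
KS_SATURATION_GUARD = 2.0


class SaturationError(ValueError):
    """Requested divergence beyond the simulator's Ks saturation guard."""


# ---------------------------------------------------------------------------
# scenario types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WgdEvent:
    """A polyploidy event placed on one branch of the species tree.

    multiplicity 2 is a tetraploidy, 3 a hexaploidy.  ``branch`` names the
    tree node (leaf taxon or internal node label) whose subtending edge
    carries the event; ``time_frac`` places it along that edge (0 = the
    rootward end, the default; 0.5 = halfway to the tipward end).
    ``loss_prob`` gives the fraction of genes lost per subgenome copy-set
    (one entry per copy-set) and ``run_p`` the geometric parameter of loss
    run lengths.  ``mode`` records whether the event is interpreted as an
    auto- or allopolyploidy (metadata; the loss probabilities carry the
    mechanism).
    """

    name: str
    multiplicity: int
    branch: str
    mode: str = "auto"
    loss_prob: tuple[float, ...] = ()
    run_p: float = 1.0
    time_frac: float = 0.0

    def __post_init__(self):
        if self.multiplicity < 2:
            raise ValueError("multiplicity must be >= 2")
        if not (0.0 <= self.time_frac < 1.0):
            raise ValueError("time_frac must lie in [0, 1)")
        lp = tuple(self.loss_prob) if self.loss_prob else (0.0,) * self.multiplicity
        object.__setattr__(self, "loss_prob", lp)
        if len(lp) != self.multiplicity:
            raise ValueError("need one loss probability per subgenome copy-set")
        if any(not (0.0 <= p < 1.0) for p in lp):
            raise ValueError("loss probabilities must lie in [0, 1)")
        if not (0.0 < self.run_p <= 1.0):
            raise ValueError("run_p must lie in (0, 1]")
        if self.mode not in ("auto", "allo"):
            raise ValueError("mode must be 'auto' or 'allo'")


@dataclass(frozen=True)
class LineageRate:
    """Multiplier scaling substitutions per Myr on one lineage's branch."""

    lineage: str
    multiplier: float

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be positive")


@dataclass
class Scenario:
    """Full description of a simulation: tree, events, rates, genome shape.

    ``species_tree`` is newick with branch lengths in Myr; internal nodes may
    carry labels so WGDs and rates can be placed on internal branches.
    ``ks_per_myr`` is the baseline synonymous substitution rate per site per
    Myr per lineage, so the true Ks peak of an event of age T on a lineage of
    rate r is 2 * r * T * ks_per_myr.
    """

    species_tree: str
    wgd_events: list[WgdEvent] = field(default_factory=list)
    rates: list[LineageRate] = field(default_factory=list)
    n_chromosomes: int = 1
    genes_per_chromosome: int = 100
    codons_per_gene: int = 100
    ks_per_myr: float = 0.004
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chromosomes, self.genes_per_chromosome, self.codons_per_gene) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class SimulationTruth:
    """Per-gene fate ledger and per-event true peaks.

    ``fates`` has one row per (ancestral gene, species, subgenome copy-set)
    with the descendant gene id or ``LOST``.  ``event_peaks[(event, species)]``
    and ``divergence_peaks[(sp_a, sp_b)]`` are the true Ks peak positions
    (2 x rate-weighted path length x ks_per_myr).  ``drawn_runs`` records the
    realized geometric loss-run lengths as drawn.
    """

    fates: pd.DataFrame
    event_peaks: dict[tuple[str, str], float]
    divergence_peaks: dict[tuple[str, str], float]
    drawn_runs: pd.DataFrame

    def retained(self, species: str) -> pd.DataFrame:
        f = self.fates
        return f[(f["species"] == species) & (f["descendant_id"] != LOST)]

    def observed_loss_spectrum(
        self, species: str, subgenome: str, ref_fates: pd.DataFrame | None = None
    ) -> dict[int, int]:
        """Maximal runs of lost genes along ancestral gene order.

        When ``ref_fates`` (a retained-fate frame of a reference genome) is
        given, the run structure is evaluated only at ancestral positions the
        reference retains, mirroring what an alignment-table column against
        that reference can see.
        """
        f = self.fates
        f = f[(f["species"] == species) & (f["subgenome"] == subgenome)]
        if ref_fates is not None:
            keep = set(ref_fates["ancestor_id"])
            f = f[f["ancestor_id"].isin(keep)]
        spectrum: dict[int, int] = {}
        for _, chrom_f in f.groupby("anc_chrom", sort=True):
            lost = (chrom_f.sort_values("anc_ordinal")["descendant_id"] == LOST).to_numpy()
            for key, grp in itertools.groupby(lost):
                if key:
                    run = sum(1 for _ in grp)
                    spectrum[run] = spectrum.get(run, 0) + 1
        return spectrum

    def write_tsv(self, path: str) -> None:
        self.fates.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# in-memory simulated genome
# ---------------------------------------------------------------------------


@dataclass
class _Gene:
    anc: str
    anc_chrom: str
    anc_ord: int
    seq: np.ndarray
    sub: tuple[tuple[str, str], ...] = ()  # ((event, label), ...)

    def copy(self) -> "_Gene":
        return _Gene(self.anc, self.anc_chrom, self.anc_ord, self.seq.copy(), self.sub)

    @property
    def subgenome(self) -> str:
        return "|".join(f"{e}.{lab}" for e, lab in self.sub)


_RUN_UID = itertools.count()


@dataclass
class SimGenome:
    """A genome being evolved: ordered genes per chromosome plus loss records."""

    name: str
    chroms: dict[str, list[_Gene]]
    lost: list[_Gene] = field(default_factory=list)
    run_records: list[tuple[str, str, int, int]] = field(default_factory=list)

    def copy(self, name: str | None = None) -> "SimGenome":
        return SimGenome(
            name or self.name,
            {c: [g.copy() for g in genes] for c, genes in self.chroms.items()},
            [g.copy() for g in self.lost],
            list(self.run_records),
        )

    def n_genes(self) -> int:
        return sum(len(v) for v in self.chroms.values())

    def gene_id(self, chrom: str, idx: int) -> str:
        return f"{self.name}_{chrom}_g{idx:05d}"

    @property
    def annotation(self) -> GenomeAnnotation:
        rows = []
        for chrom, genes in self.chroms.items():
            for i, g in enumerate(genes):
                rows.append(
                    {
                        "gene_id": self.gene_id(chrom, i),
                        "chrom": chrom,
                        "ordinal": i,
                        "start": i * 1000 + 1,
                        "end": i * 1000 + 3 * len(g.seq) // 3,
                        "strand": "+",
                        "subgenome": g.subgenome,
                    }
                )
        return GenomeAnnotation(name=self.name, genes=pd.DataFrame(rows))

    @property
    def cds(self) -> dict[str, str]:
        out = {}
        for chrom, genes in self.chroms.items():
            for i, g in enumerate(genes):
                out[self.gene_id(chrom, i)] = _NT[g.seq].tobytes().decode()
        return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_ancestor(
    n_chromosomes: int,
    genes_per_chromosome: int,
    codons_per_gene: int,
    seed: int,
    name: str = "anc",
) -> SimGenome:
    """Generate a random ancestral genome.

    Each gene is an in-frame CDS of ``codons_per_gene`` codons: an ATG start
    followed by random codons from the fourfold-degenerate NCN families (no
    internal stops by construction).  Gene order is the 0-based ordinal per
    chromosome.
    """
    if min(n_chromosomes, genes_per_chromosome, codons_per_gene) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    chroms: dict[str, list[_Gene]] = {}
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        genes = []
        for i in range(genes_per_chromosome):
            body = np.empty((codons_per_gene - 1, 3), dtype=np.int8)
            body[:, 0] = rng.integers(0, 4, size=codons_per_gene - 1)
            body[:, 1] = _C
            body[:, 2] = rng.integers(0, 4, size=codons_per_gene - 1)
            seq = np.concatenate([_ATG, body.ravel()])
            genes.append(_Gene(f"anc_{chrom}_g{i:05d}", chrom, i, seq))
        chroms[chrom] = genes
    return SimGenome(name=name, chroms=chroms)


def _jc_flip(seq_positions: np.ndarray, ks: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor draw of distance ``ks`` on an array of nucleotides."""
    p = 0.75 * (1.0 - np.exp(-4.0 * ks / 3.0))
    hit = rng.random(seq_positions.shape) < p
    shift = rng.integers(1, 4, size=seq_positions.shape)
    return np.where(hit, (seq_positions + shift) % 4, seq_positions).astype(np.int8)


def evolve_lineage(
    genome: SimGenome, ks_target: float, seed: int, ka_target: float = 0.0
) -> SimGenome:
    """Evolve all genes so expected pairwise Ks to the input equals ``ks_target``.

    Synonymous substitutions are a JC draw on third codon positions (which are
    all fourfold degenerate by construction); nonsynonymous substitutions, if
    requested, are a JC draw on first positions (always amino-acid changing
    within the NCN families, never creating stops).  Gene order is unchanged.
    """
    if ks_target < 0:
        raise ValueError("ks_target must be >= 0")
    if ks_target > KS_SATURATION_GUARD:
        raise SaturationError(
            f"ks_target {ks_target} beyond saturation guard {KS_SATURATION_GUARD}"
        )
    rng = np.random.default_rng(seed)
    out = genome.copy()
    if ks_target == 0 and ka_target == 0:
        return out
    for genes in out.chroms.values():
        for g in genes:
            codons = g.seq[3:].reshape(-1, 3)  # skip ATG
            if ks_target > 0:
                codons[:, 2] = _jc_flip(codons[:, 2], ks_target, rng)
            if ka_target > 0:
                codons[:, 0] = _jc_flip(codons[:, 0], ka_target, rng)
    return out


def apply_wgd(genome: SimGenome, event: WgdEvent, seed: int) -> SimGenome:
    """Duplicate the genome ``multiplicity``-fold and fractionate the copies.

    Every chromosome is copied (multiplicity - 1) extra times; copy-sets are
    labelled a, b, c...; then each copy-set loses ``loss_prob[k]`` of its
    genes, deleted in runs of geometric(run_p) consecutive retained genes.
    Loss runs and per-gene fates are recorded on the returned genome.
    """
    if genome.n_genes() == 0:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(seed)
    labels = [chr(ord("a") + k) for k in range(event.multiplicity)]
    out = SimGenome(genome.name, {}, [g.copy() for g in genome.lost], list(genome.run_records))
    subgenomes: dict[str, list[str]] = {}  # label -> its chromosome ids
    for chrom, genes in genome.chroms.items():
        for lab in labels:
            new_chrom = f"{chrom}-{event.name}{lab}"
            copies = []
            for g in genes:
                ng = g.copy()
                ng.sub = g.sub + ((event.name, lab),)
                copies.append(ng)
            out.chroms[new_chrom] = copies
            subgenomes.setdefault(lab, []).append(new_chrom)

    for lab, p_loss in zip(labels, event.loss_prob):
        if p_loss <= 0:
            continue
        chrom_ids = subgenomes[lab]
        n_total = sum(len(out.chroms[c]) for c in chrom_ids)
        budget = int(round(p_loss * n_total))
        deleted = 0
        while deleted < budget:
            # pick a uniformly random retained gene of this subgenome
            sizes = np.array([len(out.chroms[c]) for c in chrom_ids])
            flat = rng.integers(0, sizes.sum())
            ci = int(np.searchsorted(np.cumsum(sizes), flat, side="right"))
            chrom = chrom_ids[ci]
            j = int(flat - (np.cumsum(sizes)[ci] - sizes[ci]))
            run = int(rng.geometric(event.run_p))
            run = min(run, budget - deleted, len(out.chroms[chrom]) - j)
            if run <= 0:
                continue
            removed = out.chroms[chrom][j : j + run]
            del out.chroms[chrom][j : j + run]
            out.lost.extend(removed)
            out.run_records.append((event.name, lab, run, next(_RUN_UID)))
            deleted += run
    return out


# ---------------------------------------------------------------------------
# scenario runner
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Leaf genomes plus the truth ledger of a simulated scenario."""

    scenario: Scenario
    genomes: dict[str, SimGenome]
    truth: SimulationTruth

    def annotation(self, species: str) -> GenomeAnnotation:
        return self.genomes[species].annotation

    def cds(self, species: str) -> dict[str, str]:
        return self.genomes[species].cds

    def hits(self, species_a: str, species_b: str, seed: int = 0) -> pd.DataFrame:
        """Synthetic all-vs-all homolog hits (BLAST outfmt6 columns).

        One row per ordered pair of genes sharing an ancestral gene (truth
        homologs), with plausible score/identity values.  Stands in for an
        external BLASTP run, which the pipeline otherwise consumes as input.
        """
        rng = np.random.default_rng(seed)
        ra = self.truth.retained(species_a)
        rb = self.truth.retained(species_b)
        a_by_anc: dict[str, list[str]] = {}
        for anc, gid in zip(ra["ancestor_id"], ra["descendant_id"]):
            a_by_anc.setdefault(anc, []).append(gid)
        rows = []
        for anc, gid_b in zip(rb["ancestor_id"], rb["descendant_id"]):
            for gid_a in a_by_anc.get(anc, ()):
                if gid_a == gid_b:
                    continue
                ident = round(float(rng.uniform(78.0, 99.0)), 1)
                score = round(float(400.0 + rng.uniform(0, 25.0)), 1)
                rows.append(
                    (gid_a, gid_b, ident, 300, 10, 0, 1, 300, 1, 300, 1e-50, score)
                )
        cols = [
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ]
        return pd.DataFrame(rows, columns=cols)

    def hit_pairs(self, species_a: str, species_b: str, seed: int = 0) -> pd.DataFrame:
        """Hits in the filtered gene_a/gene_b/score/evalue form chaining expects."""
        df = self.hits(species_a, species_b, seed)
        df = df.rename(columns={"qseqid": "gene_a", "sseqid": "gene_b", "bitscore": "score"})
        return df[["gene_a", "gene_b", "score", "evalue"]]

    def write_hits(self, species_a: str, species_b: str, path: str, seed: int = 0) -> None:
        self.hits(species_a, species_b, seed).to_csv(
            path, sep="\t", header=False, index=False
        )


def _rate_of(label: str | None, rates: dict[str, float]) -> float:
    return rates.get(label, 1.0) if label else 1.0


def simulate_scenario(scenario: Scenario) -> SimulationResult:
    """Run a full scenario: evolve the ancestor down the species tree.

    Each leaf of the species tree yields one genome.  WGD events fire at the
    rootward end of their branch; fractionation is applied instantaneously at
    the event (losses are then shared by all descendant leaves of that
    branch).  True event peaks are recorded as 2 x (rate-weighted path from
    the event to the leaf) x ks_per_myr.
    """
    import dendropy

    tree = dendropy.Tree.get(data=scenario.species_tree, schema="newick")
    tree.is_rooted = True
    rates = {r.lineage: r.multiplier for r in scenario.rates}

    def node_label(nd):
        return nd.taxon.label.replace(" ", "_") if nd.taxon else nd.label

    known = {node_label(nd) for nd in tree if node_label(nd)}
    for ev in scenario.wgd_events:
        if ev.branch not in known:
            raise ValueError(f"WGD {ev.name!r} placed on unknown branch {ev.branch!r}")

    def edge_ks(nd) -> float:
        length = nd.edge.length or 0.0
        return _rate_of(node_label(nd), rates) * length * scenario.ks_per_myr

    rng = np.random.default_rng(scenario.seed)
    ancestor = generate_ancestor(
        scenario.n_chromosomes,
        scenario.genes_per_chromosome,
        scenario.codons_per_gene,
        seed=int(rng.integers(2**31)),
    )

    events_on = {}
    for ev in scenario.wgd_events:
        events_on.setdefault(ev.branch, []).append(ev)

    genomes: dict[str, SimGenome] = {}
    event_peaks: dict[tuple[str, str], float] = {}
    # ks-distance from each event point down to each node (accumulated)
    state: dict[int, tuple[SimGenome, dict[str, float]]] = {
        id(tree.seed_node): (ancestor, {})
    }

    order = tree.preorder_node_iter()
    next(order)  # seed node holds the ancestor
    for nd in order:
        parent_genome, parent_depths = state[id(nd.parent_node)]
        genome = parent_genome.copy()
        depths = dict(parent_depths)
        label = node_label(nd)
        step = edge_ks(nd)
        pos = 0.0  # fraction of this edge already evolved

        def advance(to_frac):
            nonlocal genome, pos
            seg = (to_frac - pos) * step
            if seg > 0:
                genome = evolve_lineage(genome, seg, seed=int(rng.integers(2**31)))
                for ev_name in depths:
                    depths[ev_name] += seg
            pos = to_frac

        for ev in sorted(events_on.get(label, ()), key=lambda e: e.time_frac):
            advance(ev.time_frac)
            genome = apply_wgd(genome, ev, seed=int(rng.integers(2**31)))
            depths[ev.name] = 0.0
        advance(1.0)
        state[id(nd)] = (genome, depths)
        if nd.is_leaf():
            genome.name = label
            genomes[label] = genome
            for ev_name, d in depths.items():
                event_peaks[(ev_name, label)] = 2.0 * d

    # species-pair divergence peaks
    divergence_peaks: dict[tuple[str, str], float] = {}
    leaves = list(tree.leaf_node_iter())
    for i, la in enumerate(leaves):
        for lb in leaves[i + 1 :]:
            sa, sb = node_label(la), node_label(lb)
            mrca = tree.mrca(taxa=[la.taxon, lb.taxon])
            total = 0.0
            for leaf in (la, lb):
                nd = leaf
                while nd is not mrca:
                    total += edge_ks(nd)
                    nd = nd.parent_node
            divergence_peaks[(sa, sb)] = total
            divergence_peaks[(sb, sa)] = total

    # fate ledger
    fate_rows = []
    for sp, genome in genomes.items():
        for chrom, genes in genome.chroms.items():
            for i, g in enumerate(genes):
                fate_rows.append(
                    (g.anc, g.anc_chrom, g.anc_ord, sp, genome.gene_id(chrom, i),
                     g.subgenome, "|".join(e for e, _ in g.sub))
                )
        for g in genome.lost:
            fate_rows.append(
                (g.anc, g.anc_chrom, g.anc_ord, sp, LOST, g.subgenome,
                 "|".join(e for e, _ in g.sub))
            )
    fates = pd.DataFrame(
        fate_rows,
        columns=["ancestor_id", "anc_chrom", "anc_ordinal", "species",
                 "descendant_id", "subgenome", "event"],
    ).sort_values(["species", "anc_chrom", "anc_ordinal", "subgenome"]).reset_index(drop=True)

    # runs drawn on a shared branch are carried by every descendant leaf;
    # the uid recorded at draw time deduplicates them to one row per draw
    runs = pd.DataFrame(
        [(sp, ev, lab, ln, uid)
         for sp, g in genomes.items() for ev, lab, ln, uid in g.run_records],
        columns=["species", "event", "subgenome", "length", "uid"],
    ).drop_duplicates(subset=["event", "subgenome", "uid"]).drop(columns="uid")

    peaks = {k: v for k, v in event_peaks.items()}
    truth = SimulationTruth(
        fates=fates, event_peaks=peaks, divergence_peaks=divergence_peaks, drawn_runs=runs
    )
    return SimulationResult(scenario=scenario, genomes=genomes, truth=truth)
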