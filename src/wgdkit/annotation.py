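"""Gene annotations as ordered gene lists per chromosome.

Coordinates are 1-based inclusive on disk (GFF3) and 0-based ordinals in
memory; all collinearity machinery works on ordinals only (gene order, not
base-pair positions).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "ordinal", "start", "end", "strand", "subgenome"]


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one genome.

    Parameters
    ----------
    name : str
        Genome (species) label, used in table headers and configs.
    genes : pandas.DataFrame
        One row per gene with columns ``gene_id, chrom, ordinal, start, end,
        strand, subgenome``.  ``ordinal`` is the 0-based rank of the gene on
        its chromosome; ``subgenome`` is an optional truth label (simulator
        output) and may be empty.
    """

    name: str
    genes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", "chrom", "ordinal") if c not in self.genes]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        g = self.genes.copy()
        for col, default in (("start", 0), ("end", 0), ("strand", "+"), ("subgenome", "")):
            if col not in g:
                g[col] = default
        g = g[GENE_COLUMNS].sort_values(["chrom", "ordinal"], kind="stable")
        g = g.reset_index(drop=True)
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicated gene id: {dup!r}")
        self.genes = g
        self._ordinal = dict(zip(g["gene_id"], zip(g["chrom"], g["ordinal"])))

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._ordinal

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.genes["chrom"]))

    def locate(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chrom, ordinal)`` of a gene."""
        return self._ordinal[gene_id]

    def chrom_genes(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]

    def chrom_size(self, chrom: str) -> int:
        return int((self.genes["chrom"] == chrom).sum())

    def gene_order(self, chrom: str) -> list[str]:
        """Gene ids of one chromosome in ordinal order."""
        return list(self.chrom_genes(chrom)["gene_id"])

    # -- I/O -----------------------------------------------------------

    @classmethod
    def from_gff3(cls, path: str, name: str) -> "GenomeAnnotation":
        """Read gene features from a GFF3 file.

        Only ``gene`` features are used; genes are ordered by start position
        per chromosome to assign ordinals.  The ``subgenome=`` attribute, when
        present, is kept as a truth label.
        """
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = []
        for f in db.features_of_type("gene"):
            rows.append(
                {
                    "gene_id": f.attributes.get("ID", [f.id])[0],
                    "chrom": f.seqid,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand or "+",
                    "subgenome": f.attributes.get("subgenome", [""])[0],
                }
            )
        if not rows:
            raise ValueError(f"no gene features in {path}")
        df = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="stable")
        df["ordinal"] = df.groupby("chrom").cumcount()
        return cls(name=name, genes=df)

    @classmethod
    def from_bed(cls, path: str, name: str) -> "GenomeAnnotation":
        """Read a BED-like gene list: chrom, start, end, gene_id[, score, strand]."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene_id"],
        )
        df["start"] = df["start"] + 1  # BED is 0-based half-open
        df = df.sort_values(["chrom", "start"], kind="stable")
        df["ordinal"] = df.groupby("chrom").cumcount()
        df["strand"] = "+"
        df["subgenome"] = ""
        return cls(name=name, genes=df)

    def to_gff3(self, path: str) -> None:
        """Write gene features as GFF3 (1-based, ``ID=`` and ``subgenome=``)."""
        buf = io.StringIO()
        buf.write("##gff-version 3\n")
        for row in self.genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            if row.subgenome:
                attrs += f";subgenome={row.subgenome}"
            buf.write(
                f"{row.chrom}\twgdkit\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def read_cds_fasta(path: str) -> dict[str, str]:
    """Read a CDS FASTA into an id -> sequence dict (ids match GFF3 IDs)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_cds_fasta(cds: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for gid, seq in cds.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
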