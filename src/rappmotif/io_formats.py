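"""Readers and writers for the pipeline's external formats.

Protein FASTA (one file per genome), GFF3 annotation, a two-column
taxonomy TSV (genome_id -> phylum/class), and Newick trees.  All
coordinate conventions are fixed here: genomic and protein coordinates
are 1-based inclusive throughout, matching the GFF3 standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser
from gffutils.feature import feature_from_line


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence tied to its genome of origin.

    The sequence is stored uppercased with any terminal stop character
    ``*`` stripped (downloaded translations sometimes include it, and it
    would otherwise create spurious 4-mers).  Non-standard letters
    (X/B/Z/J/U/O) are retained; downstream window counting decides how
    to treat them.
    """

    protein_id: str
    genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"whitespace in sequence of {self.protein_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A genome's proteins plus its clade label (phylum, or class for
    Pseudomonadota).  The unit over which frequency bias is computed."""

    genome_id: str
    clade: str
    proteins: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.genome_id!r} has no proteins")

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def with_clade(self, clade: str) -> "Proteome":
        return Proteome(self.genome_id, clade, self.proteins)


@dataclass(frozen=True)
class GeneFeature:
    """A CDS feature from a GFF3 file; 1-based inclusive coordinates."""

    feature_id: str
    contig: str
    start: int
    end: int
    strand: str
    product_annotation: str = ""
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad coordinates {self.start}..{self.end} for {self.feature_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.feature_id!r}")


def read_protein_fasta(path: str | Path, genome_id: str) -> Proteome:
    """Read a protein FASTA file into a Proteome (clade left blank).

    Sequences are uppercased and a single terminal ``*`` is stripped.
    Raises on an empty file and on duplicate record identifiers.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            pid = title.split()[0] if title.split() else title
            if pid in seen:
                raise ValueError(f"duplicate record identifier {pid!r} in {path}")
            seen.add(pid)
            seq = seq.upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            records.append(ProteinRecord(pid, genome_id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Proteome(genome_id=genome_id, clade="", proteins=records)


def write_protein_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as out:
        for rec in proteome:
            out.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read CDS features from a GFF3 file, sorted by (contig, start).

    Only CDS features participate in the neighborhood analysis;
    rRNA/tRNA/pseudogene lines are ignored.  ``product_annotation`` comes
    from the ``product`` attribute (empty string if absent), and
    ``protein_id`` from ``protein_id`` falling back to ``ID``.
    """
    features: list[GeneFeature] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing embedded FASTA section
                break
            ncols = line.count("\t") + 1
            if ncols != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {ncols}"
                )
            feat = feature_from_line(line)
            if feat.featuretype != "CDS":
                continue
            product = feat.attributes.get("product", [""])[0]
            pid = (
                feat.attributes.get("protein_id", [None])[0]
                or feat.attributes.get("ID", [None])[0]
            )
            features.append(
                GeneFeature(
                    feature_id=feat.attributes.get("ID", [pid or f"line{lineno}"])[0],
                    contig=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    product_annotation=product,
                    protein_id=pid,
                )
            )
    features.sort(key=lambda f: (f.contig, f.start))
    return features


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated genome_id -> clade table.

    ``#``-prefixed comment lines are allowed.  A genome mapped twice to
    different clades is an error.
    """
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            genome_id, clade = parts
            if genome_id in mapping and mapping[genome_id] != clade:
                raise ValueError(
                    f"{path}: genome {genome_id!r} mapped to both "
                    f"{mapping[genome_id]!r} and {clade!r}"
                )
            mapping[genome_id] = clade
    return mapping


def write_taxonomy(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("# genome_id\tclade\n")
        for genome_id, clade in mapping.items():
            out.write(f"{genome_id}\t{clade}\n")


def prune_tree(newick_text: str, keep: Iterable[str]) -> str:
    """Prune a Newick tree down to the leaves in ``keep``.

    Unary internal nodes left by the pruning are collapsed with branch
    lengths summed along the collapsed path, so root-to-leaf path
    lengths of retained leaves are preserved.  Raises if ``keep``
    contains labels absent from the tree.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set is empty")
    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    labels = {t.label for t in tree.taxon_namespace}
    missing = sorted(keep - labels)
    if missing:
        raise ValueError(f"labels not in tree: {', '.join(missing)}")
    tree.retain_taxa_with_labels(sorted(keep))
    # retain_taxa suppresses unifurcations, summing edge lengths; make the
    # root edge explicit too so path lengths are preserved exactly.
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return out


def leaf_depths(newick_text: str) -> dict[str, float]:
    """Root-to-leaf path lengths, treating a missing edge length as 0."""
    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node is not None:
            if node.edge.length is not None:
                d += node.edge.length
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths
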