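"""Readers, writers and domain types for the formats the pipeline touches.

All coordinates are 1-based and inclusive on both ends, matching GFF3.
No function in this module ever converts coordinates silently.

Formats handled:

* FASTA (nucleotide and amino acid), via Biopython.
* GFF3 restricted to CDS features with a mandatory ``ID=`` attribute.
  Because GFF3 has no standard slot for the chromosome/plasmid
  distinction, replicon kind and owning strain are carried in a
  ``##replicon-kind <replicon_id> <kind> <strain_id>`` pragma.
* Newick with branch lengths and optional integer support labels,
  via scikit-bio.
* Labeled rectangular TSV matrices (booleans serialized as 0/1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

REPLICON_KINDS = ("chromosome", "plasmid")

#: NCBI translation table used throughout (bacterial, archaeal, plant plastid).
TRANSLATION_TABLE = 11


@dataclass
class Replicon:
    """A chromosome or plasmid of one strain."""

    replicon_id: str
    strain_id: str
    kind: str
    length_bp: int
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in REPLICON_KINDS:
            raise ValueError(f"unknown replicon kind {self.kind!r}")
        if self.length_bp < 1:
            raise ValueError(f"replicon {self.replicon_id}: length_bp must be >= 1")
        if self.seq is not None and len(self.seq) != self.length_bp:
            raise ValueError(
                f"replicon {self.replicon_id}: sequence length "
                f"{len(self.seq)} != length_bp {self.length_bp}"
            )


@dataclass
class GeneFeature:
    """An annotated CDS. ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product: str = "hypothetical protein"
    protein_seq: str = ""
    nt_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.gene_id}: invalid coordinates "
                             f"{self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Alignment:
    """A gap-aware multiple alignment: equal-length rows over taxa."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate taxon names in alignment")
        if not self.rows or len(self.rows[0]) < 1:
            raise ValueError("alignment must have length >= 1")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{name: SEQUENCE}`` mapping (uppercased).

    Rejects duplicate record names.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as line-wrapped FASTA (uppercased)."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty FASTA file")
    recs = [SeqRecord(Seq(seq.upper()), id=name, description="")
            for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Translation

_START_CODONS = {"ATG", "GTG", "TTG", "ATT", "CTG"}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CdsTranslationError(ValueError):
    pass


def translate_cds(nt_seq: str, gene_id: str = "?") -> str:
    """Translate a CDS with the bacterial code (table 11).

    Alternative start codons are translated as M, the convention for
    annotated CDSs. A trailing stop codon is dropped. An internal stop
    codon raises :class:`CdsTranslationError` (the caller decides whether
    to skip the CDS); truncating silently would hide broken annotations.
    """
    nt = nt_seq.upper()
    if len(nt) < 3 or len(nt) % 3 != 0:
        raise CdsTranslationError(
            f"CDS {gene_id}: length {len(nt)} is not a positive codon multiple")
    prot = str(Seq(nt).translate(table=TRANSLATION_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise CdsTranslationError(f"CDS {gene_id}: internal stop codon")
    if nt[:3] in _START_CODONS:
        prot = "M" + prot[1:]
    if not prot:
        raise CdsTranslationError(f"CDS {gene_id}: empty translation")
    return prot


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, fasta_path: str | Path
              ) -> tuple[list[Replicon], list[GeneFeature]]:
    """Read CDS features from GFF3, with replicon sequences from FASTA.

    Every CDS becomes one :class:`GeneFeature` with its protein translated
    from the replicon sequence (reverse complement for minus-strand CDSs).
    Replicon kind and strain come from ``##replicon-kind`` pragmas; a
    replicon without a pragma defaults to a chromosome of strain ''.

    Raises ``ValueError`` for a CDS outside its replicon bounds or a
    replicon without sequence. A CDS whose translation contains an
    internal stop is skipped with a warning.
    """
    seqs = read_fasta(fasta_path)
    kinds: dict[str, tuple[str, str]] = {}
    rows: list[tuple[str, int, int, str, dict[str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##replicon-kind"):
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed replicon-kind pragma")
                rid, kind = parts[1], parts[2]
                strain = parts[3] if len(parts) > 3 else ""
                kinds[rid] = (kind, strain)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr = {}
            for kv in attrs.split(";"):
                if kv and "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k] = unquote(v)
            if "ID" not in attr:
                raise ValueError(f"{path}:{lineno}: CDS without ID attribute")
            rows.append((seqid, int(start), int(end), strand, attr))

    replicons: dict[str, Replicon] = {}
    for rid in sorted({r[0] for r in rows} | set(kinds)):
        if rid not in seqs:
            raise ValueError(f"{path}: replicon {rid!r} has no sequence in {fasta_path}")
        kind, strain = kinds.get(rid, ("chromosome", ""))
        replicons[rid] = Replicon(rid, strain, kind, len(seqs[rid]), seqs[rid])

    genes: list[GeneFeature] = []
    for seqid, start, end, strand, attr in rows:
        rep = replicons.get(seqid)
        if rep is None:
            raise ValueError(f"{path}: CDS {attr['ID']} on unknown replicon {seqid!r}")
        if not (1 <= start <= end <= rep.length_bp):
            raise ValueError(
                f"{path}: CDS {attr['ID']} at {seqid}:{start}-{end} outside "
                f"replicon bounds 1-{rep.length_bp}")
        nt = rep.seq[start - 1:end]
        if strand == "-":
            nt = reverse_complement(nt)
        try:
            prot = translate_cds(nt, attr["ID"])
        except CdsTranslationError as exc:
            warnings.warn(f"skipping CDS: {exc}")
            continue
        genes.append(GeneFeature(
            gene_id=attr["ID"], replicon_id=seqid, start=start, end=end,
            strand=strand, product=attr.get("product", "hypothetical protein"),
            protein_seq=prot, nt_seq=nt))
    return list(replicons.values()), genes


def write_gff3(replicons: Iterable[Replicon], genes: Iterable[GeneFeature],
               path: str | Path) -> None:
    """Write CDS features as GFF3 with replicon-kind pragmas."""
    replicons = list(replicons)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length_bp}\n")
        for rep in replicons:
            fh.write(f"##replicon-kind {rep.replicon_id} {rep.kind} {rep.strain_id}\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.start, g.gene_id)):
            attrs = f"ID={quote(g.gene_id, safe='')};product={quote(g.product, safe=' ')}"
            fh.write("\t".join([
                g.replicon_id, "genetrait", "CDS", str(g.start), str(g.end),
                ".", g.strand, "0", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> TreeNode:
    """Parse a Newick tree (branch lengths, optional integer supports)."""
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Labeled TSV matrices


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled rectangular matrix as TSV (booleans become 0/1)."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("refusing to write an empty matrix")
    out = matrix.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index_label="")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a labeled TSV matrix; rejects ragged rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.isna().any().any():
        raise ValueError(f"ragged or incomplete matrix in {path}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    return df
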