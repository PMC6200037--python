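"""Genomic-context profiling of a located gene cluster.

Two questions about the neighborhood of a cluster occurrence: how widely
is each neighboring gene conserved across the other strains of the
panel (ortholog presence, counted per strain rather than per copy), and
which neighbors are mobile-element genes (transposases / insertion
sequences, flagged from product annotations)? Wide conservation of a
flank among cluster carriers only, together with transposase flanks, is
the signature of a horizontally mobile element.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .clustering import GeneFamily
from .io_formats import GeneFeature

DEFAULT_FLANK_BP = 10_000

#: case-insensitive product keywords flagging mobile-element genes
TRANSPOSASE_KEYWORDS = ("transposase", "insertion sequence", "IS element")


@dataclass
class ContextEntry:
    gene_id: str
    family_id: str | None
    start: int
    end: int
    strand: str
    is_transposase: bool
    conservation: float  # fraction of other strains with >= 1 family member


@dataclass
class ContextProfile:
    reference_strain: str
    replicon_id: str
    span_start: int
    span_end: int
    entries: list[ContextEntry]


def extract_context(genes: Sequence[GeneFeature],
                    replicon_id: str, start: int, end: int,
                    flank_bp: int = DEFAULT_FLANK_BP,
                    replicon_length: int | None = None) -> list[GeneFeature]:
    """Genes overlapping the focal span extended by ``flank_bp`` per side.

    Coordinates are closed intervals: any shared base counts as overlap,
    so a gene ending exactly at ``start - flank_bp`` is included. The
    window is clipped to replicon bounds. Returns genes sorted by start.
    """
    lo = max(1, start - flank_bp)
    hi = end + flank_bp
    if replicon_length is not None:
        hi = min(hi, replicon_length)
    out = [g for g in genes
           if g.replicon_id == replicon_id and g.end >= lo and g.start <= hi]
    return sorted(out, key=lambda g: (g.start, g.gene_id))


def flag_transposases(genes: Sequence[GeneFeature],
                      keywords: Sequence[str] = TRANSPOSASE_KEYWORDS
                      ) -> dict[str, bool]:
    """gene_id -> True iff the product matches a mobile-element keyword
    (case-insensitive substring match)."""
    pats = [re.compile(re.escape(k), re.IGNORECASE) for k in keywords]
    return {g.gene_id: any(p.search(g.product) for p in pats) for g in genes}


def conservation_profile(context_genes: Sequence[GeneFeature],
                         families: Sequence[GeneFamily],
                         strains: Sequence[str],
                         reference_strain: str) -> ContextProfile:
    """Per-gene conservation of a genomic neighborhood across the panel.

    The conservation of gene g is the fraction of the *other* strains in
    which g's family has at least one member; strains are counted once
    however many paralogs they hold, and a gene whose family spans no
    other strain scores 0.
    """
    if reference_strain not in strains:
        raise ValueError(f"reference strain {reference_strain!r} not in panel")
    others = [s for s in strains if s != reference_strain]
    if not others:
        raise ValueError("panel must contain more than the reference strain")
    gene_to_family: dict[str, GeneFamily] = {}
    for fam in families:
        for gids in fam.members.values():
            for gid in gids:
                gene_to_family[gid] = fam

    tnp = flag_transposases(context_genes)
    entries = []
    for g in sorted(context_genes, key=lambda g: (g.start, g.gene_id)):
        fam = gene_to_family.get(g.gene_id)
        if fam is None:
            cons, fid = 0.0, None
        else:
            cons = sum(1 for s in others if s in fam.members) / len(others)
            fid = fam.family_id
        entries.append(ContextEntry(
            gene_id=g.gene_id, family_id=fid, start=g.start, end=g.end,
            strand=g.strand, is_transposase=tnp[g.gene_id], conservation=cons))
    if not entries:
        raise ValueError("no genes in the context window")
    return ContextProfile(
        reference_strain=reference_strain,
        replicon_id=context_genes[0].replicon_id,
        span_start=min(e.start for e in entries),
        span_end=max(e.end for e in entries),
        entries=entries)
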