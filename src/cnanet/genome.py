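"""Gene annotation handling and altered-region -> gene-set mapping.

Altered cytobands are translated into per-sample, per-condition gene sets:
the union of protein-coding genes overlapping any altered band (gains and
losses pooled, so each sample/condition yields one network downstream).
Non-protein-coding entries (ORFs, miRNAs, ...) are excluded by default, and
the cytoband/direction provenance of every selected gene is retained.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .cna import CNASegment, CytobandAlteration, CytobandMap

__all__ = [
    "GeneAnnotation",
    "GeneSet",
    "load_gene_annotation",
    "write_gene_annotation",
    "build_gene_set",
    "build_gene_set_from_segments",
    "load_alias_map",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval; biotype is protein_coding or other (0-based half-open)."""

    symbol: str
    chrom: str
    start: int
    end: int
    biotype: str  # "protein_coding" or "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.symbol}: start {self.start} >= end {self.end}"
            )
        if self.biotype not in ("protein_coding", "other"):
            raise ValueError(
                f"gene {self.symbol}: biotype must be protein_coding or other, "
                f"got {self.biotype!r}"
            )


def load_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Load a BED-like gene TSV: chrom, start, end, symbol, biotype.

    Coordinates are 0-based half-open (standard BED).  Any biotype other
    than ``protein_coding`` is normalized to ``other`` at load time;
    filtering happens later in :func:`build_gene_set`.  Duplicate symbols
    are an error.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(fields)}"
                )
            chrom, start_s, end_s, symbol, biotype = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            if symbol in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate gene symbol {symbol!r} "
                    f"(first seen on line {seen[symbol]})"
                )
            seen[symbol] = lineno
            genes.append(
                GeneAnnotation(
                    symbol=symbol,
                    chrom=chrom,
                    start=start,
                    end=end,
                    biotype=biotype if biotype == "protein_coding" else "other",
                )
            )
    return genes


def write_gene_annotation(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t{g.biotype}\n")


@dataclass(frozen=True)
class GeneSet:
    """Genes selected for one sample/condition, with per-gene provenance.

    ``provenance`` maps each selected symbol to the (cytoband, direction)
    pairs that put it in the set; every member has at least one entry.
    """

    sample_id: str
    condition: str
    genes: frozenset[str]
    provenance: Mapping[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        missing = self.genes - set(self.provenance)
        if missing:
            raise ValueError(
                f"genes without provenance: {sorted(missing)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.genes)


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def build_gene_set(
    alterations: Sequence[CytobandAlteration],
    annotation: Sequence[GeneAnnotation],
    cytobands: CytobandMap,
    protein_coding_only: bool = True,
) -> GeneSet:
    """Union of genes overlapping any altered cytoband of one sample/condition.

    Gains and losses are pooled into a single set (one network per
    sample/condition downstream).  With ``protein_coding_only`` the result
    is restricted to protein-coding genes and is a subset of the unfiltered
    result.  Overlap is the any-overlap rule (>= 1 base).
    """
    keys = {(a.sample_id, a.condition) for a in alterations}
    if len(keys) > 1:
        raise ValueError(
            f"alterations span multiple (sample, condition) pairs: {sorted(keys)}"
        )
    if not alterations:
        warnings.warn("empty alteration list: returning an empty gene set",
                      stacklevel=2)
        return GeneSet(sample_id="", condition="pre", genes=frozenset(),
                       provenance={})
    (sample_id, condition), = keys

    provenance: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for alt in alterations:
        chrom, band_start, band_end = cytobands.interval(alt.cytoband)
        for gene in annotation:
            if gene.chrom != chrom:
                continue
            if protein_coding_only and gene.biotype != "protein_coding":
                continue
            if _overlap(gene.start, gene.end, band_start, band_end):
                provenance[gene.symbol].append((alt.cytoband, alt.direction))
    return GeneSet(
        sample_id=sample_id,
        condition=condition,
        genes=frozenset(provenance),
        provenance={g: tuple(v) for g, v in provenance.items()},
    )


def build_gene_set_from_segments(
    segments: Sequence[CNASegment],
    annotation: Sequence[GeneAnnotation],
    protein_coding_only: bool = True,
) -> GeneSet:
    """Segment-level variant: genes overlapping gain/loss segments directly.

    Provided as a configuration alternative to the default cytoband-level
    mapping; provenance records the segment interval in place of a band
    name.
    """
    calls = [s for s in segments if s.is_call]
    keys = {(s.sample_id, s.condition) for s in calls}
    if len(keys) > 1:
        raise ValueError(
            f"segments span multiple (sample, condition) pairs: {sorted(keys)}"
        )
    if not calls:
        warnings.warn("no gain/loss segments: returning an empty gene set",
                      stacklevel=2)
        return GeneSet(sample_id="", condition="pre", genes=frozenset(),
                       provenance={})
    (sample_id, condition), = keys

    provenance: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for seg in calls:
        label = f"{seg.chrom}:{seg.start + 1}-{seg.end}"
        for gene in annotation:
            if gene.chrom != seg.chrom:
                continue
            if protein_coding_only and gene.biotype != "protein_coding":
                continue
            if _overlap(gene.start, gene.end, seg.start, seg.end):
                provenance[gene.symbol].append((label, seg.direction))
    return GeneSet(
        sample_id=sample_id,
        condition=condition,
        genes=frozenset(provenance),
        provenance={g: tuple(v) for g, v in provenance.items()},
    )


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """Export a gene set as two-column TSV: symbol, provenance."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("symbol\tprovenance\n")
        for symbol in sorted(gene_set.genes):
            prov = ",".join(
                f"{band}:{direction}"
                for band, direction in gene_set.provenance[symbol]
            )
            fh.write(f"{symbol}\t{prov}\n")


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping external protein IDs to gene symbols."""
    path = Path(path)
    aliases: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            aliases[fields[0]] = fields[1]
    return aliases
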