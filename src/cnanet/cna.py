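"""Copy-number segment ingestion, gain/loss calling and cytoband mapping.

Segments arrive as aberration-interval tables (one row per interval with a
mean log2 tumor/reference ratio and a supporting probe count).  Calling uses
the aCGH convention of a minimum average absolute log2 ratio: gains above
+0.25, losses below -0.25, and intervals supported by 3 or fewer probes are
filtered out regardless of amplitude.  Altered intervals are then projected
onto cytobands, the unit at which recurrence across samples is assessed.

Internal coordinates are 0-based half-open; segment files on disk use
1-based inclusive coordinates (vendor-report convention).  Conversion
happens only at the parse/write boundary.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CONDITIONS",
    "DIRECTIONS",
    "CNASegment",
    "CytobandAlteration",
    "CytobandMap",
    "RecurrentCytoband",
    "SegmentFormatError",
    "parse_segments",
    "classify_cna",
    "classify_all",
    "count_calls",
    "load_cytobands",
    "segments_to_cytobands",
    "recurrent_cytobands",
]

CONDITIONS = ("pre", "post")
DIRECTIONS = ("gain", "loss", "neutral", "filtered")

#: default calling thresholds (Agilent CytoGenomics convention)
GAIN_THRESHOLD = 0.25
LOSS_THRESHOLD = -0.25
MIN_PROBES = 3

SEGMENT_COLUMNS = ("chrom", "start", "end", "mean_log2", "probes")


class SegmentFormatError(ValueError):
    """A segment table violates the expected layout (bad header or row)."""


@dataclass(frozen=True)
class CNASegment:
    """One aberration interval from a single sample/condition.

    ``start``/``end`` are 0-based half-open.  ``direction`` is ``neutral``
    until :func:`classify_cna` is applied.
    """

    sample_id: str
    condition: str
    chrom: str
    start: int
    end: int
    mean_log2: float
    probe_count: int
    direction: str = "neutral"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.probe_count < 1:
            raise ValueError(f"probe_count must be >= 1, got {self.probe_count}")

    @property
    def is_call(self) -> bool:
        """True for a significant alteration (gain or loss)."""
        return self.direction in ("gain", "loss")


def parse_segments(path: str | Path, sample_id: str, condition: str) -> list[CNASegment]:
    """Read a tab-separated segment table into unclassified segments.

    The file must carry a header with the columns ``chrom``, ``start``,
    ``end``, ``mean_log2`` and ``probes``; coordinates in the file are
    1-based inclusive and are converted to 0-based half-open here.  Rows are
    returned in file order with ``direction='neutral'`` pending
    classification.

    Raises
    ------
    SegmentFormatError
        If a required column is missing, or a row has a non-numeric field or
        inverted coordinates (the message names the offending line number).
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise SegmentFormatError(f"{path}: empty file, expected a header")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in SEGMENT_COLUMNS if c not in header]
        if missing:
            raise SegmentFormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in SEGMENT_COLUMNS}

        segments: list[CNASegment] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise SegmentFormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[idx["chrom"]]
            try:
                start_1b = int(fields[idx["start"]])
                end_1b = int(fields[idx["end"]])
            except ValueError:
                raise SegmentFormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            try:
                mean_log2 = float(fields[idx["mean_log2"]])
            except ValueError:
                raise SegmentFormatError(
                    f"{path}: line {lineno}: non-numeric mean_log2 "
                    f"{fields[idx['mean_log2']]!r}"
                ) from None
            try:
                probes = int(fields[idx["probes"]])
            except ValueError:
                raise SegmentFormatError(
                    f"{path}: line {lineno}: non-numeric probes "
                    f"{fields[idx['probes']]!r}"
                ) from None
            if start_1b > end_1b:
                raise SegmentFormatError(
                    f"{path}: line {lineno}: start {start_1b} > end {end_1b}"
                )
            # 1-based inclusive [start, end] -> 0-based half-open [start-1, end)
            segments.append(
                CNASegment(
                    sample_id=sample_id,
                    condition=condition,
                    chrom=chrom,
                    start=start_1b - 1,
                    end=end_1b,
                    mean_log2=mean_log2,
                    probe_count=probes,
                )
            )
    return segments


def write_segments(segments: Iterable[CNASegment], path: str | Path) -> None:
    """Write segments as a 1-based inclusive TSV (inverse of parse_segments)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for seg in segments:
            fh.write(
                f"{seg.chrom}\t{seg.start + 1}\t{seg.end}\t"
                f"{seg.mean_log2:.4f}\t{seg.probe_count}\n"
            )


def classify_cna(
    segment: CNASegment,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_probes: int = MIN_PROBES,
) -> CNASegment:
    """Assign a gain/loss/neutral/filtered direction to one segment.

    The probe filter is strict: a segment must be supported by *more than*
    ``min_probes`` probes to be eligible at all.  Amplitude comparisons are
    strict as well, so a segment sitting exactly on a threshold is neutral.
    Classification is a pure function of (mean_log2, probe_count,
    thresholds) and is idempotent.
    """
    if not loss_threshold < 0 < gain_threshold:
        raise ValueError(
            "thresholds must satisfy loss_threshold < 0 < gain_threshold, "
            f"got loss={loss_threshold}, gain={gain_threshold}"
        )
    if segment.probe_count <= min_probes:
        direction = "filtered"
    elif segment.mean_log2 > gain_threshold:
        direction = "gain"
    elif segment.mean_log2 < loss_threshold:
        direction = "loss"
    else:
        direction = "neutral"
    return replace(segment, direction=direction)


def classify_all(
    segments: Iterable[CNASegment],
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_probes: int = MIN_PROBES,
) -> list[CNASegment]:
    """Classify every segment in a list (see :func:`classify_cna`)."""
    return [
        classify_cna(s, gain_threshold, loss_threshold, min_probes)
        for s in segments
    ]


def count_calls(segments: Iterable[CNASegment]) -> dict[tuple[str, str], int]:
    """Count significant alterations ("calls") per (sample, condition).

    A call is a segment classified as gain or loss; neutral and filtered
    segments never count.  The result is keyed independently per
    (sample_id, condition) pair and is invariant under segment order.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for seg in segments:
        if seg.is_call:
            counts[(seg.sample_id, seg.condition)] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# cytoband projection


@dataclass(frozen=True)
class CytobandMap:
    """Cytoband intervals per chromosome (0-based half-open, non-overlapping)."""

    bands: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, name)

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for chrom, start, end, name in self.bands:
            if not start < end:
                raise ValueError(f"cytoband {name}: start {start} >= end {end}")
            by_chrom[chrom].append((start, end, name))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1, n1), (s2, e2, n2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"cytobands {n1} and {n2} overlap on {chrom}"
                    )

    @property
    def chroms(self) -> set[str]:
        return {chrom for chrom, _, _, _ in self.bands}

    def interval(self, name: str) -> tuple[str, int, int]:
        for chrom, start, end, band in self.bands:
            if band == name:
                return chrom, start, end
        raise KeyError(f"unknown cytoband {name!r}")

    def overlapping(self, chrom: str, start: int, end: int) -> list[str]:
        """Names of bands overlapping [start, end) by at least one base."""
        return [
            name
            for c, s, e, name in self.bands
            if c == chrom and start < e and s < end
        ]


def load_cytobands(path: str | Path) -> CytobandMap:
    """Load a BED-like cytoband TSV: chrom, start, end, name (0-based half-open)."""
    path = Path(path)
    bands = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from None
            bands.append((fields[0], start, end, fields[3]))
    return CytobandMap(bands=tuple(bands))


@dataclass(frozen=True)
class CytobandAlteration:
    """One altered cytoband for one sample/condition/direction.

    There is one record per (cytoband, sample, condition, direction); when a
    sample carries both a gain and a loss overlapping the same band, two
    records with opposite directions exist and downstream reports flag the
    band as discordant.
    """

    cytoband: str
    sample_id: str
    condition: str
    direction: str
    supporting_segments: tuple[CNASegment, ...]

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(
                f"alteration direction must be gain or loss, got {self.direction!r}"
            )
        if not self.supporting_segments:
            raise ValueError("alteration must have at least one supporting segment")


def segments_to_cytobands(
    segments: Iterable[CNASegment], cytobands: CytobandMap
) -> list[CytobandAlteration]:
    """Project gain/loss segments onto cytobands (any-overlap rule).

    A cytoband is altered for a sample/condition/direction iff at least one
    segment with that direction overlaps it by >= 1 base.  Neutral and
    filtered segments never contribute.  Segments on a chromosome absent
    from the cytoband map are skipped with a warning.
    """
    grouped: dict[tuple[str, str, str, str], list[CNASegment]] = defaultdict(list)
    skipped: list[CNASegment] = []
    known_chroms = cytobands.chroms
    for seg in segments:
        if not seg.is_call:
            continue
        if seg.chrom not in known_chroms:
            skipped.append(seg)
            continue
        for band in cytobands.overlapping(seg.chrom, seg.start, seg.end):
            grouped[(band, seg.sample_id, seg.condition, seg.direction)].append(seg)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} segment(s) on chromosomes absent from the "
            f"cytoband map: {sorted({s.chrom for s in skipped})}",
            stacklevel=2,
        )
    return [
        CytobandAlteration(
            cytoband=band,
            sample_id=sample,
            condition=condition,
            direction=direction,
            supporting_segments=tuple(segs),
        )
        for (band, sample, condition, direction), segs in sorted(grouped.items())
    ]


@dataclass(frozen=True)
class RecurrentCytoband:
    """A cytoband altered in >= min_samples distinct samples of one condition.

    ``concordant`` is False when the direction differs across samples (the
    band is retained and flagged, not excluded).
    """

    cytoband: str
    condition: str
    samples: tuple[str, ...]
    directions: Mapping[str, tuple[str, ...]]  # sample -> directions seen
    concordant: bool
    alterations: tuple[CytobandAlteration, ...]


def recurrent_cytobands(
    alterations: Sequence[CytobandAlteration], min_samples: int = 2
) -> list[RecurrentCytoband]:
    """Select cytobands altered (either direction) in >= min_samples samples.

    Grouping is per (cytoband, condition); direction concordance across
    samples is annotated, never required.  With ``min_samples=1`` every
    altered cytoband is returned.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    grouped: dict[tuple[str, str], list[CytobandAlteration]] = defaultdict(list)
    for alt in alterations:
        grouped[(alt.cytoband, alt.condition)].append(alt)
    out = []
    for (band, condition), alts in sorted(grouped.items()):
        samples = sorted({a.sample_id for a in alts})
        if len(samples) < min_samples:
            continue
        directions: dict[str, tuple[str, ...]] = {}
        for sample in samples:
            directions[sample] = tuple(
                sorted({a.direction for a in alts if a.sample_id == sample})
            )
        all_dirs = {a.direction for a in alts}
        out.append(
            RecurrentCytoband(
                cytoband=band,
                condition=condition,
                samples=tuple(samples),
                directions=directions,
                concordant=len(all_dirs) == 1,
                alterations=tuple(alts),
            )
        )
    return out
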