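"""Source-element catalog, transduced regions, and genomic binning.

A small set of full-length LINE-1 (L1) loci remains retrotransposition
competent in the human genome.  When such an element fires, transcription
occasionally reads through its own poly(A) signal and mobilizes the unique
genomic sequence immediately 3' of the element (an "orphan" 3' transduction).
Because that downstream sequence is unique, it acts as a barcode identifying
the donor element of every new insertion.

This module loads the catalog of active source elements, derives the
orientation-aware 5 kb downstream window of each one (the transduced region,
which doubles as the capture target of the assay), models assembly gaps, and
builds the genomic bin / interval index used both by the caller (to assign
read partners to transduced regions) and by the simulator (to place
insertions in 10 kb bins).

Coordinates are 0-based half-open throughout, matching BED/BAM conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")

#: default length of the downstream window captured by the assay (bp)
DEFAULT_WINDOW_BP = 5000

#: default bin size used to place simulated insertions (bp)
DEFAULT_BIN_BP = 10_000


class CatalogError(ValueError):
    """Malformed or inconsistent source-element catalog."""


@dataclass(frozen=True)
class SourceElement:
    """One retrotransposition-competent L1 locus.

    ``element_id`` is conventionally a cytoband-style label (e.g. "22q12.1")
    but any unique string is accepted.
    """

    element_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CatalogError(
                f"element {self.element_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise CatalogError(
                f"element {self.element_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class TransducedRegion:
    """The downstream window 3' of a source element, in reference coordinates.

    The region lies to the right of a '+' element and to the left of a '-'
    element, clipped at chromosome boundaries.  ``orientation`` is inherited
    from the parent element and gives the transcript sense of the window.
    ``overlaps_element`` flags windows that run into the body of another
    cataloged element (permitted, but recorded for downstream filters).
    """

    element_id: str
    chrom: str
    start: int
    end: int
    orientation: str
    window_bp: int = DEFAULT_WINDOW_BP
    overlaps_element: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


class GapTrack:
    """Assembly-gap intervals; positions inside a gap are not usable."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                continue
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in self._trees.values():
            tree.merge_overlaps()

    @classmethod
    def from_bed(cls, path: str) -> "GapTrack":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                ivs.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(ivs)

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str], min_run: int = 10) -> "GapTrack":
        """Infer gaps as runs of >= ``min_run`` N characters."""
        ivs = []
        for chrom, seq in seqs.items():
            i, n = 0, len(seq)
            up = seq.upper()
            while i < n:
                if up[i] == "N":
                    j = i
                    while j < n and up[j] == "N":
                        j += 1
                    if j - i >= min_run:
                        ivs.append((chrom, i, j))
                    i = j
                else:
                    i += 1
        return cls(ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, tree in self._trees.items():
            for iv in sorted(tree):
                out.append((chrom, iv.begin, iv.end))
        return sorted(out)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


@dataclass
class BinIndex:
    """Fixed-width genomic bins plus an interval index over transduced regions.

    ``bin_of`` maps every position to exactly one bin (floor division);
    ``query``/``overlapping`` answer which transduced regions (if any) contain
    a position or intersect an interval, in O(log n).
    """

    bin_size_bp: int
    chrom_lengths: Mapping[str, int]
    regions: Sequence[TransducedRegion] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        self._trees: dict[str, IntervalTree] = {}
        for reg in self.regions:
            if reg.end > reg.start:
                self._trees.setdefault(reg.chrom, IntervalTree()).addi(
                    reg.start, reg.end, reg
                )

    @property
    def target_regions(self) -> tuple[TransducedRegion, ...]:
        return tuple(self.regions)

    def bin_of(self, chrom: str, pos: int) -> int:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return pos // self.bin_size_bp

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.bin_size_bp)

    def query(self, chrom: str, pos: int) -> list[TransducedRegion]:
        """Transduced regions containing ``pos`` (stabbing query)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        return sorted(hits, key=lambda r: (r.start, r.element_id))

    def overlapping(self, chrom: str, start: int, end: int) -> list[TransducedRegion]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda r: (r.start, r.element_id))


def load_source_catalog(path: str) -> list[SourceElement]:
    """Read a BED6 source-element catalog.

    Columns: chrom, start, end, element_id, score (ignored), strand.
    Duplicate ids, start >= end, and strands outside {+,-} are rejected with
    the offending line number.
    """
    elements: list[SourceElement] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise CatalogError(
                    f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CatalogError(f"{path}:{lineno}: non-integer coordinates") from exc
            if name in seen:
                raise CatalogError(f"{path}:{lineno}: duplicate element id {name!r}")
            seen.add(name)
            try:
                elements.append(SourceElement(name, chrom, start, end, strand))
            except CatalogError as exc:
                raise CatalogError(f"{path}:{lineno}: {exc}") from exc
    if not elements:
        log.warning("catalog %s is empty", path)
    return elements


def chrom_lengths_of(reference) -> dict[str, int]:
    """Chromosome lengths from a mapping of sequences or a pyfaidx.Fasta."""
    if isinstance(reference, Mapping):
        return {c: len(s) for c, s in reference.items()}
    return {name: len(reference[name]) for name in reference.keys()}


def derive_transduced_regions(
    catalog: Sequence[SourceElement],
    reference_index: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[TransducedRegion]:
    """Derive the 3' downstream window of each element, honoring orientation.

    '+' element (s, e) -> region (e, e + window); '-' element -> (s - window,
    s); both clipped to [0, chromosome length].  Windows overlapping the body
    of another cataloged element are flagged, not dropped.
    """
    regions: list[TransducedRegion] = []
    for el in catalog:
        if el.chrom not in reference_index:
            raise CatalogError(
                f"element {el.element_id}: chromosome {el.chrom!r} absent from reference"
            )
        chrom_len = reference_index[el.chrom]
        if el.strand == "+":
            start, end = el.end, min(el.end + window_bp, chrom_len)
        else:
            start, end = max(el.start - window_bp, 0), el.start
        regions.append(
            TransducedRegion(el.element_id, el.chrom, start, end, el.strand, window_bp)
        )
    # flag windows running into another element's body
    flagged = []
    for reg in regions:
        hit = any(
            el.chrom == reg.chrom
            and el.element_id != reg.element_id
            and el.start < reg.end
            and reg.start < el.end
            for el in catalog
        )
        flagged.append(replace(reg, overlaps_element=hit) if hit else reg)
    return flagged


def build_bin_index(
    regions: Sequence[TransducedRegion],
    reference_index: Mapping[str, int],
    bin_size_bp: int = DEFAULT_BIN_BP,
) -> BinIndex:
    """Build the bin/interval index over the given transduced regions."""
    return BinIndex(bin_size_bp, dict(reference_index), tuple(regions))
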