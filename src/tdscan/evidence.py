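"""Evidence extraction: discordant pairs and clipped reads from alignments.

Two read-level signals link a candidate insertion locus to a donor element's
transduced region:

* a discordant read pair whose anchor maps at the insertion locus while its
  mate maps inside a transduced region (the mobilized barcode sequence), and
* a soft-clipped read whose clipped extreme realigns inside a transduced
  region, pinning the insertion breakpoint to base precision.

``scan_alignments`` walks a coordinate-sorted BAM/SAM once and emits one
``EvidenceRead`` per qualifying signal; ``realign_clipped`` then searches each
clipped sequence against all transduced-region sequences (both strands) and
records the best supplementary hit, if any clears the identity threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import pysam

from ._seq import fetch_seq, revcomp
from .catalog import TransducedRegion

log = logging.getLogger(__name__)

DISCORDANT_ANCHOR = "DISCORDANT_ANCHOR"
CLIP_LEFT = "CLIP_LEFT"
CLIP_RIGHT = "CLIP_RIGHT"


@dataclass
class ScanParams:
    """Thresholds for the alignment scan.

    ``max_insert`` defines pair concordance (|template| above it is
    discordant even for a properly oriented same-chromosome pair); the
    default of 1000 bp is about 3x a typical 350 bp capture insert.
    ``min_clip_len`` = 20 bp keeps clip matches unique within the ~620 kb
    target space.  When ``include_duplicates`` is false (default), reads
    flagged as PCR/optical duplicates are still emitted but carry
    ``is_duplicate=True`` and are excluded from cluster support downstream.
    """

    min_clip_len: int = 20
    min_mapq: int = 0
    max_insert: int = 1000
    include_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.min_clip_len < 1:
            raise ValueError("min_clip_len must be >= 1")
        if self.max_insert <= 0:
            raise ValueError("max_insert must be positive")


@dataclass
class EvidenceRead:
    """One discordant-pair anchor or one clipped read end."""

    read_id: str
    kind: str  # DISCORDANT_ANCHOR | CLIP_LEFT | CLIP_RIGHT
    anchor_chrom: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str
    anchor_mapq: int
    is_duplicate: bool = False
    # discordant-pair fields
    mate_chrom: str | None = None
    mate_pos: int | None = None
    mate_strand: str | None = None
    # clip fields
    clip_pos: int | None = None
    clipped_seq: str | None = None
    # supplementary alignment of the clipped sequence (after realignment)
    supp_element: str | None = None
    supp_chrom: str | None = None
    supp_pos: int | None = None
    supp_strand: str | None = None
    supp_score: int | None = None

    @property
    def anchor_pos(self) -> int:
        """Single representative anchor coordinate used for clustering."""
        return self.anchor_start


def _check_sorted(af: pysam.AlignmentFile) -> None:
    so = af.header.to_dict().get("HD", {}).get("SO")
    if so != "coordinate":
        raise ValueError(
            "alignment file must be coordinate-sorted (samtools sort) and, for "
            f"BAM, indexed; header SO={so!r}"
        )


def scan_alignments(alignments, params: ScanParams | None = None) -> list[EvidenceRead]:
    """Extract discordant anchors and clipped reads from a BAM/SAM file.

    A pair is discordant when it is not flagged properly paired, is
    interchromosomal, or has |template length| > ``max_insert``.  Soft clips
    of >= ``min_clip_len`` bp at either alignment end become CLIP_LEFT /
    CLIP_RIGHT evidence carrying the clipped sequence.  Hard clips are
    skipped (their sequence is not recoverable from the primary record).
    Secondary and supplementary alignments are ignored.  The result is
    sorted, so it is invariant to the input record order.
    """
    params = params or ScanParams()
    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    try:
        _check_sorted(af)
        out: list[EvidenceRead] = []
        for r in af.fetch(until_eof=True):
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            if not r.is_paired:
                raise ValueError(
                    f"read {r.query_name} is single-end; paired-end data required"
                )
            if r.mapping_quality < params.min_mapq:
                continue
            dup = bool(r.is_duplicate) and not params.include_duplicates
            suffix = "/1" if r.is_read1 else "/2"
            rid = r.query_name + suffix
            strand = "-" if r.is_reverse else "+"
            base = dict(
                anchor_chrom=r.reference_name,
                anchor_start=r.reference_start,
                anchor_end=r.reference_end,
                anchor_strand=strand,
                anchor_mapq=r.mapping_quality,
                is_duplicate=dup,
            )
            if not r.mate_is_unmapped:
                discordant = (
                    not r.is_proper_pair
                    or r.reference_id != r.next_reference_id
                    or abs(r.template_length) > params.max_insert
                )
                if discordant:
                    out.append(
                        EvidenceRead(
                            rid,
                            DISCORDANT_ANCHOR,
                            mate_chrom=r.next_reference_name,
                            mate_pos=r.next_reference_start,
                            mate_strand="-" if r.mate_is_reverse else "+",
                            **base,
                        )
                    )
            cig = r.cigartuples or []
            seq = r.query_sequence or ""
            if cig and seq:
                if cig[0][0] == 4 and cig[0][1] >= params.min_clip_len:
                    out.append(
                        EvidenceRead(
                            rid,
                            CLIP_LEFT,
                            clip_pos=r.reference_start,
                            clipped_seq=seq[: cig[0][1]],
                            **base,
                        )
                    )
                if cig[-1][0] == 4 and cig[-1][1] >= params.min_clip_len:
                    out.append(
                        EvidenceRead(
                            rid,
                            CLIP_RIGHT,
                            clip_pos=r.reference_end,
                            clipped_seq=seq[-cig[-1][1] :],
                            **base,
                        )
                    )
        out.sort(key=lambda e: (e.anchor_chrom, e.anchor_start, e.read_id, e.kind))
        return out
    finally:
        if own:
            af.close()


def extract_region_sequences(
    reference, regions: Sequence[TransducedRegion]
) -> dict[str, str]:
    """Uppercase reference sequence of every transduced region, keyed by
    element id.  Orientation is NOT applied; the aligner handles strand."""
    return {
        reg.element_id: fetch_seq(reference, reg.chrom, reg.start, reg.end)
        for reg in regions
    }


def realign_clipped(
    clips: Sequence[EvidenceRead],
    region_seqs: Mapping[str, str],
    regions: Sequence[TransducedRegion],
    max_edit_frac: float = 0.1,
) -> list[EvidenceRead]:
    """Realign clipped sequences against all transduced regions (both strands).

    Infix (glocal) alignment; a hit is accepted when its edit distance is at
    most ``max_edit_frac`` x clip length, i.e. >= 90 % identity by default.
    The best hit (lowest edit distance, ties broken by lowest (chrom, pos))
    populates the supp_* fields in place; a clip with no qualifying hit keeps
    them empty.  Returns the same list for convenience.
    """
    by_pos = sorted(
        (r for r in regions if r.element_id in region_seqs),
        key=lambda r: (r.chrom, r.start),
    )
    for ev in clips:
        if ev.clipped_seq is None:
            continue
        query = ev.clipped_seq.upper()
        k = int(max_edit_frac * len(query))
        best: tuple | None = None  # (dist, chrom, pos, strand, element, score)
        for reg in by_pos:
            target = region_seqs[reg.element_id]
            for strand, q in (("+", query), ("-", revcomp(query))):
                res = edlib.align(q, target, mode="HW", task="locations", k=k)
                dist = res["editDistance"]
                if dist < 0:
                    continue
                loc = res["locations"][0]
                pos = reg.start + (loc[0] or 0)
                cand = (dist, reg.chrom, pos, strand, reg.element_id)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is not None:
            dist, chrom, pos, strand, element = best
            ev.supp_element = element
            ev.supp_chrom = chrom
            ev.supp_pos = pos
            ev.supp_strand = strand
            ev.supp_score = len(query) - 2 * dist
    return list(clips)
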