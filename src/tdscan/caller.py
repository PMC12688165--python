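"""Cluster evidence into somatic L1-insertion calls.

Pipeline: evidence reads are grouped into clusters (separately per evidence
kind and anchor strand, keyed by the donor transduced region their partner
coordinate falls in), a cascade of annotating filters is applied, PASS
clusters at the same locus with the same donor element are merged into
breakpointed metaclusters, and each metacluster is typed (orphan TD2 vs
partnered TD1) and strand-classified (PLUS / MINUS / RECIPROCAL).  In
matched mode, calls with germline evidence support are demoted from SOMATIC.

Filters annotate rather than delete (VCF FILTER semantics): a "discarded"
cluster simply carries a non-empty flag set and is excluded from PASS
output, so benchmarking can audit every decision.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from ._seq import fetch_seq, revcomp
from .catalog import BinIndex, SourceElement, TransducedRegion
from .evidence import (
    CLIP_LEFT,
    CLIP_RIGHT,
    DISCORDANT_ANCHOR,
    EvidenceRead,
    ScanParams,
    extract_region_sequences,
    realign_clipped,
    scan_alignments,
)

log = logging.getLogger(__name__)

DISCORDANT = "DISCORDANT"
CLIPPED = "CLIPPED"

PLUS, MINUS, RECIPROCAL = "PLUS", "MINUS", "RECIPROCAL"
TD1, TD2, AMBIGUOUS = "TD1", "TD2", "AMBIGUOUS"
SOMATIC, GERMLINE_SUPPORTED = "SOMATIC", "GERMLINE_SUPPORTED"

# filter flag labels
LOW_SUPPORT = "LOW_SUPPORT"
BLACKLIST = "BLACKLIST"
DUPLICATES = "DUPLICATES"
LOW_MAPQ = "LOW_MAPQ"
OFF_TARGET_PARTNER = "OFF_TARGET_PARTNER"
ANCHOR_IN_DONOR_REGION = "ANCHOR_IN_DONOR_REGION"


@dataclass
class CallerParams:
    """Clustering and filtering thresholds.

    ``min_support`` defaults to 3 non-duplicate reads per cluster, echoing
    the validation standard of at least three supporting reads for a true
    somatic retrotransposition.  ``cluster_gap_bp`` is on the order of the
    sequencing insert size; ``meta_merge_bp`` joins clusters flanking the
    same breakpoint (e.g. the two sides of a target-site duplication).
    """

    min_support: int = 3
    cluster_gap_bp: int = 500
    meta_merge_bp: int = 150
    min_mean_mapq: float = 20.0
    max_dup_fraction: float = 0.5
    read_len: int = 150
    blacklist: Sequence[tuple[str, int, int]] = ()

    def __post_init__(self) -> None:
        for name in ("min_support", "cluster_gap_bp", "meta_merge_bp", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReadCluster:
    cluster_kind: str  # DISCORDANT | CLIPPED
    anchor_chrom: str
    anchor_start: int
    anchor_end: int
    anchor_strand: str
    partner_element_id: str | None
    partner_lo: int | None
    partner_hi: int | None
    support: int  # non-duplicate supporting reads
    n_duplicates: int
    mean_mapq: float
    members: list[EvidenceRead] = field(default_factory=list)
    filter_flags: set[str] = field(default_factory=set)

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags


@dataclass
class MetaCluster:
    chrom: str
    bp_low: int
    bp_high: int
    element_id: str
    strand_class: str
    td_type: str
    n_discordant: int
    n_clipped: int
    member_clusters: list[ReadCluster] = field(default_factory=list)


@dataclass
class InsertionCall(MetaCluster):
    sample_id: str = "sample"
    somatic_status: str = SOMATIC
    vaf_estimate: float | None = None


def _partner_of(ev: EvidenceRead, bins: BinIndex) -> tuple[str | None, int | None]:
    """Donor region (element id) and coordinate implied by an evidence read."""
    if ev.kind == DISCORDANT_ANCHOR:
        if ev.mate_chrom is None:
            return None, None
        hits = bins.query(ev.mate_chrom, ev.mate_pos)
        return (hits[0].element_id, ev.mate_pos) if hits else (None, ev.mate_pos)
    if ev.supp_pos is None:
        return None, None
    hits = bins.query(ev.supp_chrom, ev.supp_pos)
    return (hits[0].element_id, ev.supp_pos) if hits else (None, ev.supp_pos)


def cluster_evidence(
    evidence: Sequence[EvidenceRead],
    bins: BinIndex,
    params: CallerParams | None = None,
) -> list[ReadCluster]:
    """Single-linkage clustering of anchors along the genome.

    Evidence is split into streams by (kind group, anchor strand, partner
    element); within a stream, anchors sorted by position chain into one
    cluster while consecutive gaps stay <= ``cluster_gap_bp``.  This equals
    the transitive closure of the pairwise same-cluster predicate.  Clips
    without a supplementary hit, and discordant anchors whose mates fall
    outside every transduced region, keep ``partner_element_id=None`` and are
    flagged (not silently dropped) during filtering.
    """
    params = params or CallerParams()
    streams: dict[tuple, list[tuple[int, int | None, EvidenceRead]]] = {}
    for ev in evidence:
        group = DISCORDANT if ev.kind == DISCORDANT_ANCHOR else CLIPPED
        element, ppos = _partner_of(ev, bins)
        key = (ev.anchor_chrom, group, ev.anchor_strand, element)
        streams.setdefault(key, []).append((ev.anchor_pos, ppos, ev))

    clusters: list[ReadCluster] = []
    for (chrom, group, strand, element), items in sorted(
        streams.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], str(kv[0][3]))
    ):
        items.sort(key=lambda t: (t[0], t[2].read_id))
        run: list[tuple[int, int | None, EvidenceRead]] = []
        for item in items:
            if run and item[0] - run[-1][0] > params.cluster_gap_bp:
                clusters.append(_make_cluster(chrom, group, strand, element, run))
                run = []
            run.append(item)
        if run:
            clusters.append(_make_cluster(chrom, group, strand, element, run))
    clusters.sort(key=lambda c: (c.anchor_chrom, c.anchor_start, c.cluster_kind))
    return clusters


def _make_cluster(chrom, group, strand, element, items) -> ReadCluster:
    evs = [ev for _, _, ev in items]
    ppos = [p for _, p, _ in items if p is not None]
    n_dup = sum(e.is_duplicate for e in evs)
    return ReadCluster(
        cluster_kind=group,
        anchor_chrom=chrom,
        anchor_start=min(e.anchor_start for e in evs),
        anchor_end=max(e.anchor_end for e in evs),
        anchor_strand=strand,
        partner_element_id=element,
        partner_lo=min(ppos) if ppos else None,
        partner_hi=max(ppos) + 1 if ppos else None,
        support=len(evs) - n_dup,
        n_duplicates=n_dup,
        mean_mapq=sum(e.anchor_mapq for e in evs) / len(evs),
        members=evs,
    )


def filter_clusters(
    clusters: Iterable[ReadCluster],
    params: CallerParams,
    region_index: BinIndex,
) -> list[ReadCluster]:
    """Assign filter flags; PASS clusters end up with an empty flag set.

    Flags: LOW_SUPPORT, BLACKLIST, DUPLICATES (duplicate fraction above
    ``max_dup_fraction``), LOW_MAPQ, OFF_TARGET_PARTNER (mate/supplementary
    outside every transduced region), ANCHOR_IN_DONOR_REGION (the anchor span
    itself lies in a transduced region: donor-locus self-signal and
    source-to-source events).
    """
    bl_by_chrom: dict[str, IntervalTree] = {}
    for chrom, start, end in params.blacklist:
        bl_by_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
    out = []
    for cl in clusters:
        flags = set()
        if cl.support < params.min_support:
            flags.add(LOW_SUPPORT)
        total = cl.support + cl.n_duplicates
        if total and cl.n_duplicates / total > params.max_dup_fraction:
            flags.add(DUPLICATES)
        if cl.mean_mapq < params.min_mean_mapq:
            flags.add(LOW_MAPQ)
        tree = bl_by_chrom.get(cl.anchor_chrom)
        if tree is not None and tree.overlap(cl.anchor_start, max(cl.anchor_end, cl.anchor_start + 1)):
            flags.add(BLACKLIST)
        if cl.partner_element_id is None:
            flags.add(OFF_TARGET_PARTNER)
        if region_index.overlapping(
            cl.anchor_chrom, cl.anchor_start, max(cl.anchor_end, cl.anchor_start + 1)
        ):
            flags.add(ANCHOR_IN_DONOR_REGION)
        cl.filter_flags = flags
        out.append(cl)
    return out


def build_metaclusters(
    pass_clusters: Sequence[ReadCluster], params: CallerParams | None = None
) -> list[MetaCluster]:
    """Merge PASS clusters of the same locus and donor element.

    Clusters on one chromosome with the same partner element whose anchor
    spans lie within ``meta_merge_bp`` of each other merge into one
    metacluster.  Breakpoints: the modal clip position when clip evidence
    exists (ties -> leftmost); otherwise the inner edges of the '+' and '-'
    discordant clusters; with only one discordant side, the anchor span edge
    extended by one read length.
    """
    params = params or CallerParams()
    groups: dict[tuple[str, str], list[ReadCluster]] = {}
    for cl in pass_clusters:
        if cl.partner_element_id is None:
            continue
        groups.setdefault((cl.anchor_chrom, cl.partner_element_id), []).append(cl)

    metas: list[MetaCluster] = []
    for (chrom, element), cls in sorted(groups.items()):
        cls.sort(key=lambda c: (c.anchor_start, c.anchor_end))
        bundle: list[ReadCluster] = []
        bundle_end = None
        for cl in cls:
            if bundle and cl.anchor_start - bundle_end > params.meta_merge_bp:
                metas.append(_finalize_meta(chrom, element, bundle, params))
                bundle = []
                bundle_end = None
            bundle.append(cl)
            bundle_end = cl.anchor_end if bundle_end is None else max(bundle_end, cl.anchor_end)
        if bundle:
            metas.append(_finalize_meta(chrom, element, bundle, params))
    metas.sort(key=lambda m: (m.chrom, m.bp_low, m.element_id))
    return metas


def _finalize_meta(
    chrom: str, element: str, members: list[ReadCluster], params: CallerParams
) -> MetaCluster:
    clip_positions = [
        ev.clip_pos
        for cl in members
        if cl.cluster_kind == CLIPPED
        for ev in cl.members
        if ev.clip_pos is not None and not ev.is_duplicate
    ]
    if clip_positions:
        counts = Counter(clip_positions)
        top = max(counts.values())
        bp = min(p for p, c in counts.items() if c == top)
        bp_low = bp_high = bp
    else:
        plus = [c for c in members if c.cluster_kind == DISCORDANT and c.anchor_strand == "+"]
        minus = [c for c in members if c.cluster_kind == DISCORDANT and c.anchor_strand == "-"]
        if plus and minus:
            lo = max(c.anchor_end for c in plus)
            hi = min(c.anchor_start for c in minus)
            bp_low, bp_high = min(lo, hi), max(lo, hi)
        elif plus:
            lo = max(c.anchor_end for c in plus)
            bp_low, bp_high = lo, lo + params.read_len
        else:
            hi = min(c.anchor_start for c in minus)
            bp_low, bp_high = max(hi - params.read_len, 0), hi
    meta = MetaCluster(
        chrom=chrom,
        bp_low=bp_low,
        bp_high=bp_high,
        element_id=element,
        strand_class="",
        td_type="",
        n_discordant=sum(c.support for c in members if c.cluster_kind == DISCORDANT),
        n_clipped=sum(c.support for c in members if c.cluster_kind == CLIPPED),
        member_clusters=list(members),
    )
    meta.strand_class = classify_strand(meta)
    return meta


def classify_strand(meta: MetaCluster) -> str:
    """PLUS if every supporting anchor maps to '+', MINUS if all '-',
    RECIPROCAL when both strands support the insertion."""
    strands = {c.anchor_strand for c in meta.member_clusters}
    if strands == {"+"}:
        return PLUS
    if strands == {"-"}:
        return MINUS
    return RECIPROCAL


def extract_element_termini(
    reference, catalog: Sequence[SourceElement], k: int = 100
) -> dict[str, str]:
    """Oriented 3'-terminal sequence of each element body (last ``k`` bp in
    transcript sense), used to recognize partnered (TD1) transductions."""
    out = {}
    for el in catalog:
        if el.strand == "+":
            seq = fetch_seq(reference, el.chrom, max(el.end - k, el.start), el.end)
        else:
            seq = revcomp(fetch_seq(reference, el.chrom, el.start, min(el.start + k, el.end)))
        out[el.element_id] = seq
    return out


def _shares_kmer(a: str, b: str, k: int = 15) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def determine_td_type(
    meta: MetaCluster, element_termini: Mapping[str, str] | None = None
) -> str:
    """Type a metacluster as orphan (TD2) or partnered (TD1) transduction.

    TD2: discordant mates fall strictly inside the donor's downstream region
    and no clipped sequence carries the element's 3' terminus.  TD1: some
    clipped sequence contains the element 3'-junction sequence (the L1 body
    itself travelled with the transduction).  With no discordant members and
    no junction match the evidence is AMBIGUOUS.
    """
    term = (element_termini or {}).get(meta.element_id)
    if term:
        for cl in meta.member_clusters:
            for ev in cl.members:
                if ev.clipped_seq and (
                    _shares_kmer(ev.clipped_seq.upper(), term)
                    or _shares_kmer(revcomp(ev.clipped_seq.upper()), term)
                ):
                    return TD1
    if meta.n_discordant >= 1:
        return TD2
    return AMBIGUOUS


def subtract_germline(
    calls: Sequence[InsertionCall],
    germline_evidence: Sequence[EvidenceRead],
    bins: BinIndex,
    window: int = 150,
) -> list[InsertionCall]:
    """Matched-mode somatic status.

    A call is GERMLINE_SUPPORTED when at least one germline evidence read
    shares its donor element and anchors within ``window`` bp of the
    breakpoint interval; otherwise SOMATIC (no supporting reads in the
    matched normal).
    """
    per_element: dict[tuple[str, str], list[int]] = {}
    for ev in germline_evidence:
        element, _ = _partner_of(ev, bins)
        if element is None:
            continue
        per_element.setdefault((ev.anchor_chrom, element), []).append(ev.anchor_pos)
    for call in calls:
        positions = per_element.get((call.chrom, call.element_id), ())
        lo, hi = call.bp_low - window, call.bp_high + window
        call.somatic_status = (
            GERMLINE_SUPPORTED if any(lo <= p <= hi for p in positions) else SOMATIC
        )
    return list(calls)


def call_insertions(
    tumor_bam: str,
    reference,
    catalog: Sequence[SourceElement],
    regions: Sequence[TransducedRegion],
    bins: BinIndex,
    normal_bam: str | None = None,
    params: CallerParams | None = None,
    scan_params: ScanParams | None = None,
    sample_id: str = "sample",
    keep_filtered: bool = False,
) -> list[InsertionCall]:
    """End-to-end composition: scan -> realign -> cluster -> filter ->
    metacluster -> type -> (germline subtraction).  Deterministic: identical
    inputs yield identical call lists.

    ``reference`` may be a pyfaidx.Fasta or a dict of chromosome sequences.
    When ``normal_bam`` is given, germline evidence is extracted with the
    same parameters and calls are labeled SOMATIC / GERMLINE_SUPPORTED.
    """
    params = params or CallerParams()
    scan_params = scan_params or ScanParams()
    evidence = scan_alignments(tumor_bam, scan_params)
    region_seqs = extract_region_sequences(reference, regions)
    clips = [e for e in evidence if e.kind in (CLIP_LEFT, CLIP_RIGHT)]
    realign_clipped(clips, region_seqs, regions)
    clusters = cluster_evidence(evidence, bins, params)
    clusters = filter_clusters(clusters, params, bins)
    n_pass = sum(c.is_pass for c in clusters)
    log.info(
        "%s: %d evidence reads, %d clusters (%d PASS)",
        sample_id, len(evidence), len(clusters), n_pass,
    )
    metas = build_metaclusters([c for c in clusters if c.is_pass], params)
    termini = extract_element_termini(reference, catalog)
    calls = []
    for m in metas:
        call = InsertionCall(
            chrom=m.chrom,
            bp_low=m.bp_low,
            bp_high=m.bp_high,
            element_id=m.element_id,
            strand_class=m.strand_class,
            td_type=determine_td_type(m, termini),
            n_discordant=m.n_discordant,
            n_clipped=m.n_clipped,
            member_clusters=m.member_clusters,
            sample_id=sample_id,
        )
        calls.append(call)
    if normal_bam is not None:
        germ = scan_alignments(normal_bam, scan_params)
        germ_clips = [e for e in germ if e.kind in (CLIP_LEFT, CLIP_RIGHT)]
        realign_clipped(germ_clips, region_seqs, regions)
        subtract_germline(calls, germ, bins)
    calls.sort(key=lambda c: (c.chrom, c.bp_low, c.element_id))
    log.info("%s: %d insertion calls", sample_id, len(calls))
    return calls
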