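"""Truth-annotated simulation of orphan L1 transduction insertions.

The generator reproduces the benchmark construction used to validate the
caller: for every source element a library of transduction sequences is made
by randomly 3'-trimming its 5 kb downstream window (alternative transcript
ends); insertion points are drawn in 10 kb bins over nuclear chromosomes,
avoiding assembly gaps; at each point an insert is emplaced carrying the
canonical mobile-element hallmarks (target-site duplication, poly(A) tail,
optional 5' truncation, random insert strand); paired-end reads are then
drawn at a chosen depth, with a fraction VAF of fragments coming from the
insertion-bearing haplotype.

Reads can be emitted as FASTQ (for integration with a real aligner) or as
ready-made alignment records against the ORIGINAL reference ("aligned"
mode).  Aligned mode maps each read interval analytically through the
insertion coordinate map: reads from untouched sequence align full-length,
reads inside an insert align inside the donor's transduced region, and reads
straddling a junction are soft-clipped at it -- exactly the evidence the
caller consumes, with no external aligner in the loop.

All randomness flows from one numpy Generator; every output file records the
seed in its header.
"""

from __future__ import annotations

import logging
import zlib
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam

from ._seq import fetch_seq, revcomp
from .catalog import (
    DEFAULT_BIN_BP,
    DEFAULT_WINDOW_BP,
    GapTrack,
    SourceElement,
    TransducedRegion,
    chrom_lengths_of,
    derive_transduced_regions,
)

log = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Simulation conditions.

    Defaults are the benchmark's study conditions: 20 transduction variants
    per element, 10 kb placement bins, 150 bp reads with 350 bp +/- 10 %
    inserts, VAF set {10, 20, 40, 50} %, depth set {15...150}x obtained by
    downsampling a 150x base simulation.  Hallmark distributions (TSD 5-20
    bp, poly(A) 10-60 bp, 5' truncation with probability 0.5 removing up to
    20 % of the transduction) follow typical L1 insertion biology and are
    config-exposed.
    """

    n_per_element: int = 20
    bin_size_bp: int = DEFAULT_BIN_BP
    read_len: int = 150
    insert_mean: float = 350.0
    insert_sd_frac: float = 0.10
    vafs: tuple[float, ...] = (0.10, 0.20, 0.40, 0.50)
    depths: tuple[int, ...] = (15, 30, 60, 90, 120, 150)
    base_depth: int = 150
    tsd_range: tuple[int, int] = (5, 20)
    polya_range: tuple[int, int] = (10, 60)
    trunc5_prob: float = 0.5
    trunc5_max_frac: float = 0.20
    min_td_len: int = 100
    error_rate: float = 0.001
    max_proper_insert: int = 1000
    min_anchor_bp: int = 20
    mito_names: tuple[str, ...] = ("chrM", "chrMT", "MT", "M")
    end_margin: int = 1000

    def __post_init__(self) -> None:
        if not all(0 < v <= 1 for v in self.vafs):
            raise ValueError("VAFs must lie in (0, 1]")
        if self.read_len <= 0 or self.bin_size_bp <= 0:
            raise ValueError("read_len and bin_size_bp must be positive")


@dataclass(frozen=True)
class TransductionSeq:
    """One simulated transcript read-through product, 5'->3' in transcript
    sense (orientation already applied)."""

    element_id: str
    seq: str
    length: int
    trim_offset: int


@dataclass
class SimulatedInsertion:
    """Truth record; coordinates refer to the ORIGINAL reference."""

    chrom: str
    pos: int
    element_id: str
    transduction_length: int  # length after 3' trim, before 5' truncation
    tsd_len: int
    polya_len: int
    trunc5_len: int
    vaf: float
    insert_strand: str
    insert_len: int = 0  # emplaced length incl. poly(A), excl. TSD copy


# ---------------------------------------------------------------------------
# coordinate frames: affine pieces mapping modified -> original/donor coords


@dataclass(frozen=True)
class _Frame:
    """One mappable piece of the modified genome.

    Not flipped: orig = mod + shift.  Flipped (donor window read in the
    opposite sense): a modified-coordinate block [u, v) maps to the target
    interval [shift - v, shift - u) on the reverse strand.
    """

    mod_start: int
    mod_end: int
    target_chrom: str
    flip: bool
    shift: int


@dataclass
class SimulatedGenome:
    """Original + insertion-bearing haplotype with the frame map between them."""

    original: dict[str, str]
    modified: dict[str, str]
    insertions: list[SimulatedInsertion]
    frames: dict[str, list[_Frame]]
    seed: int
    params: SimParams

    @property
    def original_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.original.items()}

    @property
    def modified_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.modified.items()}

    def write_truth(self, bed_path: str, tsv_path: str | None = None) -> None:
        with open(bed_path, "w") as fh:
            fh.write(f"# simulated insertion truth, seed={self.seed}\n")
            for ins in sorted(self.insertions, key=lambda i: (i.chrom, i.pos)):
                fh.write(
                    f"{ins.chrom}\t{ins.pos}\t{ins.pos + 1}\t{ins.element_id}\t"
                    f"{ins.transduction_length}\t{ins.insert_strand}\n"
                )
        if tsv_path:
            with open(tsv_path, "w") as fh:
                fh.write(f"# seed={self.seed}\n")
                fh.write(
                    "chrom\tpos\telement_id\ttransduction_length\ttsd_len\t"
                    "polya_len\ttrunc5_len\tvaf\tinsert_strand\tinsert_len\n"
                )
                for i in sorted(self.insertions, key=lambda i: (i.chrom, i.pos)):
                    fh.write(
                        f"{i.chrom}\t{i.pos}\t{i.element_id}\t{i.transduction_length}\t"
                        f"{i.tsd_len}\t{i.polya_len}\t{i.trunc5_len}\t{i.vaf}\t"
                        f"{i.insert_strand}\t{i.insert_len}\n"
                    )

    def write_modified_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.modified.items():
                fh.write(f">{chrom} modified seed={self.seed}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def generate_transduction_library(
    catalog: Sequence[SourceElement],
    reference,
    params: SimParams,
    rng: np.random.Generator,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[TransductionSeq]:
    """``n_per_element`` transduction sequences per element by random 3' trim.

    The downstream window is read in transcript sense (reverse-complemented
    for '-' elements); a uniform trim in [1, window - min_td_len] shortens
    the 3' end, emulating alternative downstream poly(A) sites.  All-N
    windows are skipped with a warning.
    """
    regions = derive_transduced_regions(catalog, chrom_lengths_of(reference), window_bp)
    library: list[TransductionSeq] = []
    for el, reg in zip(catalog, regions):
        seq = fetch_seq(reference, reg.chrom, reg.start, reg.end)
        if reg.orientation == "-":
            seq = revcomp(seq)
        if set(seq) <= {"N"}:
            log.warning("element %s: downstream window is all N, skipped", el.element_id)
            continue
        full = len(seq)
        max_trim = max(full - params.min_td_len, 0)
        for _ in range(params.n_per_element):
            trim = int(rng.integers(1, max_trim + 1)) if max_trim > 0 else 0
            library.append(
                TransductionSeq(el.element_id, seq[: full - trim], full - trim, trim)
            )
    return library


def select_insertion_sites(
    chrom_lengths: dict[str, int],
    gaps: GapTrack,
    n: int,
    params: SimParams,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Sample ``n`` insertion points: bins without replacement over nuclear
    chromosomes, one uniform non-gap position per chosen bin.

    Mitochondrial sequences (``mito_names``) are excluded, as are positions
    within ``end_margin`` of a chromosome end (no room for a fragment).
    """
    bins: list[tuple[str, int]] = []
    for chrom, length in chrom_lengths.items():
        if chrom in params.mito_names:
            continue
        for b in range(length // params.bin_size_bp):
            lo = max(b * params.bin_size_bp, params.end_margin)
            hi = min((b + 1) * params.bin_size_bp, length - params.end_margin)
            if hi <= lo:
                continue
            if _first_free(gaps, chrom, lo, hi) is not None:
                bins.append((chrom, b))
    if n > len(bins):
        raise ValueError(f"requested {n} sites but only {len(bins)} eligible bins")
    chosen = rng.choice(len(bins), size=n, replace=False)
    sites: list[tuple[str, int]] = []
    for idx in sorted(int(i) for i in chosen):
        chrom, b = bins[idx]
        length = chrom_lengths[chrom]
        lo = max(b * params.bin_size_bp, params.end_margin)
        hi = min((b + 1) * params.bin_size_bp, length - params.end_margin)
        pos = None
        for _ in range(100):
            cand = int(rng.integers(lo, hi))
            if not gaps.contains(chrom, cand):
                pos = cand
                break
        if pos is None:
            pos = _first_free(gaps, chrom, lo, hi)
        sites.append((chrom, pos))
    sites.sort()
    return sites


def _first_free(gaps: GapTrack, chrom: str, lo: int, hi: int):
    for pos in range(lo, hi):
        if not gaps.contains(chrom, pos):
            return pos
    return None


def emplace_insertions(
    reference,
    sites: Sequence[tuple[str, int]],
    library: Sequence[TransductionSeq],
    regions: Sequence[TransducedRegion],
    params: SimParams,
    rng: np.random.Generator,
    vaf: float = 0.5,
    seed: int = 0,
) -> SimulatedGenome:
    """Build the insertion-bearing haplotype and its truth records.

    At each site the emplaced sequence is ``[insert][TSD copy]``: the insert
    is an optionally 5'-truncated transduction followed by a poly(A) tail
    (reverse-complemented as a block when it lands on '-'), and the TSD copy
    duplicates the ``tsd_len`` reference bases immediately left of the
    insertion point, so those bases flank the insert on both sides.
    Coordinate frames for aligned-read emission are built alongside.
    """
    if not sites or not library:
        raise ValueError("sites and library must be non-empty")
    region_by_id = {r.element_id: r for r in regions}
    chroms = list(reference.keys())
    original = {c: fetch_seq(reference, c, 0, len(reference[c])) for c in chroms}
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate insertion sites")

    per_chrom: dict[str, list] = {}
    insertions: list[SimulatedInsertion] = []
    for chrom, pos in sorted(sites):
        td = library[int(rng.integers(0, len(library)))]
        tsd = int(rng.integers(params.tsd_range[0], params.tsd_range[1] + 1))
        polya = int(rng.integers(params.polya_range[0], params.polya_range[1] + 1))
        trunc5 = 0
        if rng.random() < params.trunc5_prob:
            trunc5 = int(rng.integers(0, max(int(params.trunc5_max_frac * td.length), 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        core = td.seq[trunc5:]
        ins_seq = core + "A" * polya
        if strand == "-":
            ins_seq = revcomp(ins_seq)
        rec = SimulatedInsertion(
            chrom, pos, td.element_id, td.length, tsd, polya, trunc5, vaf, strand,
            insert_len=len(ins_seq),
        )
        insertions.append(rec)
        per_chrom.setdefault(chrom, []).append((pos, rec, len(core)))

    modified: dict[str, str] = {}
    frames: dict[str, list[_Frame]] = {}
    for chrom, seq in original.items():
        events = sorted(per_chrom.get(chrom, []), key=lambda t: t[0])
        pieces: list[str] = []
        frame_list: list[_Frame] = []
        prev = 0
        offset = 0
        frame_start = 0
        for pos, rec, core_len in events:
            m = pos + offset  # modified coordinate of insert start
            pieces.append(seq[prev:pos])
            reg = region_by_id[rec.element_id]
            core = _oriented_core(original, reg, rec, core_len)
            ins_seq = core + "A" * rec.polya_len
            if rec.insert_strand == "-":
                ins_seq = revcomp(ins_seq)
            pieces.append(ins_seq)
            pieces.append(seq[pos - rec.tsd_len : pos])
            # reference frame ending at the insert start
            frame_list.append(_Frame(frame_start, m, chrom, False, -offset))
            # donor frame for the transduction part of the insert
            td_lo = m if rec.insert_strand == "+" else m + rec.polya_len
            td_hi = td_lo + core_len
            el_strand = reg.orientation
            flip = (el_strand == "-") != (rec.insert_strand == "-")
            if el_strand == "+" and rec.insert_strand == "+":
                shift = reg.start + rec.trunc5_len - td_lo
            elif el_strand == "-" and rec.insert_strand == "+":
                shift = reg.end - rec.trunc5_len + td_lo
            elif el_strand == "+" and rec.insert_strand == "-":
                shift = reg.start + rec.trunc5_len + core_len + td_lo
            else:
                shift = reg.end - rec.trunc5_len - core_len - td_lo
            frame_list.append(_Frame(td_lo, td_hi, reg.chrom, flip, shift))
            offset += rec.insert_len + rec.tsd_len
            frame_start = m + rec.insert_len  # TSD copy opens the next ref frame
            prev = pos
        pieces.append(seq[prev:])
        frame_list.append(_Frame(frame_start, len(seq) + offset, chrom, False, -offset))
        modified[chrom] = "".join(pieces)
        frames[chrom] = sorted(frame_list, key=lambda f: f.mod_start)

    return SimulatedGenome(original, modified, insertions, frames, seed, params)


def _oriented_core(original, reg: TransducedRegion, rec: SimulatedInsertion, core_len: int) -> str:
    """Transduction core (transcript sense, 5'-truncated) from the reference."""
    window = original[reg.chrom][reg.start : reg.end]
    if reg.orientation == "-":
        window = revcomp(window)
    return window[rec.trunc5_len : rec.trunc5_len + core_len]


# ---------------------------------------------------------------------------
# read simulation


def _interesting_intervals(
    simg: SimulatedGenome,
    regions: Sequence[TransducedRegion],
    margin: int,
) -> tuple[dict, dict]:
    """Merged (starts, ends) arrays per chromosome, in original- and
    modified-genome coordinates, outside which a fragment cannot be captured:
    donor windows plus insert neighborhoods."""
    orig: dict[str, list[tuple[int, int]]] = {}
    mod: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[SimulatedInsertion]] = {}
    for ins in simg.insertions:
        by_chrom.setdefault(ins.chrom, []).append(ins)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda i: i.pos)
    for reg in regions:
        orig.setdefault(reg.chrom, []).append((reg.start - margin, reg.end + margin))
        shift = 0
        for ins in by_chrom.get(reg.chrom, []):
            if ins.pos <= reg.start:
                shift += ins.insert_len + ins.tsd_len
        mod.setdefault(reg.chrom, []).append(
            (reg.start + shift - margin, reg.end + shift + margin)
        )
    for chrom, inss in by_chrom.items():
        offset = 0
        for ins in inss:
            m = ins.pos + offset
            mod.setdefault(chrom, []).append(
                (m - margin, m + ins.insert_len + ins.tsd_len + margin)
            )
            offset += ins.insert_len + ins.tsd_len

    def merge(d):
        out = {}
        for chrom, ivs in d.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                s = max(s, 0)
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = (
                np.array([m[0] for m in merged], dtype=np.int64),
                np.array([m[1] for m in merged], dtype=np.int64),
            )
        return out

    return merge(orig), merge(mod)


@dataclass
class _SimRead:
    """One mate before SAM materialization."""

    chrom: str | None  # None = unmapped
    pos: int = 0
    end: int = 0
    is_reverse: bool = False
    cigar: tuple | None = None  # (pre_clip, match, post_clip) along SEQ
    seq: str = ""


def _map_block(frames: list[_Frame], starts: list[int], a: int, b: int, min_anchor: int):
    """Longest single-frame overlap of read interval [a, b); ties leftmost.
    Returns (frame, u, v) or None if no block reaches ``min_anchor`` bp."""
    best = None
    i = max(bisect_right(starts, a) - 1, 0)
    while i < len(frames) and frames[i].mod_start < b:
        fr = frames[i]
        u, v = max(a, fr.mod_start), min(b, fr.mod_end)
        if v - u >= min_anchor:
            cand = (v - u, -u)
            if best is None or cand > best[0]:
                best = (cand, fr, u, v)
        i += 1
    return None if best is None else (best[1], best[2], best[3])


def simulate_reads(
    simg: SimulatedGenome,
    vaf: float,
    depth: float,
    rng: np.random.Generator,
    out_prefix: str,
    mode: str = "aligned",
    regions: Sequence[TransducedRegion] | None = None,
    capture: bool = False,
    params: SimParams | None = None,
) -> str | tuple[str, str]:
    """Draw paired-end fragments and emit reads.

    A fraction ``vaf`` of fragments comes from the insertion-bearing
    haplotype, the rest from the original genome; fragment lengths are
    normal (mean ``insert_mean``, sd 10 %) truncated at twice the read
    length.  ``mode="aligned"`` writes a coordinate-sorted, indexed BAM of
    analytic alignments against the original reference and returns its path;
    ``mode="fastq"`` writes an R1/R2 FASTQ pair and returns both paths.

    With ``capture=True`` only pairs with >= 1 mate overlapping a transduced
    region (after mapping) are kept, mirroring the on-target selection of a
    hybrid-capture assay; ``regions`` is then required.
    """
    params = params or simg.params
    if mode not in ("aligned", "fastq"):
        raise ValueError(f"unknown mode {mode!r}")
    if capture and regions is None:
        raise ValueError("capture=True requires regions")
    if not 0 < vaf <= 1:
        raise ValueError("vaf must be in (0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rl = params.read_len
    chroms = list(simg.original)
    orig_lens = np.array([len(simg.original[c]) for c in chroms], dtype=np.int64)
    mod_lens = np.array([len(simg.modified[c]) for c in chroms], dtype=np.int64)
    total = int(orig_lens.sum())
    n_frags = int(round(depth * total / (2 * rl)))

    frag_len = rng.normal(params.insert_mean, params.insert_mean * params.insert_sd_frac, n_frags)
    frag_len = np.clip(np.rint(frag_len), 2 * rl, 2 * params.insert_mean).astype(np.int64)
    from_mod = rng.random(n_frags) < vaf
    u = rng.random(n_frags)
    cum_orig = np.cumsum(orig_lens / orig_lens.sum())
    cum_mod = np.cumsum(mod_lens / mod_lens.sum())
    chrom_idx = np.empty(n_frags, dtype=np.int64)
    chrom_idx[~from_mod] = np.searchsorted(cum_orig, u[~from_mod])
    chrom_idx[from_mod] = np.searchsorted(cum_mod, u[from_mod])
    chrom_idx = np.clip(chrom_idx, 0, len(chroms) - 1)
    lens_of = np.where(from_mod, mod_lens[chrom_idx], orig_lens[chrom_idx])
    max_start = np.maximum(lens_of - frag_len, 1)
    start = (rng.random(n_frags) * max_start).astype(np.int64)

    # candidate prefilter: with capture on, only fragments near a donor window
    # or an insert can possibly survive; everything else is skipped wholesale
    if capture:
        orig_iv, mod_iv = _interesting_intervals(simg, regions, margin=int(2 * params.insert_mean))
        candidate = np.zeros(n_frags, dtype=bool)
        for gi, ivs in ((0, orig_iv), (1, mod_iv)):
            gmask = from_mod if gi else ~from_mod
            for ci, chrom in enumerate(chroms):
                mask = gmask & (chrom_idx == ci)
                if not mask.any() or chrom not in ivs:
                    continue
                st, en = ivs[chrom]
                xs = start[mask]
                idx = np.searchsorted(en, xs, side="right")
                ok = (idx < len(st)) & (st[np.minimum(idx, len(st) - 1)] < xs + frag_len[mask])
                sub = np.nonzero(mask)[0]
                candidate[sub[ok]] = True
        indices = np.nonzero(candidate)[0]
    else:
        indices = np.arange(n_frags)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in zip(chroms, orig_lens)],
            "PG": [{"ID": "tdscan-sim", "PN": "tdscan-sim"}],
            "CO": [f"seed={simg.seed} vaf={vaf} depth={depth}"],
        }
    )
    tid_of = {c: i for i, c in enumerate(chroms)}
    frame_starts = {c: [f.mod_start for f in simg.frames[c]] for c in simg.frames}
    region_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for reg in regions or ():
        region_by_chrom.setdefault(reg.chrom, []).append((reg.start, reg.end))

    records: list[tuple] = []
    fastq1: list[str] = []
    fastq2: list[str] = []
    pairs_written = 0

    for i in indices:
        c = chroms[int(chrom_idx[i])]
        x = int(start[i])
        L = int(frag_len[i])
        modded = bool(from_mod[i])
        genome = simg.modified[c] if modded else simg.original[c]
        mates = ((x, x + rl, False), (x + L - rl, x + L, True))

        reads: list[_SimRead] = []
        raws: list[str] = []
        for a, b, right_mate in mates:
            raw = genome[a:b]
            if params.error_rate > 0:
                raw = _mutate(raw, params.error_rate, rng)
            raws.append(raw)
            if modded:
                m = _map_block(simg.frames[c], frame_starts[c], a, b, params.min_anchor_bp)
            else:
                m = (_Frame(0, len(genome), c, False, 0), a, b)
            if m is None:
                reads.append(_SimRead(None, seq=raw, is_reverse=right_mate))
                continue
            fr, u_, v_ = m
            if not fr.flip:
                reads.append(
                    _SimRead(
                        fr.target_chrom,
                        pos=u_ + fr.shift,
                        end=v_ + fr.shift,
                        is_reverse=right_mate,
                        cigar=(u_ - a, v_ - u_, b - v_),
                        seq=raw,
                    )
                )
            else:
                reads.append(
                    _SimRead(
                        fr.target_chrom,
                        pos=fr.shift - v_,
                        end=fr.shift - u_,
                        is_reverse=not right_mate,
                        cigar=(b - v_, v_ - u_, u_ - a),
                        seq=revcomp(raw),
                    )
                )

        r1, r2 = reads
        if r1.chrom is None and r2.chrom is None:
            continue
        if capture and not any(
            rd.chrom is not None
            and any(rd.pos < e and s < rd.end for s, e in region_by_chrom.get(rd.chrom, ()))
            for rd in reads
        ):
            continue

        name = f"sim{i}"
        if mode == "fastq":
            s1 = raws[0]
            s2 = revcomp(raws[1])
            fastq1.append(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            fastq2.append(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")
            pairs_written += 1
            continue

        proper = (
            r1.chrom is not None
            and r2.chrom is not None
            and r1.chrom == r2.chrom
            and r1.is_reverse != r2.is_reverse
        )
        if proper:
            fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
            tl = rev.end - fwd.pos
            proper = 0 < tl <= params.max_proper_insert and fwd.pos <= rev.pos
        for mate_idx, (rd, mate) in enumerate(((r1, r2), (r2, r1))):
            seg = pysam.AlignedSegment(header)
            seg.query_name = name
            seg.query_sequence = rd.seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(rd.seq))
            flag = 1 | (64 if mate_idx == 0 else 128)
            if rd.chrom is None:
                flag |= 4
                seg.reference_id = tid_of[mate.chrom]
                seg.reference_start = mate.pos
                seg.mapping_quality = 0
            else:
                if rd.is_reverse:
                    flag |= 16
                seg.reference_id = tid_of[rd.chrom]
                seg.reference_start = rd.pos
                seg.mapping_quality = 60
                pre, match, post = rd.cigar
                cig = []
                if pre:
                    cig.append((4, pre))
                cig.append((0, match))
                if post:
                    cig.append((4, post))
                seg.cigartuples = cig
            if mate.chrom is None:
                flag |= 8
                seg.next_reference_id = seg.reference_id
                seg.next_reference_start = seg.reference_start
            else:
                if mate.is_reverse:
                    flag |= 32
                seg.next_reference_id = tid_of[mate.chrom]
                seg.next_reference_start = mate.pos
            if proper:
                flag |= 2
                span = max(rd.end, mate.end) - min(rd.pos, mate.pos)
                seg.template_length = span if rd.pos <= mate.pos else -span
            else:
                seg.template_length = 0
            seg.flag = flag
            records.append((seg.reference_id, seg.reference_start, name, seg.flag, seg))
        pairs_written += 1

    log.info(
        "simulated %d fragments (vaf=%.2f, depth=%.0fx): wrote %d pairs%s",
        n_frags, vaf, depth, pairs_written, " (on-target)" if capture else "",
    )

    if mode == "fastq":
        p1, p2 = out_prefix + "_R1.fastq", out_prefix + "_R2.fastq"
        with open(p1, "w") as fh:
            fh.writelines(fastq1)
        with open(p2, "w") as fh:
            fh.writelines(fastq2)
        return p1, p2

    bam_path = out_prefix + ".bam"
    records.sort(key=lambda t: t[:4])
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for *_, seg in records:
            bam.write(seg)
    pysam.index(bam_path)
    return bam_path


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    arr = list(seq)
    for pos in rng.integers(0, len(seq), size=n):
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def capture_filter(bam_in: str, regions: Sequence[TransducedRegion], bam_out: str) -> str:
    """Keep pairs with >= 1 mate overlapping >= 1 bp of a transduced region."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for reg in regions:
        by_chrom.setdefault(reg.chrom, []).append((reg.start, reg.end))

    def on_target(chrom, start, end):
        return any(start < e and s < end for s, e in by_chrom.get(chrom, ()))

    with pysam.AlignmentFile(bam_in) as src:
        keep: set[str] = set()
        for r in src.fetch(until_eof=True):
            if r.is_unmapped or r.is_secondary or r.is_supplementary:
                continue
            if on_target(r.reference_name, r.reference_start, r.reference_end):
                keep.add(r.query_name)
        src.reset()
        with pysam.AlignmentFile(bam_out, "wb", template=src) as dst:
            for r in src.fetch(until_eof=True):
                if r.query_name in keep:
                    dst.write(r)
    pysam.index(bam_out)
    return bam_out


def downsample(
    bam_in: str,
    bam_out: str,
    target_depth: float,
    base_depth: float,
    seed: int = 0,
) -> str:
    """Pair-coherent Bernoulli downsampling to ``target_depth / base_depth``.

    Keep/drop is a deterministic hash of (seed, read name), so both mates of
    a pair share their fate and reruns are bit-identical.
    """
    if target_depth > base_depth:
        raise ValueError("target depth exceeds base depth")
    frac = target_depth / base_depth
    with pysam.AlignmentFile(bam_in) as src:
        with pysam.AlignmentFile(bam_out, "wb", template=src) as dst:
            for r in src.fetch(until_eof=True):
                h = zlib.crc32(f"{seed}:{r.query_name}".encode()) / 2**32
                if h < frac:
                    dst.write(r)
    pysam.index(bam_out)
    return bam_out
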