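"""Shared fixtures: synthetic references and hand-built alignment files."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from tdscan.catalog import build_bin_index, derive_transduced_regions
from tdscan.synth import build_toy_reference


@pytest.fixture(scope="session")
def toy():
    """Small two-chromosome genome with 6 source elements and one gap each."""
    return build_toy_reference(
        n_chroms=2, chrom_len=600_000, n_elements=6, seed=3, with_mito=True
    )


@pytest.fixture(scope="session")
def toy_regions(toy):
    return derive_transduced_regions(toy.catalog, toy.chrom_lengths)


@pytest.fixture(scope="session")
def toy_bins(toy, toy_regions):
    return build_bin_index(toy_regions, toy.chrom_lengths)


def make_bam(path, chrom_lengths, records):
    """Write a coordinate-sorted, indexed BAM from simple record dicts.

    Each record: qname, chrom, pos, cigar (string), seq, flags via booleans
    (reverse, mate_reverse, proper, read1, dup), mate_chrom, mate_pos, tlen,
    mapq.
    """
    chroms = list(chrom_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    segs = []
    for r in records:
        seg = pysam.AlignedSegment(header)
        seg.query_name = r["qname"]
        seg.query_sequence = r["seq"]
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
        seg.reference_id = tid[r["chrom"]]
        seg.reference_start = r["pos"]
        seg.cigarstring = r["cigar"]
        seg.mapping_quality = r.get("mapq", 60)
        flag = 1
        flag |= 64 if r.get("read1", True) else 128
        if r.get("reverse"):
            flag |= 16
        if r.get("mate_reverse"):
            flag |= 32
        if r.get("proper"):
            flag |= 2
        if r.get("dup"):
            flag |= 1024
        seg.flag = flag
        seg.next_reference_id = tid[r.get("mate_chrom", r["chrom"])]
        seg.next_reference_start = r.get("mate_pos", r["pos"])
        seg.template_length = r.get("tlen", 0)
        segs.append(seg)
    segs.sort(key=lambda s: (s.reference_id, s.reference_start))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for seg in segs:
            bam.write(seg)
    pysam.index(str(path))
    return str(path)


def smith_waterman(query: str, target: str, match=1, mismatch=-1, gap=-2) -> int:
    """Exhaustive local-alignment score; the independent oracle for clip
    realignment acceptance thresholds (tiny inputs only)."""
    n, m = len(query), len(target)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            s = match if query[i - 1] == target[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + s, prev[j] + gap, cur[j - 1] + gap)
            best = max(best, cur[j])
        prev = cur
    return best
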