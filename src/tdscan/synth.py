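"""Deterministic synthetic reference genomes carrying L1 source elements.

Real use of the pipeline takes hg19/hg38 plus the published catalog of 124
active source elements.  For tests, benchmarks, and examples this module
fabricates a miniature stand-in: a random nucleotide genome with a chosen
number of "L1" loci (opaque element bodies; only their coordinates and
strands matter to the assay), optional N-run assembly gaps, and the matching
BED6 catalog.  Random sequence is effectively unique at 20-mer scale, which
mimics the uniqueness of real downstream transduced regions.

Everything is generated from a single seed, so the reference, catalog, and
gap track of a given configuration are reproducible bit-for-bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .catalog import DEFAULT_WINDOW_BP, GapTrack, SourceElement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticReference:
    """In-memory synthetic genome: sequences, catalog, and gap track."""

    sequences: dict[str, str]
    catalog: list[SourceElement]
    gaps: GapTrack
    seed: int

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write(self, outdir: str, prefix: str = "toy") -> dict[str, str]:
        """Write FASTA + catalog BED + gaps BED; returns the paths."""
        os.makedirs(outdir, exist_ok=True)
        fasta = os.path.join(outdir, f"{prefix}.fa")
        with open(fasta, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom} synthetic seed={self.seed}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        cat = os.path.join(outdir, f"{prefix}_catalog.bed")
        with open(cat, "w") as fh:
            fh.write(f"# synthetic source-element catalog, seed={self.seed}\n")
            for el in self.catalog:
                fh.write(
                    f"{el.chrom}\t{el.start}\t{el.end}\t{el.element_id}\t0\t{el.strand}\n"
                )
        gaps = os.path.join(outdir, f"{prefix}_gaps.bed")
        with open(gaps, "w") as fh:
            for chrom, start, end in self.gaps.intervals():
                fh.write(f"{chrom}\t{start}\t{end}\n")
        # build the .fai so pysam/pyfaidx can random-access immediately
        import pyfaidx

        pyfaidx.Faidx(fasta)
        return {"fasta": fasta, "catalog": cat, "gaps": gaps}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def build_toy_reference(
    n_chroms: int = 3,
    chrom_len: int = 2_000_000,
    n_elements: int = 12,
    element_len: int = 6000,
    window_bp: int = DEFAULT_WINDOW_BP,
    gaps_per_chrom: int = 1,
    gap_len: int = 20_000,
    seed: int = 0,
    with_mito: bool = False,
) -> SyntheticReference:
    """Build a synthetic genome with ``n_elements`` source elements.

    Elements are placed away from chromosome ends and gaps so that every
    derived downstream window is full length; element strands alternate
    deterministically with the rng.  ``with_mito`` appends a small chrM to
    exercise the simulator's nuclear-chromosome restriction.
    """
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {name: _random_seq(rng, chrom_len) for name in names}

    # punch N gaps into the middle third of each chromosome
    gap_ivs: list[tuple[str, int, int]] = []
    for name in names:
        for _ in range(gaps_per_chrom):
            lo = chrom_len // 3
            hi = 2 * chrom_len // 3 - gap_len
            start = int(rng.integers(lo, hi))
            gap_ivs.append((name, start, start + gap_len))
            s = seqs[name]
            seqs[name] = s[:start] + "N" * gap_len + s[start + gap_len :]
    gaps = GapTrack(gap_ivs)

    # element placement: keep body + window clear of ends, gaps, other elements
    margin = 50_000
    footprint = element_len + window_bp
    occupied: dict[str, list[tuple[int, int]]] = {name: list() for name in names}
    for chrom, gs, ge in gap_ivs:
        occupied[chrom].append((gs - footprint, ge + footprint))
    catalog: list[SourceElement] = []
    attempts = 0
    while len(catalog) < n_elements:
        attempts += 1
        if attempts > 200 * n_elements:
            raise RuntimeError(
                "could not place all elements; genome too small for request"
            )
        chrom = names[int(rng.integers(0, n_chroms))]
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(margin, chrom_len - margin - footprint))
        if strand == "+":
            body = (pos, pos + element_len)
            span = (pos, pos + footprint)
        else:
            body = (pos + window_bp, pos + footprint)
            span = (pos, pos + footprint)
        pad = 2000  # keep windows of different elements disjoint
        if any(span[0] - pad < e and s < span[1] + pad for s, e in occupied[chrom]):
            continue
        occupied[chrom].append(span)
        eid = f"L1_{len(catalog) + 1:03d}"
        catalog.append(SourceElement(eid, chrom, body[0], body[1], strand))
    catalog.sort(key=lambda el: (el.chrom, el.start))

    if with_mito:
        seqs["chrM"] = _random_seq(rng, 16_000)

    return SyntheticReference(seqs, catalog, gaps, seed)
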