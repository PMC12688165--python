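"""Tiny sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fetch_seq(reference, chrom: str, start: int, end: int) -> str:
    """Uppercase sequence slice from a dict of strings or a pyfaidx.Fasta.

    Raises if the requested interval is negative or out of bounds.
    """
    if start < 0 or end < start:
        raise ValueError(f"invalid region {chrom}:{start}-{end}")
    try:
        record = reference[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} absent from reference") from None
    seq = str(record[start:end])
    if len(seq) != end - start:
        raise ValueError(
            f"region {chrom}:{start}-{end} out of bounds (got {len(seq)} bp)"
        )
    return seq.upper()
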