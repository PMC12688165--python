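"""Call writers/readers (BED6, TSV, minimal VCF 4.2) and config plumbing.

Every artifact embeds the tool version, seed, and a hash of the effective
configuration in its header, so two runs with equal config hashes are
byte-comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any, Sequence

import yaml

from . import __version__
from .caller import InsertionCall

_STRAND_OF = {"PLUS": "+", "MINUS": "-", "RECIPROCAL": "."}

TSV_COLUMNS = [
    "sample_id", "chrom", "bp_low", "bp_high", "element_id", "td_type",
    "strand_class", "n_discordant", "n_clipped", "somatic_status", "vaf_estimate",
]


def config_hash(config: dict[str, Any]) -> str:
    """Stable short hash of an effective configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(seed: int | None, config: dict | None, comment: str = "#") -> list[str]:
    lines = [f"{comment}tdscan_version={__version__}"]
    if seed is not None:
        lines.append(f"{comment}seed={seed}")
    if config is not None:
        lines.append(f"{comment}config_hash={config_hash(config)}")
    return lines


def write_calls(
    calls: Sequence[InsertionCall],
    path: str,
    fmt: str = "bed",
    seed: int | None = None,
    config: dict | None = None,
) -> str:
    """Write calls as BED6, TSV, or minimal VCF 4.2.

    BED name field packs ``element|td_type|strand_class``; score is total
    supporting reads; strand column reflects the strand class ('.' for
    RECIPROCAL).  Calls must already be sorted.
    """
    if fmt == "bed":
        with open(path, "w") as fh:
            for line in _header_lines(seed, config):
                fh.write(line + "\n")
            for c in calls:
                name = f"{c.element_id}|{c.td_type}|{c.strand_class}"
                support = c.n_discordant + c.n_clipped
                strand = _STRAND_OF.get(c.strand_class, ".")
                fh.write(
                    f"{c.chrom}\t{c.bp_low}\t{max(c.bp_high, c.bp_low + 1)}\t"
                    f"{name}\t{support}\t{strand}\n"
                )
    elif fmt == "tsv":
        with open(path, "w") as fh:
            for line in _header_lines(seed, config):
                fh.write(line + "\n")
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for c in calls:
                vals = [getattr(c, col) for col in TSV_COLUMNS]
                fh.write("\t".join("" if v is None else str(v) for v in vals) + "\n")
    elif fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=tdscan {__version__}\n")
            for line in _header_lines(seed, config, comment="##"):
                fh.write(line + "\n")
            fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
            fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Breakpoint interval end">\n')
            fh.write('##INFO=<ID=SRCELEM,Number=1,Type=String,Description="Donor source element">\n')
            fh.write('##INFO=<ID=TDTYPE,Number=1,Type=String,Description="Transduction type">\n')
            fh.write('##INFO=<ID=STRANDCLASS,Number=1,Type=String,Description="Supporting-read strand class">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for i, c in enumerate(calls):
                info = (
                    f"SVTYPE=INS;END={c.bp_high + 1};SRCELEM={c.element_id};"
                    f"TDTYPE={c.td_type};STRANDCLASS={c.strand_class}"
                )
                fh.write(
                    f"{c.chrom}\t{c.bp_low + 1}\tINS{i + 1}\tN\t<INS:ME:L1>\t.\tPASS\t{info}\n"
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_calls(path: str, fmt: str = "tsv") -> list[InsertionCall]:
    """Round-trip reader for the TSV and BED writers."""
    calls: list[InsertionCall] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "tsv":
                if header is None:
                    header = fields
                    continue
                row = dict(zip(header, fields))
                calls.append(
                    InsertionCall(
                        chrom=row["chrom"],
                        bp_low=int(row["bp_low"]),
                        bp_high=int(row["bp_high"]),
                        element_id=row["element_id"],
                        td_type=row["td_type"],
                        strand_class=row["strand_class"],
                        n_discordant=int(row["n_discordant"]),
                        n_clipped=int(row["n_clipped"]),
                        sample_id=row["sample_id"],
                        somatic_status=row["somatic_status"],
                        vaf_estimate=float(row["vaf_estimate"]) if row["vaf_estimate"] else None,
                    )
                )
            elif fmt == "bed":
                chrom, start, end, name, score, _strand = fields[:6]
                element, td_type, strand_class = name.split("|")
                calls.append(
                    InsertionCall(
                        chrom=chrom,
                        bp_low=int(start),
                        bp_high=int(end) - 1 if int(end) - int(start) == 1 else int(end),
                        element_id=element,
                        td_type=td_type,
                        strand_class=strand_class,
                        n_discordant=int(score),
                        n_clipped=0,
                    )
                )
            else:
                raise ValueError(f"unknown format {fmt!r}")
    return calls


def load_config(path: str | None) -> dict[str, Any]:
    """YAML config file -> flat dict (empty when no file given)."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def params_with_overrides(cls, config: dict[str, Any], **overrides):
    """Instantiate a params dataclass from config keys + explicit overrides
    (overrides win; unknown config keys are ignored)."""
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in config.items() if k in names}
    kwargs.update({k: v for k, v in overrides.items() if v is not None and k in names})
    return cls(**kwargs)
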