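"""Precision/recall benchmarking of the caller against simulated truth.

Calls are matched to simulated insertions by coordinate intersection:
greedy, nearest-first, one-to-one within a matching window, optionally
requiring the called donor element to equal the truth donor.  Precision is
TP / (TP + FP) over all calls; recall is TP / (TP + FN) over all simulated
events.  ``run_depth_sweep`` and ``run_vaf_sweep`` reproduce the two
benchmark axes: depths {15..150}x downsampled from one 150x base simulation
at 50 % VAF, and VAFs {10,20,40,50}% each simulated at the base depth.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import CallerParams, InsertionCall, call_insertions
from .catalog import (
    BinIndex,
    GapTrack,
    SourceElement,
    TransducedRegion,
    build_bin_index,
    chrom_lengths_of,
    derive_transduced_regions,
)
from .evidence import ScanParams
from .simulator import (
    SimParams,
    SimulatedGenome,
    SimulatedInsertion,
    downsample,
    emplace_insertions,
    generate_transduction_library,
    select_insertion_sites,
    simulate_reads,
)

log = logging.getLogger(__name__)


@dataclass
class MatchParams:
    """Coordinate-intersection matching: a call and a truth event may pair
    when their positions lie within ``window_bp`` (default 500, about one
    insert size, covering discordant-only breakpoint uncertainty) and, if
    ``require_element_match``, the donor elements agree."""

    window_bp: int = 500
    require_element_match: bool = True

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be >= 0")


@dataclass
class BenchmarkResult:
    vaf: float
    depth: float
    tp: int
    fp: int
    fn: int
    precision: float | None  # None when no calls were made
    recall: float
    matched_pairs: list[tuple[InsertionCall, SimulatedInsertion]] = field(
        default_factory=list
    )


def match_calls(
    calls: Sequence[InsertionCall],
    truth: Sequence[SimulatedInsertion],
    params: MatchParams | None = None,
) -> tuple[int, int, int, list[tuple[InsertionCall, SimulatedInsertion]]]:
    """Greedy nearest-first one-to-one matching of calls to truth.

    Candidate (call, truth) pairs within the window are sorted by breakpoint
    distance (ties by call then truth order) and accepted while both sides
    are unused.  Unmatched calls count as FP, unmatched truths as FN.
    """
    params = params or MatchParams()
    cands: list[tuple[int, int, int]] = []
    for ci, call in enumerate(calls):
        mid = (call.bp_low + call.bp_high) // 2
        for ti, tr in enumerate(truth):
            if call.chrom != tr.chrom:
                continue
            if params.require_element_match and call.element_id != tr.element_id:
                continue
            dist = min(
                abs(mid - tr.pos), abs(call.bp_low - tr.pos), abs(call.bp_high - tr.pos)
            )
            if dist <= params.window_bp:
                cands.append((dist, ci, ti))
    cands.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[InsertionCall, SimulatedInsertion]] = []
    for _, ci, ti in cands:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        pairs.append((calls[ci], truth[ti]))
    tp = len(pairs)
    fp = len(calls) - tp
    fn = len(truth) - tp
    return tp, fp, fn, pairs


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """(precision, recall); a zero denominator yields None, not NaN."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return precision, recall


@dataclass
class SweepConfig:
    """Scaled-down benchmark conditions (genome built by tdscan.synth)."""

    n_insertions: int = 150
    sim: SimParams = field(default_factory=SimParams)
    caller: CallerParams = field(default_factory=CallerParams)
    scan: ScanParams = field(default_factory=ScanParams)
    match: MatchParams = field(default_factory=MatchParams)


def _prepare(
    reference: dict[str, str],
    catalog: Sequence[SourceElement],
    gaps: GapTrack,
    cfg: SweepConfig,
    seed: int,
) -> tuple[SimulatedGenome, list[TransducedRegion], BinIndex]:
    rng = np.random.default_rng(seed)
    lengths = chrom_lengths_of(reference)
    regions = derive_transduced_regions(catalog, lengths)
    bins = build_bin_index(regions, lengths, cfg.sim.bin_size_bp)
    library = generate_transduction_library(catalog, reference, cfg.sim, rng)
    sites = select_insertion_sites(lengths, gaps, cfg.n_insertions, cfg.sim, rng)
    simg = emplace_insertions(
        reference, sites, library, regions, cfg.sim, rng, seed=seed
    )
    return simg, regions, bins


def _call_bam(
    bam: str,
    reference: dict[str, str],
    catalog: Sequence[SourceElement],
    regions: Sequence[TransducedRegion],
    bins: BinIndex,
    cfg: SweepConfig,
) -> list[InsertionCall]:
    return call_insertions(
        bam,
        reference,
        catalog,
        regions,
        bins,
        params=cfg.caller,
        scan_params=cfg.scan,
    )


def run_depth_sweep(
    reference: dict[str, str],
    catalog: Sequence[SourceElement],
    gaps: GapTrack,
    seed: int,
    cfg: SweepConfig | None = None,
    workdir: str | None = None,
    vaf: float = 0.5,
) -> pd.DataFrame:
    """Depth series at fixed VAF: one base simulation at ``base_depth``,
    downsampled to every depth in ``cfg.sim.depths``, called, and matched."""
    cfg = cfg or SweepConfig()
    own_tmp = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="tdscan_bench_")
    os.makedirs(workdir, exist_ok=True)
    rng = np.random.default_rng(seed + 1)
    simg, regions, bins = _prepare(reference, catalog, gaps, cfg, seed)
    base = simulate_reads(
        simg, vaf, cfg.sim.base_depth, rng,
        out_prefix=os.path.join(workdir, "base"),
        regions=regions, capture=True,
    )
    rows = []
    for depth in cfg.sim.depths:
        if depth == cfg.sim.base_depth:
            bam = base
        else:
            bam = downsample(
                base, os.path.join(workdir, f"d{depth}.bam"),
                depth, cfg.sim.base_depth, seed=seed + depth,
            )
        calls = _call_bam(bam, simg.original, catalog, regions, bins, cfg)
        tp, fp, fn, _ = match_calls(calls, simg.insertions, cfg.match)
        precision, recall = precision_recall(tp, fp, fn)
        rows.append(dict(vaf=vaf, depth=depth, tp=tp, fp=fp, fn=fn,
                         precision=precision, recall=recall))
        log.info("depth %dx: tp=%d fp=%d fn=%d", depth, tp, fp, fn)
    df = pd.DataFrame(rows)
    if own_tmp:
        import shutil

        shutil.rmtree(workdir, ignore_errors=True)
    return df


def run_vaf_sweep(
    reference: dict[str, str],
    catalog: Sequence[SourceElement],
    gaps: GapTrack,
    seed: int,
    cfg: SweepConfig | None = None,
    workdir: str | None = None,
    depth: float | None = None,
) -> pd.DataFrame:
    """VAF series at a fixed depth (defaults to the base depth): the same
    insertion-bearing genome is sequenced once per VAF, called, matched."""
    cfg = cfg or SweepConfig()
    own_tmp = workdir is None
    workdir = workdir or tempfile.mkdtemp(prefix="tdscan_bench_")
    os.makedirs(workdir, exist_ok=True)
    depth = depth if depth is not None else cfg.sim.base_depth
    simg, regions, bins = _prepare(reference, catalog, gaps, cfg, seed)
    rows = []
    for vaf in cfg.sim.vafs:
        rng = np.random.default_rng(seed + int(round(vaf * 1000)))
        bam = simulate_reads(
            simg, vaf, depth, rng,
            out_prefix=os.path.join(workdir, f"v{int(vaf * 100)}"),
            regions=regions, capture=True,
        )
        calls = _call_bam(bam, simg.original, catalog, regions, bins, cfg)
        tp, fp, fn, _ = match_calls(calls, simg.insertions, cfg.match)
        precision, recall = precision_recall(tp, fp, fn)
        rows.append(dict(vaf=vaf, depth=depth, tp=tp, fp=fp, fn=fn,
                         precision=precision, recall=recall))
        log.info("vaf %.0f%%: tp=%d fp=%d fn=%d", vaf * 100, tp, fp, fn)
    df = pd.DataFrame(rows)
    if own_tmp:
        import shutil

        shutil.rmtree(workdir, ignore_errors=True)
    return df
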