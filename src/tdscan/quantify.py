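"""Per-sample L1 activation scoring and cohort summaries.

The count of PASS orphan-transduction (TD2) calls in a sample is an indirect
readout of total L1 activity.  To remove coverage-related bias the
activation score divides that count by the sample's median on-target depth;
total L1 activity is extrapolated from the TD2 count with the published
1:6.33 TD2-to-total ratio.  Cohort-level helpers tabulate activation by
tumor stage, compare groups with a Wilcoxon rank-sum test, and annotate
calls with overlapping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import stats

from .caller import TD2, InsertionCall
from .catalog import TransducedRegion

log = logging.getLogger(__name__)

#: published ratio of total L1 insertions to orphan transductions (y = 6.33 x)
DEFAULT_SLOPE = 6.33


@dataclass
class ActivationProfile:
    sample_id: str
    n_td2: int
    median_cov: float
    activation_score: float | None  # None when coverage is zero
    est_total_l1: float
    per_element: dict[str, int] = field(default_factory=dict)

    @property
    def active(self) -> bool:
        return self.n_td2 > 0


def median_target_coverage(bam_path: str, regions: Sequence[TransducedRegion]) -> float:
    """Median per-base depth over the union of transduced regions.

    Requires an indexed BAM.  Returns 0 (with a warning) when no on-target
    reads exist; the activation score is then undefined.
    """
    depths: list[np.ndarray] = []
    with pysam.AlignmentFile(bam_path) as af:
        for reg in regions:
            if reg.end <= reg.start:
                continue
            cov = af.count_coverage(
                reg.chrom, reg.start, reg.end, quality_threshold=0
            )
            depths.append(np.sum(cov, axis=0))
    if not depths:
        return 0.0
    allcov = np.concatenate(depths)
    med = float(np.median(allcov))
    if med == 0:
        log.warning("%s: no on-target coverage; activation score undefined", bam_path)
    return med


def activation_score(n_td2: int, median_cov: float) -> float | None:
    """TD2 count divided by median on-target coverage; None when coverage 0."""
    if median_cov <= 0:
        return None
    return n_td2 / median_cov


def extrapolate_total_activation(n_td2: int, slope: float = DEFAULT_SLOPE) -> float:
    """Estimated total somatic L1 insertions from the TD2 count."""
    if n_td2 < 0:
        raise ValueError("n_td2 must be >= 0")
    return slope * n_td2


def build_profile(
    sample_id: str,
    calls: Sequence[InsertionCall],
    bam_path: str | None,
    regions: Sequence[TransducedRegion],
    slope: float = DEFAULT_SLOPE,
    median_cov: float | None = None,
) -> ActivationProfile:
    """Assemble the per-sample activation profile from PASS TD2 calls."""
    td2 = [c for c in calls if c.td_type == TD2]
    per_element: dict[str, int] = {}
    for c in td2:
        per_element[c.element_id] = per_element.get(c.element_id, 0) + 1
    if median_cov is None:
        median_cov = median_target_coverage(bam_path, regions) if bam_path else 0.0
    return ActivationProfile(
        sample_id=sample_id,
        n_td2=len(td2),
        median_cov=median_cov,
        activation_score=activation_score(len(td2), median_cov),
        est_total_l1=extrapolate_total_activation(len(td2), slope),
        per_element=per_element,
    )


def tabulate_cohort(
    active_flags: Mapping[str, bool], stage_labels: Mapping[str, str | None]
) -> pd.DataFrame:
    """Stage x active/inactive contingency table with percentages.

    Samples with no stage label (None/NA) are excluded from the staged rows
    but reported in an extra "NA" row.  Returns a DataFrame indexed by stage
    with columns active, inactive, n, pct_active.
    """
    rows: dict[str, list[int]] = {}
    for sample, flag in active_flags.items():
        stage = stage_labels.get(sample)
        stage = "NA" if stage in (None, "", "NA") else str(stage)
        rows.setdefault(stage, [0, 0])[0 if flag else 1] += 1
    out = []
    for stage in sorted(rows):
        active, inactive = rows[stage]
        n = active + inactive
        out.append(
            dict(
                stage=stage,
                active=active,
                inactive=inactive,
                n=n,
                pct_active=100.0 * active / n if n else float("nan"),
            )
        )
    return pd.DataFrame(out).set_index("stage")


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with midrank ties.

    Exact null distribution when both groups have <= 25 observations and the
    data are tie-free; otherwise the normal approximation with continuity
    correction.  Returns (U statistic of the first group, p-value).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def annotate_gene_overlap(
    calls_by_sample: Mapping[str, Sequence[InsertionCall]],
    genes: Sequence[tuple[str, int, int, str]],
) -> tuple[dict[int, list[str]], pd.DataFrame]:
    """Gene overlap per call and per-gene recurrence across samples.

    ``genes`` rows are (chrom, start, end, name), half-open.  A call overlaps
    a gene when its breakpoint interval (bp_low, bp_high + 1) intersects the
    gene interval.  Returns (call id -> gene names) keyed by ``id()`` order
    of iteration, and a recurrence table with the number of distinct samples
    holding >= 1 overlapping call per gene.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in genes:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    per_call: dict[int, list[str]] = {}
    gene_samples: dict[str, set[str]] = {}
    idx = 0
    for sample, calls in calls_by_sample.items():
        for call in calls:
            tree = trees.get(call.chrom)
            hits = (
                sorted({iv.data for iv in tree.overlap(call.bp_low, call.bp_high + 1)})
                if tree is not None
                else []
            )
            per_call[idx] = hits
            idx += 1
            for g in hits:
                gene_samples.setdefault(g, set()).add(sample)
    rec = pd.DataFrame(
        [
            dict(gene=g, n_samples=len(s), samples=",".join(sorted(s)))
            for g, s in sorted(gene_samples.items())
        ]
    )
    return per_call, rec


def group_stages(stage: str | None) -> str | None:
    """Early (T1-T2) vs advanced (T3-T4) stage grouping helper."""
    if stage in ("T1", "T2"):
        return "T1-T2"
    if stage in ("T3", "T4"):
        return "T3-T4"
    return None
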