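"""Simulator: library, site selection, emplacement, reads, capture, depth."""

import numpy as np
import pysam
import pytest
from scipy import stats

from tdscan._seq import revcomp
from tdscan.catalog import GapTrack, build_bin_index, derive_transduced_regions
from tdscan.simulator import (
    SimParams,
    capture_filter,
    downsample,
    emplace_insertions,
    generate_transduction_library,
    select_insertion_sites,
    simulate_reads,
)

PARAMS = SimParams(error_rate=0.0)


@pytest.fixture(scope="module")
def toy_parts(toy):
    regions = derive_transduced_regions(toy.catalog, toy.chrom_lengths)
    return toy.sequences, toy.catalog, regions, toy.gaps, toy.chrom_lengths


class TestLibrary:
    def test_counts_per_element(self, toy_parts):
        seqs, catalog, *_ = toy_parts
        rng = np.random.default_rng(1)
        lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
        assert len(lib) == 20 * len(catalog)
        ids = {t.element_id for t in lib}
        assert ids == {e.element_id for e in catalog}

    def test_trim_zero_equals_full_window(self, toy_parts):
        seqs, catalog, regions, *_ = toy_parts
        params = SimParams(n_per_element=1, min_td_len=5000)
        rng = np.random.default_rng(2)
        lib = generate_transduction_library(catalog, seqs, params, rng)
        reg = regions[0]
        td = next(t for t in lib if t.element_id == reg.element_id)
        window = seqs[reg.chrom][reg.start : reg.end].upper()
        if reg.orientation == "-":
            window = revcomp(window)
        assert td.trim_offset == 0 and td.seq == window

    def test_sequences_read_transcript_sense(self, toy_parts):
        """Every transduction is a prefix of its oriented window."""
        seqs, catalog, regions, *_ = toy_parts
        rng = np.random.default_rng(3)
        lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
        windows = {}
        for reg in regions:
            w = seqs[reg.chrom][reg.start : reg.end].upper()
            windows[reg.element_id] = revcomp(w) if reg.orientation == "-" else w
        for td in lib:
            assert windows[td.element_id].startswith(td.seq)
            assert td.length >= PARAMS.min_td_len

    def test_determinism(self, toy_parts):
        seqs, catalog, *_ = toy_parts
        a = generate_transduction_library(catalog, seqs, PARAMS, np.random.default_rng(9))
        b = generate_transduction_library(catalog, seqs, PARAMS, np.random.default_rng(9))
        assert a == b


class TestSites:
    def test_sites_avoid_gaps_and_mito(self, toy_parts):
        seqs, _, _, gaps, lengths = toy_parts
        rng = np.random.default_rng(4)
        sites = select_insertion_sites(lengths, gaps, 50, PARAMS, rng)
        assert len(sites) == 50
        for chrom, pos in sites:
            assert chrom != "chrM"
            assert not gaps.contains(chrom, pos)

    def test_one_site_per_bin(self, toy_parts):
        _, _, _, gaps, lengths = toy_parts
        rng = np.random.default_rng(5)
        sites = select_insertion_sites(lengths, gaps, 60, PARAMS, rng)
        bins = {(c, p // PARAMS.bin_size_bp) for c, p in sites}
        assert len(bins) == 60

    def test_fully_gapped_genome_forces_the_free_bin(self):
        lengths = {"c": 40_000}
        gaps = GapTrack([("c", 0, 20_000)])
        params = SimParams(end_margin=0)
        sites = select_insertion_sites(lengths, gaps, 2, params, np.random.default_rng(0))
        assert all(pos >= 20_000 for _, pos in sites)

    def test_too_many_sites_rejected(self):
        lengths = {"c": 40_000}
        with pytest.raises(ValueError, match="eligible"):
            select_insertion_sites(lengths, GapTrack(), 50, SimParams(end_margin=0),
                                   np.random.default_rng(0))

    def test_bin_sampling_uniform(self):
        """Bin frequencies on a 2-bin genome stay inside the binomial 99% CI."""
        lengths = {"c": 20_000}
        params = SimParams(end_margin=0)
        rng = np.random.default_rng(6)
        first = sum(
            select_insertion_sites(lengths, GapTrack(), 1, params, rng)[0][1] < 10_000
            for _ in range(10_000)
        )
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= first <= hi


@pytest.fixture(scope="module")
def simg(toy_parts):
    seqs, catalog, regions, gaps, lengths = toy_parts
    rng = np.random.default_rng(11)
    lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
    sites = select_insertion_sites(lengths, gaps, 25, PARAMS, rng)
    return emplace_insertions(seqs, sites, lib, regions, PARAMS, rng, seed=11)


class TestEmplacement:
    def test_length_arithmetic(self, simg):
        """Modified length = original + sum of insert + TSD lengths."""
        extra = {c: 0 for c in simg.original}
        for ins in simg.insertions:
            extra[ins.chrom] += ins.insert_len + ins.tsd_len
        for chrom in simg.original:
            assert len(simg.modified[chrom]) == len(simg.original[chrom]) + extra[chrom]

    def test_tsd_duplicated_around_insert(self, simg):
        """The tsd_len bases left of the site flank the insert on both sides."""
        by_chrom = {}
        for ins in simg.insertions:
            by_chrom.setdefault(ins.chrom, []).append(ins)
        for chrom, inss in by_chrom.items():
            offset = 0
            for ins in sorted(inss, key=lambda i: i.pos):
                m = ins.pos + offset
                mod = simg.modified[chrom]
                orig = simg.original[chrom]
                tsd = orig[ins.pos - ins.tsd_len : ins.pos]
                assert mod[m - ins.tsd_len : m] == tsd
                assert mod[m + ins.insert_len : m + ins.insert_len + ins.tsd_len] == tsd
                offset += ins.insert_len + ins.tsd_len

    def test_polya_at_transcript_three_prime(self, simg):
        by_chrom = {}
        for ins in simg.insertions:
            by_chrom.setdefault(ins.chrom, []).append(ins)
        for chrom, inss in by_chrom.items():
            offset = 0
            for ins in sorted(inss, key=lambda i: i.pos):
                m = ins.pos + offset
                insert = simg.modified[chrom][m : m + ins.insert_len]
                if ins.insert_strand == "+":
                    assert insert.endswith("A" * ins.polya_len)
                else:
                    assert insert.startswith("T" * ins.polya_len)
                offset += ins.insert_len + ins.tsd_len

    def test_insert_core_matches_donor_window(self, simg, toy_parts):
        """Lifting the emplaced transduction back to the donor region
        reproduces the reference sequence exactly (truth consistency)."""
        _, _, regions, _, _ = toy_parts
        reg_by_id = {r.element_id: r for r in regions}
        by_chrom = {}
        for ins in simg.insertions:
            by_chrom.setdefault(ins.chrom, []).append(ins)
        for chrom, inss in by_chrom.items():
            offset = 0
            for ins in sorted(inss, key=lambda i: i.pos):
                m = ins.pos + offset
                insert = simg.modified[chrom][m : m + ins.insert_len]
                core = (
                    insert[: ins.insert_len - ins.polya_len]
                    if ins.insert_strand == "+"
                    else revcomp(insert[ins.polya_len :])
                )
                reg = reg_by_id[ins.element_id]
                window = simg.original[reg.chrom][reg.start : reg.end]
                if reg.orientation == "-":
                    window = revcomp(window)
                expect = window[ins.trunc5_len : ins.trunc5_len + len(core)]
                assert core == expect
                offset += ins.insert_len + ins.tsd_len

    def test_truth_records_complete(self, simg):
        for ins in simg.insertions:
            assert 0 < ins.tsd_len and 0 < ins.polya_len
            assert ins.transduction_length >= PARAMS.min_td_len
            assert ins.insert_strand in "+-"


class TestReads:
    def test_coverage_arithmetic(self, toy_parts, tmp_path):
        """Total sequenced bases / genome length lands within 5% of target."""
        seqs, catalog, regions, gaps, lengths = toy_parts
        rng = np.random.default_rng(21)
        lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
        sites = select_insertion_sites(lengths, gaps, 5, PARAMS, rng)
        simg = emplace_insertions(seqs, sites, lib, regions, PARAMS, rng, seed=21)
        bam = simulate_reads(simg, 1.0, 20, rng, out_prefix=str(tmp_path / "cov"))
        total = sum(lengths.values())
        bases = 0
        with pysam.AlignmentFile(bam) as af:
            for r in af.fetch(until_eof=True):
                bases += r.query_length
        assert abs(bases / total - 20) / 20 < 0.05

    def test_vaf_fraction_at_breakpoints(self, toy_parts, tmp_path):
        """At deep coverage, the fraction of junction-spanning reads that
        carry the insert (soft-clipped) is binomially consistent with VAF."""
        seqs, catalog, regions, gaps, lengths = toy_parts
        rng = np.random.default_rng(22)
        lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
        sites = select_insertion_sites(lengths, gaps, 8, PARAMS, rng)
        simg = emplace_insertions(seqs, sites, lib, regions, PARAMS, rng, seed=22)
        vaf = 0.5
        bam = simulate_reads(simg, vaf, 80, rng, out_prefix=str(tmp_path / "vaf"))
        # condition on reads whose left-junction crossing lies 25-75 bp from
        # the read's right end: such reads always anchor in the flank, so
        # carrier status (right soft clip at the junction) is Bernoulli(vaf)
        carrier = spanning = 0
        with pysam.AlignmentFile(bam) as af:
            for ins in simg.insertions:
                for r in af.fetch(ins.chrom, max(ins.pos - 200, 0), ins.pos + 200):
                    if r.is_unmapped or r.reference_start is None:
                        continue
                    cig = r.cigartuples
                    right_clip = cig[-1][1] if cig[-1][0] == 4 else 0
                    left_clip = cig[0][1] if cig[0][0] == 4 else 0
                    if right_clip and left_clip:
                        continue
                    if right_clip and r.reference_end == ins.pos and 25 <= right_clip <= 75:
                        carrier += 1
                        spanning += 1
                    elif (
                        not right_clip
                        and not left_clip
                        and r.reference_start < ins.pos
                        and 25 <= r.reference_end - ins.pos <= 75
                    ):
                        spanning += 1
        assert spanning > 100
        lo, hi = stats.binom.interval(0.999, spanning, vaf)
        assert lo <= carrier <= hi

    def test_aligned_records_match_reference(self, toy_parts, tmp_path):
        """Matched blocks of emitted alignments reproduce the reference
        sequence base-for-base (no sequencing errors injected)."""
        seqs, catalog, regions, gaps, lengths = toy_parts
        rng = np.random.default_rng(23)
        lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
        sites = select_insertion_sites(lengths, gaps, 5, PARAMS, rng)
        simg = emplace_insertions(seqs, sites, lib, regions, PARAMS, rng, seed=23)
        bam = simulate_reads(simg, 0.5, 4, rng, out_prefix=str(tmp_path / "ref"))
        n = 0
        with pysam.AlignmentFile(bam) as af:
            for r in af.fetch(until_eof=True):
                if r.is_unmapped:
                    continue
                qstart = r.query_alignment_start
                qend = r.query_alignment_end
                ref = seqs[r.reference_name][r.reference_start : r.reference_end].upper()
                assert r.query_sequence[qstart:qend] == ref
                n += 1
        assert n > 1000

    def test_fastq_mode_round_trip(self, toy_parts, tmp_path):
        seqs, catalog, regions, gaps, lengths = toy_parts
        rng = np.random.default_rng(24)
        lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
        sites = select_insertion_sites(lengths, gaps, 3, PARAMS, rng)
        simg = emplace_insertions(seqs, sites, lib, regions, PARAMS, rng, seed=24)
        p1, p2 = simulate_reads(simg, 0.5, 2, rng, out_prefix=str(tmp_path / "fq"),
                                mode="fastq")
        lines1 = open(p1).read().splitlines()
        lines2 = open(p2).read().splitlines()
        assert len(lines1) == len(lines2) and len(lines1) % 4 == 0
        assert lines1[0].startswith("@sim") and lines1[0].endswith("/1")
        assert all(len(l) == PARAMS.read_len for l in lines1[1::4])


@pytest.fixture(scope="module")
def small_bam(toy_parts, tmp_path_factory):
    seqs, catalog, regions, gaps, lengths = toy_parts
    rng = np.random.default_rng(31)
    lib = generate_transduction_library(catalog, seqs, PARAMS, rng)
    sites = select_insertion_sites(lengths, gaps, 5, PARAMS, rng)
    simg = emplace_insertions(seqs, sites, lib, regions, PARAMS, rng, seed=31)
    out = tmp_path_factory.mktemp("cap")
    bam = simulate_reads(simg, 0.5, 8, rng, out_prefix=str(out / "all"))
    return bam, regions, out


class TestCaptureAndDepth:
    def test_capture_filter_matches_brute_force(self, small_bam):
        bam, regions, out = small_bam
        kept = capture_filter(bam, regions, str(out / "cap.bam"))
        with pysam.AlignmentFile(bam) as af:
            mates = {}
            for r in af.fetch(until_eof=True):
                if r.is_unmapped:
                    continue
                mates.setdefault(r.query_name, []).append(
                    (r.reference_name, r.reference_start, r.reference_end)
                )
        expect = {
            name
            for name, spans in mates.items()
            if any(
                reg.chrom == c and s < reg.end and reg.start < e
                for c, s, e in spans
                for reg in regions
            )
        }
        with pysam.AlignmentFile(kept) as af:
            got = {r.query_name for r in af.fetch(until_eof=True)}
        assert got == expect

    def test_capture_mode_equals_post_hoc_filter(self, toy_parts, tmp_path):
        """simulate_reads(capture=True) is the composition of full simulation
        and capture_filter (same seed, same pairs)."""
        seqs, catalog, regions, gaps, lengths = toy_parts
        lib = generate_transduction_library(catalog, seqs, PARAMS, np.random.default_rng(33))
        sites = select_insertion_sites(lengths, gaps, 4, PARAMS, np.random.default_rng(33))
        simg = emplace_insertions(seqs, sites, lib, regions, PARAMS,
                                  np.random.default_rng(33), seed=33)
        full = simulate_reads(simg, 0.5, 6, np.random.default_rng(99),
                              out_prefix=str(tmp_path / "full"))
        cap = simulate_reads(simg, 0.5, 6, np.random.default_rng(99),
                             out_prefix=str(tmp_path / "cap"),
                             regions=regions, capture=True)
        posthoc = capture_filter(full, regions, str(tmp_path / "ph.bam"))
        def names(path):
            with pysam.AlignmentFile(path) as af:
                return sorted(r.query_name for r in af.fetch(until_eof=True))
        assert names(cap) == names(posthoc)

    def test_downsample_binomial_and_pair_coherent(self, small_bam):
        bam, _, out = small_bam
        ds = downsample(bam, str(out / "ds.bam"), 2, 8, seed=5)
        with pysam.AlignmentFile(bam) as af:
            total_pairs = len({r.query_name for r in af.fetch(until_eof=True)})
        with pysam.AlignmentFile(ds) as af:
            by_name = {}
            for r in af.fetch(until_eof=True):
                by_name.setdefault(r.query_name, 0)
                by_name[r.query_name] += 1
        with pysam.AlignmentFile(bam) as af:
            full_counts = {}
            for r in af.fetch(until_eof=True):
                full_counts.setdefault(r.query_name, 0)
                full_counts[r.query_name] += 1
        # pair coherence: every kept name keeps all its records
        for name, n in by_name.items():
            assert n == full_counts[name]
        lo, hi = stats.binom.interval(0.999, total_pairs, 0.25)
        assert lo <= len(by_name) <= hi

    def test_downsample_identity_and_bounds(self, small_bam):
        bam, _, out = small_bam
        same = downsample(bam, str(out / "id.bam"), 8, 8, seed=1)
        with pysam.AlignmentFile(bam) as a, pysam.AlignmentFile(same) as b:
            assert sum(1 for _ in a.fetch(until_eof=True)) == sum(
                1 for _ in b.fetch(until_eof=True)
            )
        with pytest.raises(ValueError):
            downsample(bam, str(out / "x.bam"), 9, 8)
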