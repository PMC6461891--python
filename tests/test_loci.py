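import pytest

from conftest import locus_matches_planted
from nmsrna.io import (
    Feature,
    GenomeAnnotation,
    LibraryInfo,
    LibraryManifest,
    ReadInterval,
    SequenceRecord,
)
from nmsrna.loci import (
    LocusParams,
    build_coverage,
    call_loci,
    classify_overlaps,
    infer_cap_status,
    SRNALocus,
)


def _ann(length=2000, features=()):
    return GenomeAnnotation(
        sequences={"c": SequenceRecord("c", "ACGU" * (length // 4))},
        features=list(features),
    )


def _reads(intervals, chrom="c", strand="+"):
    return [ReadInterval(chrom, strand, s, e, n) for s, e, n in intervals]


def _peak(start, end, n_reads=5, count=1):
    """n_reads stacked reads across [start, end)."""
    return [(start, end, count)] * n_reads


class TestBuildCoverage:
    def test_single_read_depth(self):
        cov = build_coverage({"l1": _reads([(10, 20, 3)])}, _ann())
        d = cov.depth_matrix("c", "+")[0]
        assert d[10] == 3 and d[19] == 3 and d[9] == 0 and d[20] == 0

    def test_overlapping_reads_sum(self):
        cov = build_coverage({"l1": _reads([(10, 20, 1), (15, 25, 2)])}, _ann())
        d = cov.depth_matrix("c", "+")[0]
        assert d[12] == 1 and d[17] == 3 and d[22] == 2

    def test_empty_read_set_all_zero(self):
        cov = build_coverage({"l1": []}, _ann())
        assert cov.pooled("c", "+").sum() == 0
        assert cov.pooled("c", "-").sum() == 0

    def test_out_of_bounds_read_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_coverage({"l1": _reads([(1990, 2010, 1)])}, _ann())

    def test_strands_kept_separate(self):
        cov = build_coverage(
            {"l1": _reads([(10, 20, 1)]) + _reads([(10, 20, 4)], strand="-")}, _ann()
        )
        assert cov.depth_matrix("c", "+")[0, 15] == 1
        assert cov.depth_matrix("c", "-")[0, 15] == 4


class TestCallLoci:
    def _four_lib_reads(self, interval=(100, 140)):
        s, e = interval
        return {f"l{i}": _reads(_peak(s, e)) for i in range(1, 5)}

    def test_supported_intergenic_peak_called(self):
        cov = build_coverage(self._four_lib_reads(), _ann())
        (locus,) = call_loci(cov, _ann())
        assert (locus.start, locus.end) == (100, 140)
        assert locus.peak_depth == 20

    def test_zero_reads_in_one_library_vetoes(self):
        reads = self._four_lib_reads()
        reads["l4"] = []
        cov = build_coverage(reads, _ann())
        assert call_loci(cov, _ann()) == []

    def test_low_support_in_one_library_vetoes(self):
        reads = self._four_lib_reads()
        reads["l4"] = _reads(_peak(100, 140, n_reads=2))
        cov = build_coverage(reads, _ann())
        assert call_loci(cov, _ann()) == []

    def test_peak_inside_cds_discarded_overlap_kept(self):
        # fully inside a CDS: no locus
        ann = _ann(features=[Feature("g", "c", "+", 50, 300, "CDS")])
        cov = build_coverage(self._four_lib_reads(), ann)
        assert call_loci(cov, ann) == []
        # overlapping a CDS by 20 nt at the 3' end: locus with overlap3=20
        ann = _ann(features=[Feature("g", "c", "+", 120, 300, "CDS")])
        cov = build_coverage(self._four_lib_reads(), ann)
        (locus,) = call_loci(cov, ann)
        assert locus.overlap3 == 20 and locus.overlap5 == 0

    def test_any_rrna_overlap_discards(self):
        ann = _ann(features=[Feature("r", "c", "+", 139, 300, "rRNA")])
        cov = build_coverage(self._four_lib_reads(), ann)
        assert call_loci(cov, ann) == []

    def test_short_runs_dropped(self):
        cov = build_coverage(self._four_lib_reads((100, 110)), _ann())
        assert call_loci(cov, _ann()) == []  # 10 nt < min_locus_len 16

    def test_gap_merging(self):
        reads = {
            f"l{i}": _reads(_peak(100, 130) + _peak(133, 160))  # 3-nt gap <= gap_max
            for i in range(1, 5)
        }
        cov = build_coverage(reads, _ann())
        (locus,) = call_loci(cov, _ann())
        assert (locus.start, locus.end) == (100, 160)

    def test_depth_min_monotonicity_on_peaky_coverage(self, sim42):
        """On peak-shaped coverage, raising depth_min never increases the
        number of called loci. (This can fail on multi-modal plateaus, where a
        higher threshold splits one run in two; expression peaks are unimodal
        enough that the monotone behaviour is the relevant contract.)"""
        cov = build_coverage(sim42.reads, sim42.annotation)
        n_prev = None
        for depth_min in (1, 3, 10, 50, 200, 800):
            n = len(call_loci(cov, sim42.annotation, LocusParams(depth_min=depth_min)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_called_loci_disjoint_and_retention_recheckable(self, sim42):
        cov = build_coverage(sim42.reads, sim42.annotation)
        params = LocusParams()
        called = call_loci(cov, sim42.annotation, params)
        by_strand: dict[str, list] = {}
        for l in called:
            by_strand.setdefault(l.strand, []).append(l)
            assert len(l) >= params.min_locus_len
            for lib in cov.libraries:
                assert (
                    cov.library_reads_on(lib, l.chrom, l.strand, l.start, l.end)
                    >= params.support_min
                )
        for strand, ls in by_strand.items():
            ls = sorted(ls, key=lambda l: l.start)
            assert all(a.end <= b.start for a, b in zip(ls, ls[1:]))

    def test_recovery_on_default_synthetic_dataset(self, sim42):
        """Planted-truth recovery at seed 42: recall >= 0.90, precision >= 0.80."""
        cov = build_coverage(sim42.reads, sim42.annotation)
        called = call_loci(cov, sim42.annotation)
        expressed = sim42.truth.expressed()
        recall = sum(
            any(locus_matches_planted(l, p) for l in called) for p in expressed
        ) / len(expressed)
        precision = sum(
            any(locus_matches_planted(l, p) for p in expressed) for l in called
        ) / len(called)
        assert recall >= 0.90
        assert precision >= 0.80

    def test_silent_pseudogene_not_called(self, sim42):
        cov = build_coverage(sim42.reads, sim42.annotation)
        called = call_loci(cov, sim42.annotation)
        (pseudo,) = sim42.truth.by_class("pseudogene")
        assert not any(locus_matches_planted(l, pseudo) for l in called)


class TestClassifyOverlaps:
    def test_plus_strand_three_prime_overlap(self):
        ann = _ann(features=[Feature("g", "c", "+", 180, 400, "CDS")])
        l = SRNALocus("x", "c", "+", 100, 200, 10)
        classify_overlaps(l, ann)
        assert (l.overlap5, l.overlap3) == (0, 20)

    def test_minus_strand_flips_orientation(self):
        ann = _ann(features=[Feature("g", "c", "+", 180, 400, "CDS")])
        l = SRNALocus("x", "c", "-", 100, 200, 10)
        classify_overlaps(l, ann)
        assert (l.overlap5, l.overlap3) == (20, 0)

    def test_no_overlap(self):
        l = SRNALocus("x", "c", "+", 100, 200, 10)
        classify_overlaps(l, _ann())
        assert (l.overlap5, l.overlap3) == (0, 0)


class TestCapStatus:
    def _setup(self, te_reads):
        reads = {
            "l1": _reads(_peak(100, 140, 10)),
            "te": te_reads,
        }
        manifest = LibraryManifest(
            [
                LibraryInfo("l1", "light", 1, False),
                LibraryInfo("te", "light", 1, True),
            ]
        )
        ann = _ann()
        cov = build_coverage(reads, ann)
        locus = SRNALocus("x", "c", "+", 100, 140, 10)
        return locus, cov, manifest

    def test_equal_normalized_signal_is_capped_like(self):
        locus, cov, manifest = self._setup(_reads(_peak(100, 140, 10)))
        assert infer_cap_status(locus, cov, manifest) == "capped-like"

    def test_zero_te_signal_is_monophosphate_like(self):
        # TE library keeps its size via off-locus reads, none on the locus
        locus, cov, manifest = self._setup(_reads(_peak(500, 540, 10)))
        assert infer_cap_status(locus, cov, manifest) == "monophosphate-like"

    def test_missing_te_library_is_ambiguous_with_warning(self):
        reads = {"l1": _reads(_peak(100, 140, 10))}
        manifest = LibraryManifest([LibraryInfo("l1", "light", 1, False)])
        cov = build_coverage(reads, _ann())
        locus = SRNALocus("x", "c", "+", 100, 140, 10)
        with pytest.warns(UserWarning, match="TE-treated"):
            assert infer_cap_status(locus, cov, manifest) == "ambiguous"
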