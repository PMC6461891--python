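import numpy as np
import pytest

from nmsrna.io import reverse_complement
from nmsrna.motifs import WC_PAIRS
from nmsrna.synth import (
    LibrarySpec,
    SimulationConfig,
    SimulationSizeError,
    SyntheticTruth,
    generate_genome,
    simulate_libraries,
    write_dataset,
)

SMALL = dict(genome_length=30_000, n_cds=15, n_snorna=3, n_orphan=2)


class TestGenerateGenome:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=7, **SMALL)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_dataset(d1, cfg)
        p2 = write_dataset(d2, cfg)
        for key in ("genome", "gff", "truth", "targets"):
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
        for lib in cfg.libraries:
            assert (d1 / f"reads_{lib.id}.bed").read_bytes() == (
                d2 / f"reads_{lib.id}.bed"
            ).read_bytes()

    def test_single_snorna_truth_self_consistent(self):
        cfg = SimulationConfig(seed=3, genome_length=20_000, n_cds=8,
                               n_snorna=1, snrna_kinds=(), n_orphan=0)
        _, truth = generate_genome(cfg)
        (sno,) = truth.by_class("snoRNA")
        assert len(sno.guides) >= 1
        for g in sno.guides:
            target = truth.targets[g.target_id]
            guide = sno.sequence[g.rel_start : g.rel_end]
            # the +5 rule applied to the planted guide recovers the position
            assert g.methyl_pos == g.target_start + 4
            assert reverse_complement(guide) == target[g.target_start : g.target_end]
            assert (guide[len(guide) - 5], target[g.methyl_pos]) in WC_PAIRS

    def test_plus5_self_consistency_across_seeds(self):
        for seed in (1, 2, 11):
            cfg = SimulationConfig(seed=seed, **SMALL)
            _, truth = generate_genome(cfg)
            for sno in truth.by_class("snoRNA"):
                for g in sno.guides:
                    guide = sno.sequence[g.rel_start : g.rel_end]
                    assert (
                        guide[len(guide) - 5],
                        truth.targets[g.target_id][g.methyl_pos],
                    ) in WC_PAIRS

    def test_too_small_genome_raises_sizing_error(self):
        with pytest.raises(SimulationSizeError):
            generate_genome(SimulationConfig(seed=1, genome_length=1_000, n_cds=80))

    def test_planted_features_inside_genome_and_disjoint(self, sim42):
        loci = sorted(sim42.truth.loci, key=lambda l: l.start)
        glen = sim42.config.genome_length
        for l in loci:
            assert 0 <= l.start < l.end <= glen
        for a, b in zip(loci, loci[1:]):
            assert a.end <= b.start

    def test_genomic_sequence_matches_truth(self, sim42):
        for l in sim42.truth.loci:
            assert (
                sim42.annotation.subsequence(l.chrom, l.start, l.end, l.strand)
                == l.sequence
            )

    def test_some_planted_loci_overlap_flanking_cds(self, sim42):
        """A configurable fraction of sRNAs overlap a neighbouring CDS by
        13-43 nt; overlaps are mostly at the 3' end."""
        n_overlap = 0
        for l in sim42.truth.loci:
            if l.sclass == "pseudogene":
                continue
            for f in sim42.annotation.overlapping(l.chrom, l.start, l.end, ("CDS",)):
                ov = min(f.end, l.end) - max(f.start, l.start)
                assert 13 <= ov <= 43
                n_overlap += 1
        assert n_overlap >= 3

    def test_truth_json_round_trip(self, tmp_path, sim42):
        p = tmp_path / "truth.json"
        sim42.truth.to_json(p)
        back = SyntheticTruth.from_json(p)
        assert back.chrom == sim42.truth.chrom
        assert back.targets == sim42.truth.targets
        assert len(back.loci) == len(sim42.truth.loci)
        for a, b in zip(back.loci, sim42.truth.loci):
            assert (a.id, a.start, a.end, a.sequence, a.boxes, a.guides) == (
                b.id, b.start, b.end, b.sequence, b.boxes, b.guides
            )


class TestSimulateLibraries:
    def test_te_retention_pass_through(self):
        """Mean TE-library counts approach retention x untreated mean."""
        cfg = SimulationConfig(seed=5, **SMALL)
        ann, truth = generate_genome(cfg)
        sums = {"capped": [0.0, 0.0], "monophosphate": [0.0, 0.0]}  # te, untreated
        n_sims = 60
        for i in range(n_sims):
            rng = np.random.default_rng([5, 50 + i])
            reads = simulate_libraries(ann, truth, cfg, rng=rng)
            for l in truth.expressed():
                if l.expression != "constitutive":
                    continue
                te = sum(
                    r.count for r in reads["te_1"]
                    if r.strand == l.strand and r.start < l.end and r.end > l.start
                )
                un = sum(
                    r.count for r in reads["light_1"]
                    if r.strand == l.strand and r.start < l.end and r.end > l.start
                )
                sums[l.cap][0] += te
                sums[l.cap][1] += un
        r_capped = sums["capped"][0] / sums["capped"][1]
        r_mono = sums["monophosphate"][0] / sums["monophosphate"][1]
        assert abs(r_capped - cfg.te_capped_retention) < 0.1
        assert abs(r_mono - cfg.te_monop_retention) < 0.05

    def test_zero_dispersion_counts_converge_to_means(self):
        """With dispersion -> 0 the mean per-locus count over many loci is
        within 5% of the configured mean."""
        cfg = SimulationConfig(
            seed=9, genome_length=100_000, n_cds=10, n_snorna=20,
            snrna_kinds=(), n_orphan=5, dispersion=0.0, noise_depth=0.0,
            libraries=[LibrarySpec("light_1", "light", 1)],
        )
        ann, truth = generate_genome(cfg)
        reads = simulate_libraries(ann, truth, cfg)
        counts = []
        for l in truth.expressed():
            if l.expression != "constitutive":
                continue
            counts.append(
                sum(
                    r.count for r in reads["light_1"]
                    if r.strand == l.strand and r.start < l.end and r.end > l.start
                )
            )
        assert len(counts) >= 24
        assert abs(np.mean(counts) - cfg.mean_depth) / cfg.mean_depth < 0.05

    def test_dark_induction_ratio_in_zero_dispersion_limit(self):
        cfg = SimulationConfig(seed=9, dispersion=1e-9, noise_depth=0.0, **SMALL)
        ann, truth = generate_genome(cfg)
        (dark_locus,) = [l for l in truth.loci if l.expression == "dark_induced"]
        ratios = []
        for i in range(10):
            rng = np.random.default_rng([9, i])
            reads = simulate_libraries(ann, truth, cfg, rng=rng)
            def count(lib):
                return sum(
                    r.count for r in reads[lib]
                    if r.strand == dark_locus.strand
                    and r.start < dark_locus.end and r.end > dark_locus.start
                )
            ratios.append(count("dark_1") / count("light_1"))
        assert abs(np.mean(ratios) - cfg.dark_induced_fold) < 0.5

    def test_locus_reads_are_subintervals(self, sim42):
        """Locus-derived reads never cross a planted locus boundary: for each
        expressed locus, boundary-crossing read mass is negligible (only
        uniform background noise can straddle an edge)."""
        for l in sim42.truth.expressed():
            inside = crossing = 0
            for lib, reads in sim42.reads.items():
                for r in reads:
                    if r.strand != l.strand or r.end <= l.start or r.start >= l.end:
                        continue
                    if r.start >= l.start and r.end <= l.end:
                        inside += r.count
                    else:
                        crossing += r.count
            assert inside > 0
            assert crossing <= max(2, 0.02 * inside), l.id

    def test_silent_locus_gets_no_reads(self, sim42):
        (pseudo,) = sim42.truth.by_class("pseudogene")
        for lib, reads in sim42.reads.items():
            n = sum(
                r.count for r in reads
                if r.strand == pseudo.strand
                and r.start >= pseudo.start and r.end <= pseudo.end
            )
            assert n <= 2  # at most stray background noise
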