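import numpy as np
import pandas as pd
import pytest

from nmsrna.io import SequenceRecord, reverse_complement
from nmsrna.methyl import (
    DuplexParams,
    PositionMap,
    call_conserved_and_homologs,
    find_guide_duplex,
    guide_identity,
    predict_sites,
)
from nmsrna.motifs import WC_PAIRS
from nmsrna.snorna import assemble_cd_candidates
from oracles import oracle_duplex_windows, random_rna


def _target(seq: str, tid: str = "T") -> SequenceRecord:
    return SequenceRecord(tid, seq)


class TestFindGuideDuplex:
    def test_perfect_complement_single_window(self):
        rng = np.random.default_rng(0)
        t = random_rna(rng, 60)
        guide = reverse_complement(t[10:22])
        hits = find_guide_duplex(guide, _target(t))
        exact = [d for d in hits if (d.target_start, d.target_end) == (10, 22)]
        assert len(exact) == 1
        assert exact[0].wc_count == 12 and exact[0].mismatch_count == 0

    def test_gu_pair_retained(self):
        # build a target whose window pairs the guide with exactly one G-U
        t = "CCCCC" + "AGCAGCAGCAGU" + "CCCCC"
        guide = reverse_complement(t[5:17])          # perfect guide
        assert (guide[0], t[16]) == ("A", "U")
        mutated = "G" + guide[1:]                    # A->G creates G.U vs target U
        hits = find_guide_duplex(mutated, _target(t))
        hit = next(d for d in hits if d.target_start == 5)
        assert hit.gu_count == 1 and hit.mismatch_count == 0

    def test_short_guide_rejected(self):
        with pytest.raises(ValueError, match=">= 9"):
            find_guide_duplex("ACGUACGU", _target("ACGU" * 10))

    def test_plus5_pair_must_be_watson_crick(self):
        rng = np.random.default_rng(1)
        t = random_rna(rng, 40)
        guide = reverse_complement(t[8:20])
        # break the +5 pair (guide offset 5 from the box = index L-5)
        g5 = guide[len(guide) - 5]
        swap = {"A": "C", "C": "A", "G": "A", "U": "C"}[g5]
        broken = guide[: len(guide) - 5] + swap + guide[len(guide) - 4 :]
        hits = find_guide_duplex(broken, _target(t), DuplexParams(min_pairs=10, max_mismatch=2))
        assert all(d.target_start != 8 for d in hits)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_windows_oracle(self, seed):
        rng = np.random.default_rng(10 + seed)
        for _ in range(25):
            t = random_rna(rng, int(rng.integers(30, 120)))
            L = int(rng.integers(9, 16))
            if rng.random() < 0.5:
                s = int(rng.integers(0, len(t) - L))
                guide = reverse_complement(t[s : s + L])
                k = int(rng.integers(0, L))
                guide = guide[:k] + random_rna(rng, 1) + guide[k + 1 :]
            else:
                guide = random_rna(rng, L)
            params = DuplexParams(min_pairs=L - 1, max_mismatch=1, max_gu=2)
            got = {
                (d.target_start, d.wc_count, d.gu_count, d.mismatch_count)
                for d in find_guide_duplex(guide, _target(t), params)
            }
            want = set(oracle_duplex_windows(guide, t, L - 1, 1, 2))
            assert got == want


class TestPredictSites:
    def test_site_is_plus5_of_window_start(self):
        t = "CCCCCCCCCC" + "AGCAGCAGCAGC" + "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC"
        guide = reverse_complement(t[10:22])
        assert "UGA" not in guide
        (cand,) = assemble_cd_candidates(
            "AA" + "AUGAUGA" + "CAACCAACCAAC" + "UUGA" + "ACCAC" + "UUGA"
            + guide + "CUGA" + "AC"
        )
        sites = predict_sites(cand, [_target(t)])
        d_sites = [s for s in sites if s.box_kind == "D" and s.target_id == "T"]
        assert any(s.position == 14 for s in d_sites)  # window [10,22) -> 10+4

    def test_planted_truth_recovered(self, sim42):
        targets = sim42.truth.target_records()
        for planted in sim42.truth.by_class("snoRNA"):
            (cand,) = assemble_cd_candidates(planted.sequence, planted.id)
            got = {(s.box_kind, s.target_id, s.position) for s in predict_sites(cand, targets)}
            for g in planted.guides:
                assert (g.box_kind, g.target_id, g.methyl_pos) in got

    def test_shifting_guide_shifts_site_by_one(self):
        rng = np.random.default_rng(3)
        t = random_rna(rng, 80)
        for s in (20, 19):  # windows one nt apart
            guide = reverse_complement(t[s : s + 12])
            hits = find_guide_duplex(guide, _target(t))
            positions = {d.target_start + 4 for d in hits if d.target_start == s}
            assert positions == {s + 4}

    def test_plus5_invariant_on_all_emitted_sites(self, pipeline42):
        """Every reported site pairs the guide's +5 base Watson-Crick."""
        assert pipeline42.sites, "pipeline emitted no methylation sites"
        for s in pipeline42.sites:
            g = s.duplex.guide
            assert (g[len(g) - 5], s.residue) in WC_PAIRS
            assert s.duplex.target_start <= s.position < s.duplex.target_end

    def test_no_sites_against_snrnas_without_planted_guides(self, sim42):
        """Guides planted against rRNA predict nothing on the snRNA set."""
        snrna_targets = [
            SequenceRecord(f"snRNA_{k}", seq) for k, seq in sim42.truth.snrna_seqs.items()
        ]
        n = 0
        for planted in sim42.truth.by_class("snoRNA"):
            (cand,) = assemble_cd_candidates(planted.sequence, planted.id)
            n += len(predict_sites(cand, snrna_targets))
        assert n == 0


class TestPositionMap:
    def test_identity_alignment(self):
        pm = PositionMap([SequenceRecord("a", "ACGU"), SequenceRecord("b", "ACGU")])
        for i in range(4):
            assert pm.map_position("a", i, "b") == i

    def test_gap_in_target_returns_none(self):
        pm = PositionMap([SequenceRecord("a", "ACGU"), SequenceRecord("b", "AC-U")])
        assert pm.map_position("a", 2, "b") is None

    def test_hand_computed_column_bookkeeping(self):
        # "AC-GU" vs "ACUGU": seq1 pos 2 is G in column 3 -> seq2 pos 3
        pm = PositionMap([SequenceRecord("s1", "AC-GU"), SequenceRecord("s2", "ACUGU")])
        assert pm.map_position("s1", 2, "s2") == 3

    def test_round_trip_when_ungapped(self):
        rng = np.random.default_rng(4)
        raw = random_rna(rng, 50)
        rows = []
        for sid in ("a", "b"):
            s = list(raw)
            for pos in sorted(rng.integers(0, 50, 6), reverse=True):
                s.insert(int(pos), "-")
            rows.append(SequenceRecord(sid, "".join(s)))
        pm = PositionMap(rows)
        for pos in range(50):
            mapped = pm.map_position("a", pos, "b")
            if mapped is not None:
                assert pm.map_position("b", mapped, "a") == pos

    def test_out_of_range_rejected(self):
        pm = PositionMap([SequenceRecord("a", "ACGU")])
        with pytest.raises(IndexError):
            pm.column_of("a", 10)


class TestConservedAndHomologs:
    def _setup(self, sim42):
        # one alignment per rRNA, each with a reference species row identical
        # to the nucleomorph sequence
        targets = sim42.truth.target_records()
        maps = [
            PositionMap(
                [
                    SequenceRecord(t.id, t.residues),
                    SequenceRecord(f"ref_{t.id}", t.residues),
                ]
            )
            for t in targets
        ]
        return targets, maps

    def test_truth_built_reference_all_conserved(self, sim42):
        targets, pm = self._setup(sim42)
        planted = sim42.truth.by_class("snoRNA")
        rows, sites = [], []
        for p in planted:
            (cand,) = assemble_cd_candidates(p.sequence, p.id)
            for s in predict_sites(cand, targets):
                sites.append(s)
            for g in p.guides:
                rows.append(
                    {
                        "species": "refsp", "rna": f"ref_{g.target_id}",
                        "position": g.methyl_pos + 1, "snoRNA": f"REF_{p.id}",
                        "guide": p.sequence[g.rel_start : g.rel_end],
                    }
                )
        # map nucleomorph sites onto the reference rows via the alignment:
        # reference ids differ, so point each site at its ref_<rna> row
        ref = pd.DataFrame(rows)
        calls = call_conserved_and_homologs(sites, ref, pm)
        planted_keys = {(f"{g.target_id}", g.methyl_pos) for p in planted for g in p.guides}
        conserved = {
            (c.site.target_id, c.site.position) for c in calls if c.conserved
        }
        assert planted_keys <= conserved
        # identical guides -> homolog flag set on the planted calls
        assert all(
            c.homolog for c in calls
            if c.conserved and (c.site.target_id, c.site.position) in planted_keys
        )

    def test_different_column_not_conserved(self):
        pm = PositionMap(
            [SequenceRecord("nm", "ACGUACGUAC"), SequenceRecord("hs", "ACGUACGUAC")]
        )
        t = SequenceRecord("nm", "ACGUACGUAC")
        guide = reverse_complement(t.residues[0:9]) + "AAA"  # any 12-nt guide
        ref = pd.DataFrame(
            [{"species": "human", "rna": "hs", "position": 9, "snoRNA": "SNORDX"}]
        )
        from nmsrna.methyl import GuideDuplex, MethylationSite

        dup = GuideDuplex("s", "D", guide, "nm", 0, 12, "|" * 12, 12, 0, 0)
        site = MethylationSite("nm", 4, t.residues[4], "nm-A5", "s", "D", dup)
        (call,) = call_conserved_and_homologs([site], ref, pm)
        assert not call.conserved and not call.homolog

    def test_low_guide_identity_blocks_homolog_flag(self):
        pm = PositionMap(
            [SequenceRecord("nm", "ACGUACGUAC"), SequenceRecord("hs", "ACGUACGUAC")]
        )
        from nmsrna.methyl import GuideDuplex, MethylationSite

        dup = GuideDuplex("s", "D", "ACGUACGUACGU", "nm", 0, 12, "|" * 12, 12, 0, 0)
        site = MethylationSite("nm", 4, "A", "nm-A5", "s", "D", dup)
        ref = pd.DataFrame(
            [
                {
                    "species": "human", "rna": "hs", "position": 5,
                    "snoRNA": "SNORDX", "guide": "UUUUUUACGUAC"[:6] + "UUUUUU",
                }
            ]
        )
        (call,) = call_conserved_and_homologs([site], ref, pm)
        assert call.conserved
        assert call.guide_identity is not None and call.guide_identity < 0.7
        assert not call.homolog

    def test_guide_identity_is_three_prime_anchored(self):
        assert guide_identity("AAACGUACGUAC", "CGUACGUAC") == 1.0
        assert guide_identity("AAAAAA", "CCCCCC") == 0.0
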