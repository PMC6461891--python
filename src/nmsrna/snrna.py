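"""Rule-based evaluation of sRNA loci as spliceosomal snRNA candidates.

Each snRNA kind is scored against the sequence elements that define it in
highly reduced genomes:

* U1 -- the 5' splice-site recognition sequence (ACUUAC, the perfect reverse
  complement of the GUAAGU donor site) within the first few nucleotides;
* U2 -- a branch-point interaction motif (GUAG class) in the 5' half plus at
  least two intermolecular helices with U6;
* U4 -- two intermolecular helices with U6 separated by a spacer that folds
  into a hairpin (the 5' stem-loop);
* U5 -- the invariant loop I motif (UGCCUUUUACY) closed by a flanking stem;
* U6 -- the 5' splice-site binding sequence ACAGAGA plus a 3' U-tract
  (Lsm-binding).

An Sm/Lsm-site motif is searched in the 3' third of every candidate and
reported, but never vetoes a candidate (its consensus is weakly defined).
Intron branch points are predicted from the DURAU motif near the 3' splice
site by bulging out an adenosine so that the remaining bases pair the U2
branch-point interaction region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import reverse_complement
from .motifs import (
    PAIRS,
    DegeneratePattern,
    PatternMatch,
    find_hairpin_stem,
    search_pattern,
)

SNRNA_KINDS = ("U1", "U2", "U4", "U5", "U6")


@dataclass
class HelixInteraction:
    """A maximal contiguous antiparallel pairing run between two RNAs."""

    a_id: str
    a_start: int
    a_end: int
    b_id: str
    b_start: int
    b_end: int
    length: int
    wc_count: int
    gu_count: int


def find_intermolecular_helices(
    rna_a: str,
    rna_b: str,
    min_len: int = 6,
    *,
    a_id: str = "A",
    b_id: str = "B",
) -> list[HelixInteraction]:
    """All maximal antiparallel contiguous pairing runs (Watson-Crick plus G-U)
    of length >= ``min_len`` between two sequences.

    A run pairs ``rna_a[i+k]`` with ``rna_b[j-k]`` for k = 0..L-1; runs are
    enumerated along the anti-diagonals of the pairing matrix.
    """
    a = rna_a.upper().replace("T", "U")
    b = rna_b.upper().replace("T", "U")
    la, lb = len(a), len(b)
    out: list[HelixInteraction] = []
    for c in range(la + lb - 1):  # c = i + j
        i_lo = max(0, c - lb + 1)
        i_hi = min(la - 1, c)
        run = 0
        for i in range(i_lo, i_hi + 2):
            paired = i <= i_hi and (a[i], b[c - i]) in PAIRS
            if paired:
                run += 1
            else:
                if run >= min_len:
                    i0 = i - run
                    j0 = c - i0  # b index paired with a[i0]
                    wc = sum(
                        (a[i0 + k], b[j0 - k]) in (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"))
                        for k in range(run)
                    )
                    out.append(
                        HelixInteraction(
                            a_id, i0, i0 + run,
                            b_id, j0 - run + 1, j0 + 1,
                            run, wc, run - wc,
                        )
                    )
                run = 0
    return out


@dataclass
class RuleOutcome:
    passed: bool
    mandatory: bool
    detail: str = ""


@dataclass
class SnRNAReport:
    locus_id: str
    kind: str
    rules: dict[str, RuleOutcome]
    helices: list[HelixInteraction] = field(default_factory=list)
    hairpin_stem: int = 0
    sm_site: PatternMatch | None = None
    verdict: bool = False
    reasons: list[str] = field(default_factory=list)


@dataclass
class SnRNAParams:
    """Per-kind rule tunables."""

    u1_window: int = 12          # 5'SS-binding motif must start within this window
    u1_mm: int = 0
    u2_bp_motif: str = "GUAG"
    u2_min_helices: int = 2
    helix_min_len: int = 6
    # the U4/U6 helices are long in vivo (helix I ~11 bp, helix II up to 16 bp),
    # so the U4 call demands longer contiguous pairing than the generic scan
    u4_helix_min_len: int = 9
    u4_min_stem: int = 5
    u4_min_loop: int = 3
    u5_loop_motif: str = "UGCCUUUUACY"
    u5_mm: int = 6
    u5_stem_min: int = 4
    u6_motif: str = "ACAGAGA"
    u6_utract_min: int = 4       # U count in the last u6_utract_window nt
    u6_utract_window: int = 10
    sm_site_motifs: tuple[str, ...] = ("RAUUUUG", "RAUUUUUG", "RAUUUUUUG")


U1_5SS_BINDING = "ACUUAC"  # reverse complement of the GUAAGU donor consensus


def _flanking_stem(seq: str, loop_start: int, loop_end: int) -> int:
    """Length of the stem closing seq[loop_start:loop_end): pairs
    (loop_start-1-k, loop_end+k) extending outward."""
    k = 0
    while (
        loop_start - 1 - k >= 0
        and loop_end + k < len(seq)
        and (seq[loop_start - 1 - k], seq[loop_end + k]) in PAIRS
    ):
        k += 1
    return k


def _helix_pairs_with_hairpin(
    seq: str, helices: list[HelixInteraction], min_stem: int, min_loop: int
) -> tuple[bool, int, tuple[HelixInteraction, HelixInteraction] | None]:
    """Whether any ordered pair of U6-helices on the candidate brackets a
    spacer folding into a hairpin."""
    best = (False, 0, None)
    ordered = sorted(helices, key=lambda h: h.a_start)
    for x in range(len(ordered)):
        for y in range(x + 1, len(ordered)):
            h1, h2 = ordered[x], ordered[y]
            if h1.a_end > h2.a_start:
                continue
            spacer = seq[h1.a_end : h2.a_start]
            stem = find_hairpin_stem(spacer, min_stem=min_stem, min_loop=min_loop)
            if stem >= min_stem:
                return True, stem, (h1, h2)
    return best


def evaluate_snrna_candidate(
    sequence: str,
    kind: str,
    u6_sequence: str | None = None,
    params: SnRNAParams | None = None,
    *,
    locus_id: str = "locus",
) -> SnRNAReport:
    """Evaluate a sequence against the mandatory rules for one snRNA kind.

    ``u6_sequence`` is required for kinds U2 and U4 (their identity rests on
    intermolecular pairing with U6). The verdict is True iff every mandatory
    rule for the kind passes; the Sm/Lsm-site search is always reported but
    never mandatory.
    """
    if kind not in SNRNA_KINDS:
        raise ValueError(f"unknown snRNA kind {kind!r}")
    p = params or SnRNAParams()
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    rules: dict[str, RuleOutcome] = {}
    helices: list[HelixInteraction] = []
    hairpin_stem = 0

    if kind in ("U2", "U4"):
        if u6_sequence is None:
            raise ValueError(f"{kind} evaluation requires a U6 sequence")
        min_len = p.u4_helix_min_len if kind == "U4" else p.helix_min_len
        helices = find_intermolecular_helices(
            seq, u6_sequence, min_len, a_id=locus_id, b_id="U6"
        )

    if kind == "U1":
        hits = [
            m
            for m in search_pattern(seq, DegeneratePattern(U1_5SS_BINDING, p.u1_mm))
            if m.start < p.u1_window
        ]
        rules["u1_5ss_binding"] = RuleOutcome(
            bool(hits), True,
            f"{U1_5SS_BINDING} (revcomp of donor {reverse_complement(U1_5SS_BINDING)}) "
            + (f"at {hits[0].start}" if hits else "not found in 5' window"),
        )
    elif kind == "U2":
        bp = [
            m
            for m in search_pattern(seq, DegeneratePattern(p.u2_bp_motif))
            if m.end <= n // 2
        ]
        rules["u2_bp_interaction"] = RuleOutcome(
            bool(bp), True,
            f"{p.u2_bp_motif} in 5' half" + ("" if bp else " not found"),
        )
        rules["u2_u6_helices"] = RuleOutcome(
            len(helices) >= p.u2_min_helices, True,
            f"{len(helices)} helix(es) of >= {p.helix_min_len} bp with U6",
        )
    elif kind == "U4":
        ok2 = len(helices) >= 2
        rules["u4_u6_helices"] = RuleOutcome(
            ok2, True, f"{len(helices)} helix(es) of >= {p.u4_helix_min_len} bp with U6"
        )
        has_hp = False
        if ok2:
            has_hp, hairpin_stem, _pair = _helix_pairs_with_hairpin(
                seq, helices, p.u4_min_stem, p.u4_min_loop
            )
        rules["u4_interhelix_hairpin"] = RuleOutcome(
            has_hp, True,
            f"5' stem-loop of {hairpin_stem} bp between the U6 helices"
            if has_hp else "no hairpin between the two U6-pairing regions",
        )
        # descriptive only: sheared-G.A-capable juxtapositions near the stem
        ga = seq.count("GA")
        rules["u4_kturn_like"] = RuleOutcome(
            ga >= 2, False, f"{ga} G.A-capable juxtapositions (descriptive)"
        )
    elif kind == "U5":
        loops = search_pattern(
            seq, DegeneratePattern(p.u5_loop_motif, max_mismatch=p.u5_mm)
        )
        stem_ok = False
        best_stem = 0
        for m in loops:
            stem = _flanking_stem(seq, m.start, m.end)
            best_stem = max(best_stem, stem)
            if stem >= p.u5_stem_min:
                stem_ok = True
        rules["u5_loop1"] = RuleOutcome(
            bool(loops), True,
            f"{len(loops)} loop I motif hit(s) (<= {p.u5_mm} mismatches)",
        )
        rules["u5_loop1_stem"] = RuleOutcome(
            stem_ok, True,
            f"flanking stem of {best_stem} bp" if loops else "no loop to flank",
        )
    elif kind == "U6":
        has_motif = bool(search_pattern(seq, DegeneratePattern(p.u6_motif)))
        rules["u6_5ss_binding"] = RuleOutcome(
            has_motif, True,
            f"{p.u6_motif} present" if has_motif else f"{p.u6_motif} absent",
        )
        tail = seq[-p.u6_utract_window:]
        u_count = tail.count("U")
        rules["u6_lsm_utract"] = RuleOutcome(
            u_count >= p.u6_utract_min, True,
            f"{u_count} U in the last {p.u6_utract_window} nt",
        )

    # Sm/Lsm site in the 3' third -- reported, never mandatory
    third = seq[2 * n // 3 :]
    sm_hit: PatternMatch | None = None
    for motif in p.sm_site_motifs:
        hits = search_pattern(third, DegeneratePattern(motif))
        if hits:
            m = hits[0]
            sm_hit = PatternMatch(
                locus_id, "+", m.start + 2 * n // 3, m.end + 2 * n // 3,
                m.mismatches, m.insertions, m.deletions, m.matched,
            )
            break
    rules["sm_site"] = RuleOutcome(
        sm_hit is not None, False,
        "Sm/Lsm-like site found" if sm_hit else "no Sm/Lsm-like site",
    )

    mandatory_failed = [k for k, r in rules.items() if r.mandatory and not r.passed]
    return SnRNAReport(
        locus_id=locus_id, kind=kind, rules=rules,
        helices=helices, hairpin_stem=hairpin_stem, sm_site=sm_hit,
        verdict=not mandatory_failed, reasons=mandatory_failed,
    )


# ---------------------------------------------------------------------------
# branch point prediction
# ---------------------------------------------------------------------------

@dataclass
class BranchPointCall:
    intron_id: str
    motif_start: int
    motif_end: int
    branch_position: int   # 0-based position of the bulged adenosine
    paired_u2_region: str


def count_introns_with_branch_motif(
    introns: list[str],
    motif_pattern: str = "DURAU",
    *,
    dist_min: int = 2,
    dist_max: int = 6,
) -> int:
    """How many introns carry the branch-point motif with its 3' end
    ``dist_min``-``dist_max`` nt upstream of the 3' splice site."""
    n = 0
    for intron in introns:
        seq = intron.upper().replace("T", "U")
        hits = search_pattern(seq, DegeneratePattern(motif_pattern))
        if any(dist_min <= len(seq) - m.end <= dist_max for m in hits):
            n += 1
    return n


def predict_branch_point(
    intron_sequence: str,
    u2_bp_region: str,
    motif_pattern: str = "DURAU",
    *,
    fallback_pattern: str = "YURAC",
    intron_id: str = "intron",
    dist_min: int = 2,
    dist_max: int = 6,
) -> BranchPointCall | None:
    """Predict the branch adenosine of an intron from its 3'-proximal motif.

    Scans for the motif whose 3' end lies ``dist_min``-``dist_max`` nt upstream
    of the intron 3' splice site. For each occurrence, a window anchored at the
    motif 3' end (up to one base longer than the U2 branch-point interaction
    region) is tested: the branch A is an adenosine inside the motif whose
    removal leaves the remaining bases exactly reverse-complementary to a
    contiguous stretch of the U2 region. The 3'-most valid call is returned.
    """
    seq = intron_sequence.upper().replace("T", "U")
    u2 = u2_bp_region.upper().replace("T", "U")
    if len(seq) < len(motif_pattern) + dist_min:
        return None
    if not seq.endswith("AG"):
        raise ValueError("intron must end with the AG 3' splice site")

    u2_rc_subs: dict[int, set[str]] = {}

    def _rc_substrings(k: int) -> set[str]:
        if k not in u2_rc_subs:
            u2_rc_subs[k] = {
                reverse_complement(u2[i : i + k]) for i in range(len(u2) - k + 1)
            }
        return u2_rc_subs[k]

    for pattern in (motif_pattern, fallback_pattern):
        occs = [
            m
            for m in search_pattern(seq, DegeneratePattern(pattern))
            if dist_min <= len(seq) - m.end <= dist_max
        ]
        for m in sorted(occs, key=lambda m: -m.end):  # 3'-most motif first
            wlen = min(len(u2) + 1, m.end)
            wstart = m.end - wlen
            window = seq[wstart : m.end]
            # try 3'-most adenosine inside the motif first
            for g in range(m.end - 1, m.start - 1, -1):
                if seq[g] != "A":
                    continue
                rel = g - wstart
                remaining = window[:rel] + window[rel + 1 :]
                if not remaining:
                    continue
                if remaining in _rc_substrings(len(remaining)):
                    return BranchPointCall(
                        intron_id, m.start, m.end, g, u2,
                    )
    return None
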