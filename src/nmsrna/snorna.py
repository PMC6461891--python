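"""C/D box snoRNA detection: box motif location, K-turn pairing validation,
and guide-window extraction.

A box C/D snoRNA carries a C box (consensus RUGAUGA) near its 5' end and a
D box (CUGA) near its 3' end; the two fold back on each other into a kink-turn
(K-turn) whose signature is a tandem of sheared G.A base pairs at the base of
stem II. Internal D' and C' boxes may form a second, K-loop-like element. The
sequence immediately 5' of each D/D' box is the methylation guide, antisense
to the target RNA.

K-turn register
---------------
With 1-based indexing from each motif's 5' end, the C and D boxes pair
antiparallel as (C3,D4), (C4,D3), (C5,D2), (C6,D1). The two sheared pairs are
G(C3).A(D4) and A(C4).G(D3); C5-D2 is the noncanonical U-U pair of the
canonical boxes (a Watson-Crick A-U works equally); C6-D1 is the terminal
Watson-Crick pair closing stem II (G-C canonically, any Watson-Crick
combination is compensatory). A 7th C-box nucleotide, when present, is bulged
and unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import DegeneratePattern, WC_PAIRS, search_pattern

#: default box motif sets; the noncanonical C entries cover observed
#: compensatory variants (AUGAUU pairs its terminal U with a D-box 5' A;
#: GUGAAG replaces the U-U pair with Watson-Crick A-U and has a 5' purine G).
DEFAULT_MOTIF_SETS: dict[str, tuple[str, ...]] = {
    "C": ("RUGAUGA", "AUGAUG", "AUGAUGA", "AUGAUU", "GUGAAG"),
    "D": ("CUGA", "AUGA"),
    "C'": ("UUGA", "AUGA"),
    "D'": ("UUGA", "AUGA"),
}


@dataclass
class BoxMotif:
    kind: str  # C, D, C', D'
    sequence: str
    start: int
    end: int
    consensus_id: str  # which motif-set entry matched


@dataclass
class KTurnReport:
    pairs: list[tuple[str, str, str]]  # (C base, D base, class) over the register
    sheared_ga_count: int
    pair_c5d2: str  # WC / UU / other
    pair_c6d1: str  # WC / other
    valid: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class GuideWindow:
    start: int
    end: int
    sequence: str


@dataclass
class CDSnoRNACandidate:
    locus_id: str
    sequence: str
    box_c: BoxMotif
    box_d: BoxMotif
    box_dprime: BoxMotif | None
    box_cprime: BoxMotif | None
    kturn: KTurnReport
    guide_d: GuideWindow | None
    guide_dprime: GuideWindow | None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def guides(self) -> list[tuple[str, GuideWindow]]:
        out = []
        if self.guide_d is not None:
            out.append(("D", self.guide_d))
        if self.guide_dprime is not None:
            out.append(("D'", self.guide_dprime))
        return out


@dataclass
class CDParams:
    """Tunables for candidate assembly (all artifact-level conventions)."""

    terminal_margin: int = 12     # C box must start / D box must end this close to the ends
    min_length: int = 50
    max_length: int = 250
    guide_max: int = 20           # guide window, truncated at the nearest upstream box
    dprime_cprime_spacing: tuple[int, int] = (2, 12)
    motif_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_SETS)
    )


def find_boxes(
    sequence: str, motif_sets: dict[str, tuple[str, ...]] | None = None
) -> list[BoxMotif]:
    """All occurrences of all box-set members in ``sequence`` (exact degenerate
    matches, no edit budgets), labelled by kind and consensus entry."""
    sets = motif_sets if motif_sets is not None else DEFAULT_MOTIF_SETS
    boxes: list[BoxMotif] = []
    for kind, motifs in sets.items():
        for motif in motifs:
            for m in search_pattern(sequence, DegeneratePattern(motif)):
                boxes.append(BoxMotif(kind, m.matched, m.start, m.end, motif))
    boxes.sort(key=lambda b: (b.start, b.kind, -len(b.sequence)))
    return boxes


def _pair_class(c_base: str, d_base: str) -> str:
    if (c_base, d_base) in WC_PAIRS:
        return "WC"
    if c_base == "U" and d_base == "U":
        return "UU"
    return "other"


def validate_kturn(c_box_seq: str, d_box_seq: str) -> KTurnReport:
    """Apply the K-turn pairing register to a C box (6 or 7 nt) and D box (4 nt).

    Validity requires both sheared pairs in the canonical orientation
    (G at C3 with A at D4; A at C4 with G at D3), a Watson-Crick pair at
    C6-D1, and either Watson-Crick or U-U at C5-D2.
    """
    c = c_box_seq.upper().replace("T", "U")
    d = d_box_seq.upper().replace("T", "U")
    if len(c) not in (6, 7):
        raise ValueError(f"C box must be 6 or 7 nt, got {len(c)}")
    if len(d) != 4:
        raise ValueError(f"D box must be 4 nt, got {len(d)}")

    notes: list[str] = []
    if len(c) == 7:
        notes.append("7th C-box nucleotide treated as bulged/unpaired")
    if c[0] == "G":
        notes.append("C box 5' purine G (eukaryotic consensus)")

    sheared = 0
    pairs: list[tuple[str, str, str]] = []
    # (C3, D4) and (C4, D3): sheared G.A pairs, fixed orientation
    for (ci, di, want_c) in ((2, 3, "G"), (3, 2, "A")):
        ok = (c[ci] == want_c) and ({c[ci], d[di]} == {"G", "A"})
        sheared += int(ok)
        pairs.append((c[ci], d[di], "sheared-GA" if ok else "other"))

    c5d2 = _pair_class(c[4], d[1])
    pairs.append((c[4], d[1], c5d2))
    if c5d2 == "WC":
        notes.append("Watson-Crick pair replaces U-U at the base of stem II")

    c6d1 = "WC" if (c[5], d[0]) in WC_PAIRS else "other"
    pairs.append((c[5], d[0], c6d1))
    if c6d1 == "WC" and (c[5], d[0]) != ("G", "C"):
        notes.append("compensatory Watson-Crick pair at C6-D1")

    valid = sheared == 2 and c6d1 == "WC" and c5d2 in ("WC", "UU")
    return KTurnReport(pairs, sheared, c5d2, c6d1, valid, notes)


def assemble_cd_candidates(
    locus_sequence: str,
    locus_id: str = "locus",
    params: CDParams | None = None,
) -> list[CDSnoRNACandidate]:
    """Assemble C/D box snoRNA candidates from a locus sequence.

    Requires a C box starting within ``terminal_margin`` of the 5' end, a
    D box ending within ``terminal_margin`` of the 3' end, a valid K-turn
    between them, and a total length within bounds. Internal D' (with a C'
    2-12 nt downstream) is optional. Guides are the up-to-``guide_max`` nt
    immediately 5' of D and D', truncated at the nearest upstream box.
    Returns at most one candidate per locus.
    """
    p = params or CDParams()
    seq = locus_sequence.upper().replace("T", "U")
    n = len(seq)
    if not (p.min_length <= n <= p.max_length):
        return []
    boxes = find_boxes(seq, p.motif_sets)

    c_cands = [b for b in boxes if b.kind == "C" and b.start < p.terminal_margin]
    d_cands = [b for b in boxes if b.kind == "D" and b.end >= n - p.terminal_margin]
    # earliest C, then latest/longest D
    c_cands.sort(key=lambda b: (b.start, -len(b.sequence)))
    d_cands.sort(key=lambda b: (-b.end, b.start))

    chosen: tuple[BoxMotif, BoxMotif, KTurnReport] | None = None
    for c in c_cands:
        for d in d_cands:
            if c.end + 1 > d.start:  # need at least 1 nt of guide room
                continue
            kt = validate_kturn(c.sequence, d.sequence)
            if kt.valid:
                chosen = (c, d, kt)
                break
        if chosen:
            break
    if chosen is None:
        return []
    c, d, kt = chosen

    # optional internal D'/C' pair between the C and D boxes
    lo, hi = p.dprime_cprime_spacing
    dprime = cprime = None
    internals = [
        b for b in boxes
        if b.kind == "D'" and b.start > c.end and b.end < d.start
    ]
    cprimes = [
        b for b in boxes
        if b.kind == "C'" and b.end < d.start
    ]
    for dp in sorted(internals, key=lambda b: b.start):
        for cp in sorted(cprimes, key=lambda b: b.start):
            gap = cp.start - dp.end
            if lo <= gap <= hi:
                dprime, cprime = dp, cp
                break
        if dprime:
            break

    def _guide(box_start: int, upstream_end: int) -> GuideWindow | None:
        gs = max(box_start - p.guide_max, upstream_end)
        if gs >= box_start:
            return None
        return GuideWindow(gs, box_start, seq[gs:box_start])

    prev_end = cprime.end if cprime else (dprime.end if dprime else c.end)
    guide_d = _guide(d.start, prev_end)
    guide_dp = _guide(dprime.start, c.end) if dprime else None

    cand = CDSnoRNACandidate(
        locus_id=locus_id, sequence=seq,
        box_c=c, box_d=d, box_dprime=dprime, box_cprime=cprime,
        kturn=kt, guide_d=guide_d, guide_dprime=guide_dp,
    )
    return [cand]
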