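"""Degenerate pattern matching with independent mismatch/insertion/deletion
budgets, plus the composite two-helix-with-hairpin search used for U4 snRNA.

The matcher aligns an IUPAC pattern against subject substrings. The three edit
budgets are independent caps, not a summed edit distance:

* mismatch -- a subject base outside the IUPAC class of the pattern letter;
* insertion -- an extra subject base consumed by no pattern letter;
* deletion -- a pattern letter matched to no subject base.

A degenerate letter whose class contains the subject base costs nothing. For
each start position the single best alignment is reported (minimal
mismatches+insertions+deletions, ties broken by fewer indels, then by the
leftmost end); overlapping matches from different starts are all kept.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGURYSWKMBDHVN", "UGCAYRSWMKVHDBN")

#: allowed base pairs in helices/hairpins: Watson-Crick plus G-U wobble
PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)
WC_PAIRS = frozenset([("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")])


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (R<->Y, K<->M, B<->V, D<->H...)."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass
class DegeneratePattern:
    """An IUPAC pattern with independent mismatch/insertion/deletion budgets."""

    pattern: str
    max_mismatch: int = 0
    max_ins: int = 0
    max_del: int = 0

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper().replace("T", "U")
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) in pattern: {sorted(bad)}")
        if min(self.max_mismatch, self.max_ins, self.max_del) < 0:
            raise ValueError("budgets must be >= 0")

    def reverse_complement(self) -> "DegeneratePattern":
        return DegeneratePattern(
            reverse_complement_pattern(self.pattern),
            self.max_mismatch, self.max_ins, self.max_del,
        )


@dataclass
class PatternMatch:
    seq_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    insertions: int
    deletions: int
    matched: str

    @property
    def cost(self) -> int:
        return self.mismatches + self.insertions + self.deletions


def _dominates(a: tuple[int, int, int], b: tuple[int, int, int]) -> bool:
    return a[0] <= b[0] and a[1] <= b[1] and a[2] <= b[2]


def _align_from(
    subject: str, s: int, pattern: str, classes: list[frozenset[str]],
    bmm: int, bins: int, bdel: int,
) -> tuple[int, int, int, int] | None:
    """Best alignment of the whole pattern starting at subject position ``s``.

    Returns ``(end, mm, ins, dl)`` or None. Dynamic program over (pattern
    consumed, subject consumed) keeping Pareto-minimal budget triples.
    """
    plen = len(pattern)
    n = len(subject)
    # frontier[j] = set of Pareto triples with i pattern letters consumed
    frontier: dict[int, list[tuple[int, int, int]]] = {0: [(0, 0, 0)]}
    finals: list[tuple[int, int, int, int]] = []  # (end, mm, ins, dl)

    for i in range(plen):
        cls = classes[i]
        nxt: dict[int, list[tuple[int, int, int]]] = {}

        def _add(j: int, t: tuple[int, int, int]) -> None:
            bucket = nxt.setdefault(j, [])
            for u in bucket:
                if _dominates(u, t):
                    return
            bucket[:] = [u for u in bucket if not _dominates(t, u)] + [t]

        for j, triples in frontier.items():
            for (mm, ins, dl) in triples:
                # deletion: skip pattern letter
                if dl < bdel:
                    _add(j, (mm, ins, dl + 1))
                pos = s + j
                if pos < n:
                    base = subject[pos]
                    # match / mismatch
                    cost = 0 if base in cls else 1
                    if mm + cost <= bmm:
                        _add(j + 1, (mm + cost, ins, dl))
                    # insertion: consume subject base without the pattern letter
                    if ins < bins:
                        for jj in range(j + 1, min(j + 1 + (bins - ins), n - s + 1)):
                            # consume (jj - j) subject bases as insertions, then
                            # match this pattern letter at position s+jj
                            k = jj - j
                            pos2 = s + jj
                            if pos2 >= n:
                                break
                            cost2 = 0 if subject[pos2] in cls else 1
                            if mm + cost2 <= bmm:
                                _add(jj + 1, (mm + cost2, ins + k, dl))
        frontier = nxt
        if not frontier:
            return None

    for j, triples in frontier.items():
        for (mm, ins, dl) in triples:
            finals.append((s + j, mm, ins, dl))
    if not finals:
        return None
    # minimal total cost, then fewer indels, then leftmost end
    finals.sort(key=lambda t: (t[1] + t[2] + t[3], t[2] + t[3], t[0]))
    end, mm, ins, dl = finals[0]
    return end, mm, ins, dl


def search_pattern(
    subject: str,
    pattern: DegeneratePattern | str,
    *,
    seq_id: str = "seq",
    strand: str = "+",
) -> list[PatternMatch]:
    """All matches of ``pattern`` in ``subject`` within the edit budgets.

    Matches are anchored per start position: for every subject position where
    an alignment of the full pattern fits within the budgets, the best
    alignment from that start is reported.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern(pattern)
    subject = subject.upper().replace("T", "U")
    classes = [IUPAC[c] for c in pattern.pattern]
    plen = len(pattern.pattern)
    out: list[PatternMatch] = []
    n = len(subject)
    min_span = plen - pattern.max_del
    for s in range(n):
        if n - s < min_span:
            break
        res = _align_from(
            subject, s, pattern.pattern, classes,
            pattern.max_mismatch, pattern.max_ins, pattern.max_del,
        )
        if res is None:
            continue
        end, mm, ins, dl = res
        if end == s:  # whole pattern deleted: not a sequence match
            continue
        out.append(
            PatternMatch(seq_id, strand, s, end, mm, ins, dl, subject[s:end])
        )
    return out


# ---------------------------------------------------------------------------
# hairpins and the two-helix composite search
# ---------------------------------------------------------------------------

def find_hairpin_stem(seq: str, min_stem: int = 5, min_loop: int = 3) -> int:
    """Longest hairpin stem in ``seq``: two antiparallel substrings pairing
    base-by-base (Watson-Crick or G-U), separated by >= ``min_loop`` unpaired
    bases. Returns the stem length, or 0 if none reaches ``min_stem``.
    """
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            k = 0
            while (
                i + k < j - k
                and (j - k) - (i + k) - 1 >= min_loop
                and (seq[i + k], seq[j - k]) in PAIRS
            ):
                k += 1
            if k > best:
                best = k
    return best if best >= min_stem else 0


@dataclass
class TwoHelixHit:
    """A candidate carrying both U6-interaction helices with a hairpin between."""

    helix_a: PatternMatch  # 5'-most helix region on the candidate
    helix_b: PatternMatch  # 3'-most helix region
    spacer_start: int
    spacer_end: int
    stem_len: int
    labels: tuple[str, str] = ("helixII", "helixI")


def find_two_helix_candidates(
    subject: str,
    helix1: DegeneratePattern | str,
    helix2: DegeneratePattern | str,
    *,
    spacer_min: int = 20,
    spacer_max: int = 120,
    min_stem: int = 5,
    min_loop: int = 3,
    helix2_first: bool = True,
    seq_id: str = "seq",
    strand: str = "+",
) -> list[TwoHelixHit]:
    """Find regions able to pair with both given helices with a hairpin between.

    ``helix1``/``helix2`` are the interaction-partner sequences (e.g. the two
    U6-side helices); the subject is searched for their reverse complements.
    By default the helix-II-pairing region lies 5' of the helix-I-pairing
    region, matching U4/U6 architecture. Budgets apply per helix.
    """
    if isinstance(helix1, str):
        helix1 = DegeneratePattern(helix1)
    if isinstance(helix2, str):
        helix2 = DegeneratePattern(helix2)
    subject = subject.upper().replace("T", "U")
    m1 = search_pattern(subject, helix1.reverse_complement(), seq_id=seq_id, strand=strand)
    m2 = search_pattern(subject, helix2.reverse_complement(), seq_id=seq_id, strand=strand)
    first, second = (m2, m1) if helix2_first else (m1, m2)
    labels = ("helixII", "helixI") if helix2_first else ("helixI", "helixII")
    hits: list[TwoHelixHit] = []
    for a in first:
        for b in second:
            if a.end > b.start:
                continue
            spacer = subject[a.end : b.start]
            if not (spacer_min <= len(spacer) <= spacer_max):
                continue
            stem = find_hairpin_stem(spacer, min_stem=min_stem, min_loop=min_loop)
            if stem >= min_stem:
                hits.append(
                    TwoHelixHit(a, b, a.end, b.start, stem, labels)
                )
    return hits
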