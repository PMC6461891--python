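"""Prediction of 2'-O-methylation sites on target RNAs from C/D snoRNA guides.

The guide region immediately 5' of a D or D' box pairs antiparallel with the
target RNA; the target nucleotide paired to the guide base *five* residues
upstream of the box (counting the box-adjacent base as 1) is ribose-methylated
(the "+5 rule"). With contiguous antiparallel pairing over a target window
[s, s+L), the box-adjacent guide base pairs target position s, so the +5
nucleotide sits at s+4 (0-based).

Duplexes are contiguous (no bulges): the guide's reverse complement is slid
along the target and windows are scored by Watson-Crick / G-U / mismatch
content. Cross-species conservation is assessed by mapping predicted positions
through a multiple alignment and comparing with a reference table of verified
sites (snOPY-style TSV).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .io import SequenceRecord
from .motifs import PAIRS, WC_PAIRS
from .snorna import CDSnoRNACandidate

log = logging.getLogger(__name__)

MIN_GUIDE_LEN = 9


@dataclass
class DuplexParams:
    """Acceptance thresholds for guide-target duplexes.

    ``min_pairs`` defaults to guide length - 1 (at most one unpaired position);
    the +5 pair must always be strict Watson-Crick.
    """

    min_pairs: int | None = None
    max_mismatch: int = 1
    max_gu: int = 2


@dataclass
class GuideDuplex:
    snorna_id: str
    box_kind: str          # D or D'
    guide: str
    target_id: str
    target_start: int      # 0-based half-open window on the target
    target_end: int
    pair_string: str       # one symbol per target position: '|' WC, ':' GU, '.' mismatch
    wc_count: int
    gu_count: int
    mismatch_count: int


@dataclass
class MethylationSite:
    target_id: str
    position: int          # 0-based on the target
    residue: str
    label: str             # e.g. "LSU-A1363": residue + 1-based position
    snorna_id: str
    box_kind: str
    duplex: GuideDuplex


def _classify(guide_base: str, target_base: str) -> str:
    if (guide_base, target_base) in WC_PAIRS:
        return "|"
    if (guide_base, target_base) in PAIRS:
        return ":"
    return "."


def find_guide_duplex(
    guide: str,
    target: SequenceRecord,
    params: DuplexParams | None = None,
    *,
    snorna_id: str = "snoRNA",
    box_kind: str = "D",
) -> list[GuideDuplex]:
    """Slide the guide along the target and report accepted duplex windows."""
    p = params or DuplexParams()
    guide = guide.upper().replace("T", "U")
    L = len(guide)
    if L < MIN_GUIDE_LEN:
        raise ValueError(f"guide must be >= {MIN_GUIDE_LEN} nt, got {L}")
    min_pairs = p.min_pairs if p.min_pairs is not None else L - 1
    tseq = target.residues
    out: list[GuideDuplex] = []
    for s in range(len(tseq) - L + 1):
        # guide base L-1-t (0-based from guide 5' end) pairs target position s+t
        symbols = [_classify(guide[L - 1 - t], tseq[s + t]) for t in range(L)]
        if symbols[4] != "|":  # +5 pair must be Watson-Crick
            continue
        wc = symbols.count("|")
        gu = symbols.count(":")
        mm = symbols.count(".")
        if wc + gu >= min_pairs and mm <= p.max_mismatch and gu <= p.max_gu:
            out.append(
                GuideDuplex(
                    snorna_id, box_kind, guide, target.id, s, s + L,
                    "".join(symbols), wc, gu, mm,
                )
            )
    return out


def predict_sites(
    candidate: CDSnoRNACandidate,
    targets: list[SequenceRecord],
    params: DuplexParams | None = None,
) -> list[MethylationSite]:
    """Apply the +5 rule to every accepted duplex of the candidate's guides.

    Sites guided by the D and D' boxes are reported separately even when they
    coincide. Guides shorter than 9 nt are skipped (too short to specify a
    target).
    """
    sites: list[MethylationSite] = []
    for box_kind, gw in candidate.guides:
        if len(gw.sequence) < MIN_GUIDE_LEN:
            log.debug(
                "%s: %s guide of %d nt skipped", candidate.locus_id, box_kind,
                len(gw.sequence),
            )
            continue
        for target in targets:
            for dup in find_guide_duplex(
                gw.sequence, target, params,
                snorna_id=candidate.locus_id, box_kind=box_kind,
            ):
                pos = dup.target_start + 4
                residue = target.residues[pos]
                sites.append(
                    MethylationSite(
                        target.id, pos, residue,
                        f"{target.id}-{residue}{pos + 1}",
                        candidate.locus_id, box_kind, dup,
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# alignment position mapping
# ---------------------------------------------------------------------------

class PositionMap:
    """Bidirectional maps between ungapped positions and alignment columns.

    Built from an aligned FASTA (gap character ``-``); all rows must have equal
    length.
    """

    def __init__(self, aligned: list[SequenceRecord]):
        if not aligned:
            raise ValueError("alignment is empty")
        width = len(aligned[0].residues)
        if any(len(r.residues) != width for r in aligned):
            raise ValueError("alignment rows differ in length")
        self.width = width
        self._col_of: dict[str, list[int]] = {}
        self._pos_at: dict[str, list[int | None]] = {}
        for rec in aligned:
            cols: list[int] = []
            posv: list[int | None] = [None] * width
            for col, ch in enumerate(rec.residues):
                if ch != "-":
                    posv[col] = len(cols)
                    cols.append(col)
            self._col_of[rec.id] = cols
            self._pos_at[rec.id] = posv

    def ids(self) -> list[str]:
        return list(self._col_of)

    def column_of(self, seq_id: str, pos: int) -> int:
        cols = self._col_of[seq_id]
        if not (0 <= pos < len(cols)):
            raise IndexError(f"position {pos} out of range for {seq_id!r}")
        return cols[pos]

    def position_at(self, seq_id: str, col: int) -> int | None:
        if not (0 <= col < self.width):
            raise IndexError(f"column {col} out of range")
        return self._pos_at[seq_id][col]

    def map_position(self, from_seq: str, pos: int, to_seq: str) -> int | None:
        """Ungapped position of ``to_seq`` at the alignment column of
        ``from_seq``'s position ``pos``, or None if ``to_seq`` is gapped there."""
        return self.position_at(to_seq, self.column_of(from_seq, pos))


# ---------------------------------------------------------------------------
# conservation and homology
# ---------------------------------------------------------------------------

@dataclass
class ConservedSiteCall:
    site: MethylationSite
    column: int
    conserved: bool
    ref_species: str | None = None
    ref_rna: str | None = None
    ref_position: int | None = None   # 1-based, as in the reference table
    ref_snorna: str | None = None
    guide_identity: float | None = None
    homolog: bool = False


def guide_identity(guide_a: str, guide_b: str) -> float:
    """Identity between two guides over their 3'-anchored overlap (the
    box-proximal ends are the functionally aligned ends)."""
    k = min(len(guide_a), len(guide_b))
    if k == 0:
        return 0.0
    a, b = guide_a[-k:], guide_b[-k:]
    return sum(x == y for x, y in zip(a, b)) / k


def call_conserved_and_homologs(
    sites: list[MethylationSite],
    reference_table: pd.DataFrame,
    position_maps: PositionMap | list[PositionMap],
    *,
    id_min: float = 0.70,
) -> list[ConservedSiteCall]:
    """Flag predicted sites that fall on the same alignment column as a
    reference (verified) site; call homology when the guides also agree.

    ``position_maps`` holds one alignment per target RNA family (e.g. one SSU
    and one LSU alignment); a site and a reference row are only compared when
    both sequences are rows of the same alignment. ``reference_table`` columns:
    ``species``, ``rna`` (alignment record id), ``position`` (1-based),
    ``snoRNA``, and optionally ``guide``. A site is conserved if its alignment
    column equals a reference site's column; the homolog flag additionally
    requires guide identity >= ``id_min`` (a sequence stand-in for
    covariance-model homology assessment).
    """
    maps = [position_maps] if isinstance(position_maps, PositionMap) else list(position_maps)
    # precompute reference columns per alignment
    refs: list[tuple[pd.Series, int, int]] = []  # (row, map index, column)
    for _, row in reference_table.iterrows():
        rna = str(row["rna"])
        placed = False
        for mi, pm in enumerate(maps):
            if rna not in pm.ids():
                continue
            try:
                refs.append((row, mi, pm.column_of(rna, int(row["position"]) - 1)))
                placed = True
            except IndexError:
                warnings.warn(
                    f"reference position {row['position']} outside {rna!r}; row skipped"
                )
                placed = True
            break
        if not placed:
            warnings.warn(f"reference rna {rna!r} absent from alignments; row skipped")

    calls: list[ConservedSiteCall] = []
    for site in sites:
        pm_index = next(
            (mi for mi, pm in enumerate(maps) if site.target_id in pm.ids()), None
        )
        if pm_index is None:
            warnings.warn(
                f"site target {site.target_id!r} absent from alignments; site skipped"
            )
            continue
        col = maps[pm_index].column_of(site.target_id, site.position)
        matched = [(row, c) for row, mi, c in refs if mi == pm_index and c == col]
        if not matched:
            calls.append(ConservedSiteCall(site, col, conserved=False))
            continue
        row, _ = matched[0]
        ident: float | None = None
        if "guide" in row.index and isinstance(row["guide"], str) and row["guide"]:
            ident = guide_identity(site.duplex.guide, row["guide"])
        calls.append(
            ConservedSiteCall(
                site, col, conserved=True,
                ref_species=str(row["species"]), ref_rna=str(row["rna"]),
                ref_position=int(row["position"]), ref_snorna=str(row["snoRNA"]),
                guide_identity=ident,
                homolog=(ident is not None and ident >= id_min),
            )
        )
    return calls
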