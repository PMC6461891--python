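"""Coverage-based calling of intergenic sRNA-expressing loci.

A locus is a maximal run of pooled read depth above a threshold, present with
minimum read support in *every* sequenced library, not fully contained in a
protein/rRNA/tRNA gene, and not overlapping an rRNA/tRNA gene at all (rRNA and
tRNA degradation fragments dominate sRNA libraries). Ends are trimmed to the
outermost positions holding a fraction of the peak depth -- a reproducible
proxy for the manual end delineation such data sets otherwise receive.

5'-cap status is inferred from Terminator-exonuclease (TE) treated libraries:
TE degrades 5'-monophosphate RNAs, so loci retaining normalized signal under
TE treatment behave as 5'-capped transcripts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GenomeAnnotation, LibraryManifest, ReadInterval

log = logging.getLogger(__name__)

EXCLUDE_CONTAINING = ("CDS", "rRNA", "tRNA")
EXCLUDE_ANY_OVERLAP = ("rRNA", "tRNA")


@dataclass
class LocusParams:
    depth_min: int = 3        # pooled depth defining candidate runs
    gap_max: int = 5          # sub-threshold gaps merged into a run (nt)
    end_frac: float = 0.1     # end trim: outermost positions >= end_frac * peak
    support_min: int = 3      # per-library minimum read count on the locus
    min_locus_len: int = 16


@dataclass
class SRNALocus:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    peak_depth: int
    lib_max_depth: dict[str, int] = field(default_factory=dict)
    lib_read_count: dict[str, int] = field(default_factory=dict)
    overlap5: int = 0
    overlap3: int = 0
    contained_in_gene: bool = False
    cap_status: str = "ambiguous"

    def __len__(self) -> int:
        return self.end - self.start


class _ReadIndex:
    """Sorted-array index over one library's reads on one (chrom, strand):
    counts of reads overlapping an interval in O(log n)."""

    def __init__(self, reads: list[ReadInterval]):
        starts = np.array([r.start for r in reads], dtype=np.int64)
        ends = np.array([r.end for r in reads], dtype=np.int64)
        counts = np.array([r.count for r in reads], dtype=np.int64)
        o = np.argsort(starts, kind="stable")
        self.starts = starts[o]
        self.cum_by_start = np.concatenate([[0], np.cumsum(counts[o])])
        o2 = np.argsort(ends, kind="stable")
        self.ends = ends[o2]
        self.cum_by_end = np.concatenate([[0], np.cumsum(counts[o2])])

    def overlapping_count(self, start: int, end: int) -> int:
        # reads with r.start < end minus reads with r.end <= start
        # (r.end <= start implies r.start < end, so the difference is exact)
        a = self.cum_by_start[np.searchsorted(self.starts, end, side="left")]
        b = self.cum_by_end[np.searchsorted(self.ends, start, side="right")]
        return int(a - b)


class CoverageProfile:
    """Per-(chromosome, strand, library) base-resolution read depth.

    Retains the read lists it was built from so that per-library read support
    on an interval can be recomputed exactly.
    """

    def __init__(self, annotation: GenomeAnnotation, libraries: list[str]):
        self.libraries = list(libraries)
        self._lib_index = {lib: i for i, lib in enumerate(self.libraries)}
        self.reads: dict[str, list[ReadInterval]] = {lib: [] for lib in libraries}
        self.chrom_lengths = {c: len(r) for c, r in annotation.sequences.items()}
        # depth accumulated as difference vectors; integrated lazily
        self._diff: dict[tuple[str, str], np.ndarray] = {}
        self._depth: dict[tuple[str, str], np.ndarray] = {}
        for chrom, L in self.chrom_lengths.items():
            for strand in "+-":
                self._diff[(chrom, strand)] = np.zeros(
                    (len(libraries), L + 1), dtype=np.int64
                )
        self._indexes: dict[tuple[str, str, str], _ReadIndex] = {}
        self._totals: dict[str, int] = {}

    def add_reads(self, library: str, reads: list[ReadInterval]) -> None:
        li = self._lib_index[library]
        self.reads[library].extend(reads)
        self._depth.clear()
        self._indexes.clear()
        self._totals.pop(library, None)
        by_key: dict[tuple[str, str], list[ReadInterval]] = {}
        for r in reads:
            L = self.chrom_lengths.get(r.chrom)
            if L is None:
                raise ValueError(f"read on unknown chromosome {r.chrom!r}")
            if r.start < 0 or r.end > L:
                raise ValueError(
                    f"read interval [{r.start},{r.end}) outside {r.chrom!r} (length {L})"
                )
            by_key.setdefault((r.chrom, r.strand), []).append(r)
        for key, rs in by_key.items():
            diff = self._diff[key][li]
            starts = np.array([r.start for r in rs], dtype=np.int64)
            ends = np.array([r.end for r in rs], dtype=np.int64)
            counts = np.array([r.count for r in rs], dtype=np.int64)
            np.add.at(diff, starts, counts)
            np.subtract.at(diff, ends, counts)

    def depth_matrix(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._depth:
            self._depth[key] = np.cumsum(self._diff[key][:, :-1], axis=1)
        return self._depth[key]

    def pooled(self, chrom: str, strand: str) -> np.ndarray:
        return self.depth_matrix(chrom, strand).sum(axis=0)

    def _index(self, library: str, chrom: str, strand: str) -> _ReadIndex:
        key = (library, chrom, strand)
        if key not in self._indexes:
            self._indexes[key] = _ReadIndex(
                [
                    r
                    for r in self.reads[library]
                    if r.chrom == chrom and r.strand == strand
                ]
            )
        return self._indexes[key]

    def library_reads_on(
        self, library: str, chrom: str, strand: str, start: int, end: int
    ) -> int:
        return self._index(library, chrom, strand).overlapping_count(start, end)

    def library_total(self, library: str) -> int:
        if library not in self._totals:
            self._totals[library] = sum(r.count for r in self.reads[library])
        return self._totals[library]


def build_coverage(
    reads_by_library: dict[str, list[ReadInterval]],
    annotation: GenomeAnnotation,
) -> CoverageProfile:
    """Sum read multiplicities into per-base depth, per strand and library."""
    cov = CoverageProfile(annotation, list(reads_by_library))
    for lib, reads in reads_by_library.items():
        cov.add_reads(lib, reads)
    return cov


def _runs_above(pooled: np.ndarray, depth_min: int, gap_max: int) -> list[tuple[int, int]]:
    mask = pooled >= depth_min
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 > gap_max:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    return runs


def call_loci(
    coverage: CoverageProfile,
    annotation: GenomeAnnotation,
    params: LocusParams | None = None,
) -> list[SRNALocus]:
    """Call sRNA loci from pooled coverage, applying the retention rules.

    Candidate intervals are maximal runs of pooled depth >= ``depth_min``
    (gaps <= ``gap_max`` merged), end-trimmed to ``end_frac`` of the peak;
    retained only with >= ``support_min`` reads in every library, length >=
    ``min_locus_len``, not fully inside a CDS/rRNA/tRNA feature and without
    any overlap of rRNA/tRNA features.
    """
    p = params or LocusParams()
    loci: list[SRNALocus] = []
    counter = 0
    for chrom in coverage.chrom_lengths:
        for strand in "+-":
            pooled = coverage.pooled(chrom, strand)
            for a, b in _runs_above(pooled, p.depth_min, p.gap_max):
                peak = int(pooled[a:b].max())
                thr = p.end_frac * peak
                above = np.flatnonzero(pooled[a:b] >= thr)
                if above.size == 0:
                    continue
                s, e = a + int(above[0]), a + int(above[-1]) + 1
                if e - s < p.min_locus_len:
                    continue
                support = {
                    lib: coverage.library_reads_on(lib, chrom, strand, s, e)
                    for lib in coverage.libraries
                }
                if any(v < p.support_min for v in support.values()):
                    continue
                containing = [
                    f
                    for f in annotation.overlapping(chrom, s, e, EXCLUDE_CONTAINING)
                    if f.contains(s, e)
                ]
                if containing:
                    continue
                if annotation.overlapping(chrom, s, e, EXCLUDE_ANY_OVERLAP):
                    continue
                counter += 1
                depth = coverage.depth_matrix(chrom, strand)
                locus = SRNALocus(
                    id=f"locus_{counter:04d}",
                    chrom=chrom, strand=strand, start=s, end=e,
                    peak_depth=peak,
                    lib_max_depth={
                        lib: int(depth[i, s:e].max())
                        for i, lib in enumerate(coverage.libraries)
                    },
                    lib_read_count=support,
                )
                loci.append(classify_overlaps(locus, annotation))
    return loci


def classify_overlaps(locus: SRNALocus, annotation: GenomeAnnotation) -> SRNALocus:
    """Annotate gene overlap at the locus ends, in transcript orientation.

    The overlap at the end nearer the locus's own 5' terminus is ``overlap5``
    (on the minus strand that is the right-hand genomic end).
    """
    left = right = 0
    contained = False
    for f in annotation.overlapping(locus.chrom, locus.start, locus.end, ("CDS",)):
        if f.contains(locus.start, locus.end):
            contained = True
            continue
        if f.start <= locus.start:
            left = max(left, min(f.end, locus.end) - locus.start)
        if f.end >= locus.end:
            right = max(right, locus.end - max(f.start, locus.start))
    if locus.strand == "+":
        locus.overlap5, locus.overlap3 = left, right
    else:
        locus.overlap5, locus.overlap3 = right, left
    locus.contained_in_gene = contained
    return locus


def infer_cap_status(
    locus: SRNALocus,
    coverage: CoverageProfile,
    manifest: LibraryManifest,
    *,
    r_high: float = 0.5,
    r_low: float = 0.2,
) -> str:
    """Classify the 5' end from TE-treated vs untreated signal.

    r = (mean reads-per-million over TE libraries) / (same over untreated
    libraries of the TE libraries' growth condition). r >= ``r_high`` ->
    capped-like; r <= ``r_low`` -> monophosphate-like; otherwise ambiguous.
    """
    te = [l for l in manifest.te_libraries() if l.id in coverage.libraries]
    te_libs = [l.id for l in te]
    # compare against untreated libraries grown under the same condition(s)
    # as the TE-treated ones, so condition-specific induction cancels out
    te_conditions = {l.condition for l in te}
    un_libs = [
        l.id
        for l in manifest.untreated()
        if l.id in coverage.libraries and l.condition in te_conditions
    ] or [l.id for l in manifest.untreated() if l.id in coverage.libraries]
    if not te_libs:
        warnings.warn("no TE-treated library in manifest; cap status is ambiguous")
        locus.cap_status = "ambiguous"
        return locus.cap_status

    def _rpm(libs: list[str]) -> float:
        vals = []
        for lib in libs:
            total = coverage.library_total(lib)
            if total == 0:
                continue
            n = coverage.library_reads_on(
                lib, locus.chrom, locus.strand, locus.start, locus.end
            )
            vals.append(n / total * 1e6)
        return float(np.mean(vals)) if vals else float("nan")

    te_rpm, un_rpm = _rpm(te_libs), _rpm(un_libs)
    if not np.isfinite(te_rpm) or not np.isfinite(un_rpm) or un_rpm == 0:
        locus.cap_status = "ambiguous"
        return locus.cap_status
    r = te_rpm / un_rpm
    if r >= r_high:
        locus.cap_status = "capped-like"
    elif r <= r_low:
        locus.cap_status = "monophosphate-like"
    else:
        locus.cap_status = "ambiguous"
    return locus.cap_status
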