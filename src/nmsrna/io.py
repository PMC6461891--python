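"""Readers/writers for the standard formats the pipeline touches, plus the shared
sequence and coordinate conventions.

Conventions
-----------
* Sequences are stored as uppercase RNA (``A C G U N``). DNA input is normalized
  on read (``T`` -> ``U``); IUPAC ambiguity codes other than ``N`` are replaced
  by ``N`` with a warning. Degeneracy is handled in *patterns* (see
  :mod:`nmsrna.motifs`), never in subject sequences.
* All intervals are 0-based half-open internally. GFF3 (1-based inclusive) and
  BED (0-based half-open) are converted at the format boundary only.
* BED6 is used for mapped read intervals; the score column carries the read
  multiplicity of a collapsed read (0 or empty means 1). This dialect is the
  only departure from plain BED6.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
_AMBIGUITY = frozenset("RYSWKMBDHV")

#: complement table for normalized RNA plus gap (used by aligned FASTA)
_COMPLEMENT = str.maketrans("ACGUN-", "UGCAN-")

#: mapping from GFF3 ``type`` column to the internal feature vocabulary
GFF3_TYPE_MAP = {
    "CDS": "CDS",
    "gene": "CDS",
    "mRNA": "CDS",
    "protein_coding_gene": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intron": "intron",
    "sRNA": "sRNA",
    "ncRNA": "sRNA",
    "snoRNA": "sRNA",
    "snRNA": "sRNA",
}

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "intron", "sRNA", "other")


class FastaFormatError(ValueError):
    """Malformed FASTA input (message names the offending line)."""


class GFF3FormatError(ValueError):
    """Malformed or out-of-bounds GFF3 record."""


class BedFormatError(ValueError):
    """Malformed BED6 record."""


def normalize_residues(raw: str, *, context: str = "", allow_gaps: bool = False) -> str:
    """Uppercase, convert T->U, and map non-N ambiguity codes to N.

    Raises :class:`ValueError` on characters outside the IUPAC nucleotide
    alphabet. ``context`` is prefixed to error/warning messages.
    """
    seq = raw.upper().replace("T", "U")
    out = []
    for ch in seq:
        if ch in RNA_ALPHABET or (allow_gaps and ch == "-"):
            out.append(ch)
        elif ch in _AMBIGUITY:
            warnings.warn(
                f"{context}: ambiguity code {ch!r} replaced by N", stacklevel=2
            )
            out.append("N")
        else:
            raise ValueError(f"{context}: illegal character {ch!r}")
    return "".join(out)


def reverse_complement(residues: str) -> str:
    """Reverse complement on the normalized RNA alphabet (A<->U, C<->G, N<->N).

    >>> reverse_complement("ACUUAC")
    'GUAAGU'
    """
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (genome chromosome, rRNA, snRNA, ...)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence record {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """A typed, stranded genomic feature in 0-based half-open coordinates."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    ftype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"feature {self.id!r}: unknown ftype {self.ftype!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus their typed features."""

    sequences: dict[str, SequenceRecord]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: Feature) -> None:
        if f.chrom not in self.sequences:
            raise ValueError(f"feature {f.id!r}: unknown chromosome {f.chrom!r}")
        if f.end > len(self.sequences[f.chrom]):
            raise ValueError(
                f"feature {f.id!r}: end {f.end} beyond chromosome "
                f"{f.chrom!r} length {len(self.sequences[f.chrom])}"
            )

    def add_feature(self, f: Feature) -> None:
        self._check_feature(f)
        self.features.append(f)

    def features_of_type(self, *ftypes: str) -> list[Feature]:
        want = set(ftypes)
        return [f for f in self.features if f.ftype in want]

    def overlapping(
        self, chrom: str, start: int, end: int, ftypes: Sequence[str] | None = None
    ) -> list[Feature]:
        want = set(ftypes) if ftypes is not None else None
        return [
            f
            for f in self.features
            if f.chrom == chrom
            and f.overlaps(start, end)
            and (want is None or f.ftype in want)
        ]

    def subsequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-aware extraction: '-' returns the reverse complement."""
        s = self.sequences[chrom].residues[start:end]
        return reverse_complement(s) if strand == "-" else s


@dataclass
class LibraryInfo:
    """One sequenced sRNA library."""

    id: str
    condition: str  # "light" or "dark"
    replicate: int
    te_treated: bool
    reads_path: str = ""

    def __post_init__(self) -> None:
        if self.condition not in ("light", "dark"):
            raise ValueError(f"library {self.id!r}: condition must be light/dark")


@dataclass
class LibraryManifest:
    """The set of libraries in an experiment (>=1, unique ids)."""

    libraries: list[LibraryInfo]

    def __post_init__(self) -> None:
        if not self.libraries:
            raise ValueError("manifest must list at least one library")
        ids = [lib.id for lib in self.libraries]
        if len(set(ids)) != len(ids):
            raise ValueError("library ids must be unique")

    def __iter__(self):
        return iter(self.libraries)

    def __len__(self) -> int:
        return len(self.libraries)

    def te_libraries(self) -> list[LibraryInfo]:
        return [l for l in self.libraries if l.te_treated]

    def untreated(self) -> list[LibraryInfo]:
        return [l for l in self.libraries if not l.te_treated]

    def by_condition(self, condition: str, include_te: bool = False) -> list[LibraryInfo]:
        return [
            l
            for l in self.libraries
            if l.condition == condition and (include_te or not l.te_treated)
        ]


@dataclass
class ReadInterval:
    """A mapped (possibly collapsed) sRNA read, 0-based half-open."""

    chrom: str
    strand: str
    start: int
    end: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"read interval strand must be + or -, got {self.strand!r}")
        if self.end - self.start < 1:
            raise ValueError(f"read interval [{self.start},{self.end}) is empty")
        if self.count < 1:
            raise ValueError("read count must be a positive integer")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Input order is preserved; T is converted to U. Errors name the offending
    line. ``allow_gaps`` admits ``-`` characters (aligned FASTA).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def _flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        if not chunks:
            raise FastaFormatError(
                f"{path}: record {header!r} (line {header_line}) has no sequence"
            )
        records.append(SequenceRecord(header, "".join(chunks), desc))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {line_no}")
                header, desc = parts[0], parts[1] if len(parts) > 1 else ""
                header_line = line_no
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence before any header at line {line_no}"
                    )
                try:
                    chunks.append(
                        normalize_residues(
                            line, context=f"{path} line {line_no}", allow_gaps=allow_gaps
                        )
                    )
                except ValueError as exc:
                    raise FastaFormatError(str(exc)) from None
        _flush()
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, sequences: dict[str, SequenceRecord]) -> GenomeAnnotation:
    """Read GFF3 into a :class:`GenomeAnnotation`.

    Coordinates are converted from 1-based inclusive to 0-based half-open
    (``start-1``, ``end``); the GFF3 ``type`` column is mapped through
    :data:`GFF3_TYPE_MAP` (unknown types become ``other``).
    """
    ann = GenomeAnnotation(sequences=dict(sequences), features=[])
    with open(Path(path)) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                g = feature_from_line(line)
            except Exception as exc:
                raise GFF3FormatError(f"{path} line {line_no}: {exc}") from None
            fid = g.attributes.get("ID", [f"{g.featuretype}_{line_no}"])[0]
            ftype = GFF3_TYPE_MAP.get(g.featuretype, "other")
            strand = g.strand if g.strand in ("+", "-") else "+"
            feat = Feature(
                id=fid, chrom=g.seqid, strand=strand,
                start=g.start - 1, end=g.end, ftype=ftype,
            )
            try:
                ann.add_feature(feat)
            except ValueError as exc:
                raise GFF3FormatError(f"{path} line {line_no}: {exc}") from None
    return ann


_FTYPE_TO_GFF3 = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
                  "intron": "intron", "sRNA": "sRNA", "other": "region"}


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, rec in annotation.sequences.items():
            fh.write(f"##sequence-region {chrom} 1 {len(rec)}\n")
        for f in annotation.features:
            fh.write(
                "\t".join(
                    [
                        f.chrom, "nmsrna", _FTYPE_TO_GFF3[f.ftype],
                        str(f.start + 1), str(f.end), ".", f.strand, ".",
                        f"ID={f.id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6 read intervals
# ---------------------------------------------------------------------------

def read_reads_bed(path: str | Path) -> list[ReadInterval]:
    """Read mapped sRNA reads from BED6 (score column = multiplicity)."""
    path = Path(path)
    reads: list[ReadInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise BedFormatError(f"{path} line {line_no}: expected 6 BED columns")
            chrom, start, end, _name, score, strand = cols[:6]
            if strand not in ("+", "-"):
                raise BedFormatError(
                    f"{path} line {line_no}: strand must be + or -, got {strand!r}"
                )
            count = int(float(score)) if score not in ("", ".") else 1
            if count == 0:
                count = 1  # dialect rule: 0/empty score means single read
            reads.append(ReadInterval(chrom, strand, int(start), int(end), count))
    return reads


def write_reads_bed(reads: Iterable[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t{r.count}\t{r.strand}\n"
            )


def write_bedgraph(depth_by_chrom: dict[str, "list[float]"], path: str | Path) -> None:
    """Export a per-base depth vector as bedGraph (runs of equal depth merged)."""
    with open(path, "w") as fh:
        for chrom, depth in depth_by_chrom.items():
            run_start = 0
            for pos in range(1, len(depth) + 1):
                if pos == len(depth) or depth[pos] != depth[run_start]:
                    if depth[run_start] != 0:
                        fh.write(f"{chrom}\t{run_start}\t{pos}\t{depth[run_start]}\n")
                    run_start = pos


# ---------------------------------------------------------------------------
# manifest TSV
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> LibraryManifest:
    """Read a library manifest TSV with columns
    ``library_id condition replicate te_treated reads_path``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "condition", "replicate", "te_treated"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    libs = [
        LibraryInfo(
            id=row["library_id"],
            condition=row["condition"],
            replicate=int(row["replicate"]),
            te_treated=str(row["te_treated"]).lower() in ("1", "true", "yes"),
            reads_path=str(row.get("reads_path", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    return LibraryManifest(libs)


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    rows = [
        {
            "library_id": l.id,
            "condition": l.condition,
            "replicate": l.replicate,
            "te_treated": int(l.te_treated),
            "reads_path": l.reads_path,
        }
        for l in manifest
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
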