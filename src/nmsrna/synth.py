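"""Synthetic nucleomorph-like genomes with planted sRNA genes and simulated
replicate sRNA-seq libraries.

The generator emulates the salient properties of a miniaturized, gene-dense
nucleomorph genome: short intergenic spaces (geometric, mean ~130 nt), rRNA
genes (SSU/LSU/5.8S), planted C/D box snoRNA genes whose guides are exact
antisense copies of rRNA windows, planted spliceosomal snRNA genes carrying
the class-defining motifs (U1 ACUUAC, U2 GUAG + U6 pairing, U4 two U6 helices
with an intervening stem-loop, U5 loop I with closing stem, U6 ACAGAGA +
3' U-tract), orphan loci, one expressed locus induced under darkness, an
unexpressed truncated snoRNA pseudogene, and replicate read libraries with
negative-binomial counts where Terminator-exonuclease (TE) treatment spares
5'-capped loci but depletes 5'-monophosphate loci.

Planted snRNAs are fixed motif/helix cores joined by seeded random padding;
pads are rejection-sampled so a planted sequence never accidentally satisfies
another kind's mandatory rules (and orphans satisfy none). Planted snoRNA
guides are drawn from rRNA windows whose reverse complement contains no UGA
trinucleotide, so guides can never harbour spurious box motifs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    Feature,
    GenomeAnnotation,
    LibraryInfo,
    LibraryManifest,
    ReadInterval,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_manifest,
    write_reads_bed,
)
from .motifs import WC_PAIRS
from .snorna import assemble_cd_candidates
from .snrna import SNRNA_KINDS, evaluate_snrna_candidate

log = logging.getLogger(__name__)

BASES = np.array(list("ACGU"))


class SimulationSizeError(ValueError):
    """The requested features do not fit in the requested genome length."""


@dataclass
class LibrarySpec:
    id: str
    condition: str
    replicate: int
    te_treated: bool = False


def default_libraries() -> list[LibrarySpec]:
    """2 conditions x 2 replicates plus one TE-treated library."""
    return [
        LibrarySpec("light_1", "light", 1),
        LibrarySpec("light_2", "light", 2),
        LibrarySpec("dark_1", "dark", 1),
        LibrarySpec("dark_2", "dark", 2),
        LibrarySpec("te_1", "light", 1, te_treated=True),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data set."""

    seed: int = 42
    genome_length: int = 120_000
    chrom_name: str = "nmchr1"
    n_cds: int = 80
    cds_length: tuple[int, int] = (300, 900)
    n_snorna: int = 20
    snrna_kinds: tuple[str, ...] = SNRNA_KINDS
    n_orphan: int = 5
    ssu_length: int = 1500
    lsu_length: int = 2900
    r58_length: int = 160
    libraries: list[LibrarySpec] = field(default_factory=default_libraries)
    mean_depth: float = 200.0          # expected reads per expressed locus per library
    dispersion: float = 0.1            # NB: var = mu + dispersion * mu^2
    dark_induced_fold: float = 6.0
    te_capped_retention: float = 0.9
    te_monop_retention: float = 0.05
    read_len: tuple[int, int] = (18, 76)
    offset_geom_p: float = 0.2         # 5' read offsets ~ geometric (0-based)
    frac_internal: float = 0.3         # fraction of reads tiling the locus body
    overlap_fraction: float = 0.3      # planted sRNAs overlapping a flanking CDS
    overlap_nt: tuple[int, int] = (13, 43)
    prob_overlap_3prime: float = 0.9   # 3' overlaps dominate over 5' overlaps
    intergenic_mean: int = 130
    intergenic_min: int = 20
    guide_len: int = 12
    noise_depth: float = 0.3           # expected genome-wide background depth
    noise_read_len: tuple[int, int] = (18, 30)

    def __post_init__(self) -> None:
        for name in ("n_cds", "n_snorna", "n_orphan", "genome_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("te_capped_retention", "te_monop_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if not self.libraries:
            raise ValueError("at least one library is required")
        bad = set(self.snrna_kinds) - set(SNRNA_KINDS)
        if bad:
            raise ValueError(f"unknown snRNA kinds {sorted(bad)}")

    def manifest(self, reads_dir: str | Path = "") -> LibraryManifest:
        base = str(reads_dir)
        return LibraryManifest(
            [
                LibraryInfo(
                    l.id, l.condition, l.replicate, l.te_treated,
                    str(Path(base) / f"reads_{l.id}.bed") if base else "",
                )
                for l in self.libraries
            ]
        )


@dataclass
class PlantedGuide:
    box_kind: str          # D or D'
    rel_start: int         # on the sRNA sequence
    rel_end: int
    target_id: str
    target_start: int      # duplex window on the target, 0-based half-open
    target_end: int
    methyl_pos: int        # 0-based methylated position on the target


@dataclass
class PlantedLocus:
    id: str
    sclass: str            # snoRNA / snRNA / orphan / pseudogene
    chrom: str
    strand: str
    start: int
    end: int
    sequence: str          # transcript orientation
    expression: str        # constitutive / dark_induced / silent
    cap: str               # capped / monophosphate
    snrna_kind: str | None = None
    boxes: dict[str, tuple[int, int]] = field(default_factory=dict)
    guides: list[PlantedGuide] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SyntheticTruth:
    chrom: str
    loci: list[PlantedLocus]
    targets: dict[str, str]       # rRNA id -> sequence (methylation targets)
    snrna_seqs: dict[str, str]    # kind -> planted sequence

    def expressed(self) -> list[PlantedLocus]:
        return [l for l in self.loci if l.expression != "silent"]

    def by_class(self, sclass: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.sclass == sclass]

    def target_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(k, v) for k, v in self.targets.items()]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        loci = [
            PlantedLocus(
                **{
                    **l,
                    "boxes": {k: tuple(v) for k, v in l["boxes"].items()},
                    "guides": [PlantedGuide(**g) for g in l["guides"]],
                }
            )
            for l in raw["loci"]
        ]
        return cls(raw["chrom"], loci, raw["targets"], raw["snrna_seqs"])


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _rand_seq_no_uga(rng: np.random.Generator, n: int) -> str:
    for _ in range(200):
        s = _rand_seq(rng, n)
        if "UGA" not in s:
            return s
    raise RuntimeError("could not sample a UGA-free pad")


# Fixed U6 core: helix partners for U4 (X1/X2) and U2 (Y1/Y2). The partner
# segments are A/C-only and the 3' U-tract is C-interrupted, so U6 carries the
# mandatory elements yet has essentially no self-complementarity (A/C strings
# cannot base-pair with A/C strings, and no G.U wobble run can reach helix
# length through the interruptions).
U6_X1 = "CCAACCACCAAC"
U6_X2 = "ACCAAACCCA"
U6_Y1 = "CAACACCAAC"
U6_Y2 = "ACCCACAACC"
U6_SEQ = "C" + U6_X1 + "ACAGAGA" + U6_X2 + "CAC" + U6_Y1 + "CACA" + U6_Y2 + "UUCUUCUUCC"

_SM_SITE = "AAUUUUUG"
_U4_STEM = "GGCAUC"
_U4_LOOP = "UUCG"
U5_STEM = "GGCAC"
U5_LOOP = "UGCCUUUUACC"  # loop I, Y realized as C


def _build_snrna(kind: str, rng: np.random.Generator) -> str:
    """One draw of a planted snRNA: fixed cores joined by random pads."""
    pad = lambda n: _rand_seq(rng, n)
    if kind == "U6":
        return U6_SEQ
    if kind == "U1":
        return "ACUUAC" + pad(30) + _SM_SITE + pad(4)
    if kind == "U2":
        return (
            pad(4) + "GUAG" + pad(4)
            + reverse_complement(U6_Y1) + "AG" + reverse_complement(U6_Y2)
            + pad(6) + _SM_SITE + pad(2)
        )
    if kind == "U4":
        return (
            pad(5) + reverse_complement(U6_X1)
            + "AC" + _U4_STEM + _U4_LOOP + reverse_complement(_U4_STEM) + "AA"
            + reverse_complement(U6_X2) + pad(4) + _SM_SITE + pad(2)
        )
    if kind == "U5":
        return (
            pad(4) + U5_STEM + U5_LOOP + reverse_complement(U5_STEM)
            + pad(8) + _SM_SITE + pad(2)
        )
    raise ValueError(kind)


def _snrna_is_unambiguous(
    seq: str, kind: str, u6: str, avoid_guides: tuple[str, ...] = ()
) -> bool:
    """True when ``seq`` passes its own kind's mandatory rules, no other
    kind's, and is not an accidental duplex target of any planted snoRNA
    guide (planted snoRNAs act on rRNA only)."""
    from .methyl import find_guide_duplex
    from .io import SequenceRecord

    for k in SNRNA_KINDS:
        report = evaluate_snrna_candidate(seq, k, u6_sequence=u6)
        if report.verdict != (k == kind):
            return False
    rec = SequenceRecord("candidate", seq)
    return not any(find_guide_duplex(g, rec) for g in avoid_guides)


def _sample_snrna(
    kind: str,
    rng: np.random.Generator,
    u6: str,
    avoid_guides: tuple[str, ...] = (),
    tries: int = 200,
) -> str:
    for _ in range(tries):
        seq = _build_snrna(kind, rng)
        if _snrna_is_unambiguous(seq, kind, u6, avoid_guides):
            return seq
    raise RuntimeError(f"could not sample an unambiguous {kind} sequence")


def _sample_orphan(rng: np.random.Generator, u6: str, tries: int = 500) -> str:
    """A random sequence passing no detector (the negative class)."""
    for _ in range(tries):
        seq = _rand_seq(rng, int(rng.integers(80, 171)))
        if assemble_cd_candidates(seq):
            continue
        if any(
            evaluate_snrna_candidate(seq, k, u6_sequence=u6).verdict
            for k in SNRNA_KINDS
        ):
            continue
        return seq
    raise RuntimeError("could not sample an orphan sequence")


def _pick_guide_window(
    rng: np.random.Generator, targets: dict[str, str], guide_len: int,
    used: set[tuple[str, int]],
) -> tuple[str, int, str]:
    """A target window whose antisense guide is UGA-free and unused."""
    ids = sorted(targets)
    for _ in range(1000):
        tid = ids[int(rng.integers(0, len(ids)))]
        tseq = targets[tid]
        s = int(rng.integers(0, len(tseq) - guide_len + 1))
        if (tid, s) in used:
            continue
        guide = reverse_complement(tseq[s : s + guide_len])
        if "UGA" in guide or "N" in guide:
            continue
        used.add((tid, s))
        return tid, s, guide
    raise RuntimeError("could not pick a guide window")


def _build_snorna(
    idx: int,
    rng: np.random.Generator,
    targets: dict[str, str],
    used_windows: set[tuple[str, int]],
    guide_len: int,
) -> tuple[str, dict[str, tuple[int, int]], list[PlantedGuide]]:
    """One planted C/D box snoRNA; every 6th/7th uses the noncanonical
    compensatory box variants."""
    variant = idx % 7
    if variant == 5:
        c_box, d_box = "AUGAUU", "AUGA"   # compensatory U-A at C6-D1
    elif variant == 6:
        c_box, d_box = "GUGAAG", "CUGA"   # 5' purine G; A-U replaces U-U
    else:
        c_box, d_box = "AUGAUGA", "CUGA"
    dp_box = cp_box = "UUGA"

    tid_dp, s_dp, guide_dp = _pick_guide_window(rng, targets, guide_len, used_windows)
    tid_d, s_d, guide_d = _pick_guide_window(rng, targets, guide_len, used_windows)

    lead = _rand_seq_no_uga(rng, 2)
    tail = _rand_seq_no_uga(rng, int(rng.integers(2, 4)))
    gap_len = 10 if idx == 0 else int(rng.integers(2, 13))
    # mature C/D snoRNAs are >= ~50 nt; pad the D'-C' spacer so every planted
    # gene clears that floor (the worst-case pad still fits the spacer's
    # 2-12 nt envelope given these box and guide sizes)
    fixed = len(lead) + len(c_box) + 2 * guide_len + len(dp_box) + len(cp_box) + len(d_box) + len(tail)
    gap_len = max(gap_len, 52 - fixed)
    gap = _rand_seq_no_uga(rng, gap_len)

    parts = [lead, c_box, guide_dp, dp_box, gap, cp_box, guide_d, d_box, tail]
    seq = "".join(parts)

    pos = 0
    coords: dict[str, tuple[int, int]] = {}
    for name, part in zip(
        ("lead", "C", "guide_dp", "D'", "gap", "C'", "guide_d", "D", "tail"), parts
    ):
        if name in ("C", "D'", "C'", "D"):
            coords[name] = (pos, pos + len(part))
        elif name == "guide_dp":
            gdp = (pos, pos + len(part))
        elif name == "guide_d":
            gd = (pos, pos + len(part))
        pos += len(part)

    guides = [
        PlantedGuide("D'", gdp[0], gdp[1], tid_dp, s_dp, s_dp + guide_len, s_dp + 4),
        PlantedGuide("D", gd[0], gd[1], tid_d, s_d, s_d + guide_len, s_d + 4),
    ]
    # self-consistency: the +5 rule applied to the planted guide recovers the
    # recorded position (guide base at offset 5 pairs target position start+4)
    for g, guide in ((guides[0], guide_dp), (guides[1], guide_d)):
        tbase = targets[g.target_id][g.methyl_pos]
        gbase = guide[len(guide) - 5]
        assert (gbase, tbase) in WC_PAIRS, "planted guide violates the +5 rule"
    return seq, coords, guides


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, SyntheticTruth]:
    """Build the genome, its annotation and the ground truth. Deterministic
    for a given config (all randomness flows from ``config.seed``)."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])

    targets = {
        "SSU": _rand_seq(rng, cfg.ssu_length),
        "LSU": _rand_seq(rng, cfg.lsu_length),
        "5.8S": _rand_seq(rng, cfg.r58_length),
    }

    # --- planted sRNAs -----------------------------------------------------
    planted: list[PlantedLocus] = []
    used_windows: set[tuple[str, int]] = set()
    for i in range(cfg.n_snorna):
        seq, coords, guides = _build_snorna(i, rng, targets, used_windows, cfg.guide_len)
        planted.append(
            PlantedLocus(
                id=f"sno_{i:02d}", sclass="snoRNA", chrom=cfg.chrom_name,
                strand="+", start=-1, end=-1, sequence=seq,
                expression="constitutive", cap="capped",
                boxes=coords, guides=guides,
            )
        )
    planted_guides = tuple(
        p.sequence[g.rel_start : g.rel_end] for p in planted for g in p.guides
    )
    snrna_seqs: dict[str, str] = {}
    for kind in cfg.snrna_kinds:
        seq = _sample_snrna(kind, rng, U6_SEQ, planted_guides)
        snrna_seqs[kind] = seq
        planted.append(
            PlantedLocus(
                id=f"snrna_{kind}", sclass="snRNA", chrom=cfg.chrom_name,
                strand="+", start=-1, end=-1, sequence=seq,
                expression="constitutive", cap="capped", snrna_kind=kind,
            )
        )
    for i in range(cfg.n_orphan):
        planted.append(
            PlantedLocus(
                id=f"orphan_{i:02d}", sclass="orphan", chrom=cfg.chrom_name,
                strand="+", start=-1, end=-1,
                sequence=_sample_orphan(rng, U6_SEQ),
                expression="dark_induced" if i == 0 else "constitutive",
                cap="capped" if i % 2 == 0 else "monophosphate",
            )
        )
    if cfg.n_snorna > 0:
        # truncated pseudogene copy lacking the C'/D boxes, never expressed
        planted.append(
            PlantedLocus(
                id="sno_pseudo", sclass="pseudogene", chrom=cfg.chrom_name,
                strand="+", start=-1, end=-1,
                sequence=planted[0].sequence[:34],
                expression="silent", cap="monophosphate",
            )
        )

    # strands: overlap-designated sRNAs stay on +, the rest are random
    n_overlap = int(round(cfg.overlap_fraction * (cfg.n_snorna + len(snrna_seqs) + cfg.n_orphan)))
    overlap_ids = [l.id for l in planted if l.sclass != "pseudogene"]
    rng.shuffle(overlap_ids)
    overlap_set = set(overlap_ids[:n_overlap])
    for l in planted:
        if l.id not in overlap_set and rng.random() < 0.5:
            l.strand = "-"

    # --- placement ---------------------------------------------------------
    cds_lens = rng.integers(cfg.cds_length[0], cfg.cds_length[1] + 1, cfg.n_cds)
    items: list[tuple] = []
    for rid, rseq in targets.items():
        items.append(("rRNA", rid, rseq))
    cds_queue = [(f"cds_{i:03d}", int(n)) for i, n in enumerate(cds_lens)]
    overlap_loci = [l for l in planted if l.id in overlap_set]
    plain_loci = [l for l in planted if l.id not in overlap_set]
    for l in overlap_loci:
        if not cds_queue:
            break
        cds = cds_queue.pop()
        mode = "3prime" if rng.random() < cfg.prob_overlap_3prime else "5prime"
        items.append(("sRNA_overlap", l, cds, mode))
    for cid, clen in cds_queue:
        items.append(("CDS", cid, clen))
    for l in plain_loci:
        items.append(("sRNA", l))
    rng.shuffle(items)

    chunks: list[str] = []
    cursor = 0
    features: list[Feature] = []
    gap_p = 1.0 / max(1, cfg.intergenic_mean - cfg.intergenic_min + 1)

    def _gap() -> None:
        nonlocal cursor
        n = cfg.intergenic_min + int(rng.geometric(gap_p)) - 1
        chunks.append(_rand_seq(rng, n))
        cursor += n

    def _place_seq(seq: str) -> tuple[int, int]:
        nonlocal cursor
        chunks.append(seq)
        start = cursor
        cursor += len(seq)
        return start, cursor

    def _place_locus(l: PlantedLocus) -> None:
        genomic = l.sequence if l.strand == "+" else reverse_complement(l.sequence)
        l.start, l.end = _place_seq(genomic)

    for item in items:
        _gap()
        if item[0] == "rRNA":
            _, rid, rseq = item
            s, e = _place_seq(rseq)
            features.append(Feature(f"rrna_{rid}", cfg.chrom_name, "+", s, e, "rRNA"))
        elif item[0] == "CDS":
            _, cid, clen = item
            s, e = _place_seq(_rand_seq(rng, clen))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(Feature(cid, cfg.chrom_name, strand, s, e, "CDS"))
        elif item[0] == "sRNA":
            _place_locus(item[1])
        else:  # sRNA overlapping a flanking CDS by 13-43 nt
            _, l, (cid, clen), mode = item
            k = int(rng.integers(cfg.overlap_nt[0], cfg.overlap_nt[1] + 1))
            k = min(k, len(l.sequence) - 1)
            if mode == "3prime":
                _place_locus(l)
                s, e = _place_seq(_rand_seq(rng, clen))
                features.append(
                    Feature(cid, cfg.chrom_name, "+", l.end - k, e, "CDS")
                )
            else:
                s, e = _place_seq(_rand_seq(rng, clen))
                _place_locus(l)
                features.append(
                    Feature(cid, cfg.chrom_name, "+", s, l.start + k, "CDS")
                )

    if cursor > cfg.genome_length:
        raise SimulationSizeError(
            f"placed features need {cursor} nt but genome_length is "
            f"{cfg.genome_length}; enlarge the genome or reduce feature counts"
        )
    chunks.append(_rand_seq(rng, cfg.genome_length - cursor))
    genome = "".join(chunks)

    ann = GenomeAnnotation(
        sequences={cfg.chrom_name: SequenceRecord(cfg.chrom_name, genome)},
        features=features,
    )
    truth = SyntheticTruth(cfg.chrom_name, planted, targets, snrna_seqs)

    # invariants: planted loci inside the genome and pairwise disjoint
    placed = sorted((l.start, l.end) for l in planted)
    assert all(0 <= s < e <= cfg.genome_length for s, e in placed)
    assert all(placed[i][1] <= placed[i + 1][0] for i in range(len(placed) - 1))
    for l in planted:
        got = ann.subsequence(cfg.chrom_name, l.start, l.end, l.strand)
        assert got == l.sequence
    return ann, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_libraries(
    annotation: GenomeAnnotation,
    truth: SyntheticTruth,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> dict[str, list[ReadInterval]]:
    """Simulate per-library read intervals for the planted loci plus uniform
    background noise. Counts are negative-binomial around the configured mean;
    dark-induced loci are scaled in dark libraries and TE-treated libraries
    retain loci according to their 5'-end class. Read 5' ends concentrate at
    the locus 5' end (geometric offsets)."""
    cfg = config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    genome_len = len(annotation.sequences[truth.chrom])
    rmin, rmax = cfg.read_len
    out: dict[str, list[ReadInterval]] = {}

    for lib in cfg.libraries:
        bag: Counter[tuple[str, int, int]] = Counter()
        for l in truth.loci:
            if l.expression == "silent":
                continue
            mu = cfg.mean_depth
            if l.expression == "dark_induced" and lib.condition == "dark":
                mu *= cfg.dark_induced_fold
            if lib.te_treated:
                mu *= (
                    cfg.te_capped_retention
                    if l.cap == "capped"
                    else cfg.te_monop_retention
                )
            n = _nb_draw(rng, mu, cfg.dispersion)
            if n == 0:
                continue
            llen = l.length
            hi = min(rmax, llen)
            lengths = rng.integers(min(rmin, hi), hi + 1, n)
            # most read 5' ends sit at the locus 5' end (intact, capped
            # molecules); a fraction are internal degradation fragments
            # tiling the locus body
            offsets = np.minimum(
                rng.geometric(cfg.offset_geom_p, n) - 1, max(0, llen - rmin)
            )
            internal = rng.random(n) < cfg.frac_internal
            if internal.any():
                offsets[internal] = rng.integers(
                    0, max(1, llen - rmin + 1), int(internal.sum())
                )
            if l.strand == "+":
                starts = l.start + offsets
                ends = np.minimum(starts + lengths, l.end)
            else:
                ends = l.end - offsets
                starts = np.maximum(ends - lengths, l.start)
            for s, e in zip(starts.tolist(), ends.tolist()):
                if e - s >= 1:
                    bag[(l.strand, s, e)] += 1
        # uniform background noise
        mean_nlen = (cfg.noise_read_len[0] + cfg.noise_read_len[1]) / 2
        n_noise = int(round(cfg.noise_depth * genome_len / mean_nlen))
        if n_noise:
            nlens = rng.integers(cfg.noise_read_len[0], cfg.noise_read_len[1] + 1, n_noise)
            nstarts = rng.integers(0, genome_len - cfg.noise_read_len[1], n_noise)
            nstrands = rng.integers(0, 2, n_noise)
            for s, L, st in zip(nstarts.tolist(), nlens.tolist(), nstrands.tolist()):
                bag[("+" if st else "-", s, s + L)] += 1
        out[lib.id] = [
            ReadInterval(truth.chrom, strand, s, e, c)
            for (strand, s, e), c in sorted(bag.items())
        ]
    return out


def write_dataset(
    out_dir: str | Path,
    config: SimulationConfig,
    annotation: GenomeAnnotation | None = None,
    truth: SyntheticTruth | None = None,
    reads: dict[str, list[ReadInterval]] | None = None,
) -> dict[str, Path]:
    """Write genome.fasta, annotation.gff3, targets.fasta, truth.json,
    manifest.tsv and reads_<lib>.bed under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if annotation is None or truth is None:
        annotation, truth = generate_genome(config)
    if reads is None:
        reads = simulate_libraries(annotation, truth, config)
    paths = {
        "genome": out / "genome.fasta",
        "gff": out / "annotation.gff3",
        "targets": out / "targets.fasta",
        "truth": out / "truth.json",
        "manifest": out / "manifest.tsv",
    }
    write_fasta(annotation.sequences.values(), paths["genome"])
    write_gff3(annotation, paths["gff"])
    write_fasta(truth.target_records(), paths["targets"])
    truth.to_json(paths["truth"])
    write_manifest(config.manifest(out), paths["manifest"])
    for lib_id, rds in reads.items():
        p = out / f"reads_{lib_id}.bed"
        write_reads_bed(rds, p)
        paths[f"reads_{lib_id}"] = p
    return paths
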