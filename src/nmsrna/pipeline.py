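"""End-to-end orchestration: locus calling, classification (snoRNA / snRNA /
orphan), cap inference, target prediction and differential expression, joined
into one per-locus report.

Classification precedence is deterministic: a locus passing the C/D snoRNA
detector is a snoRNA even if an snRNA rule also fires; among snRNA kinds the
first passing kind in the order U1 < U2 < U4 < U5 < U6 wins and any additional
passing kind is logged as a conflict. Loci matching no detector are orphans.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr, loci as loci_mod, methyl, snorna, snrna
from .io import (
    GenomeAnnotation,
    LibraryManifest,
    ReadInterval,
    SequenceRecord,
    read_fasta,
    read_gff3,
    read_manifest,
    read_reads_bed,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineParams:
    locus: loci_mod.LocusParams = field(default_factory=loci_mod.LocusParams)
    cd: snorna.CDParams = field(default_factory=snorna.CDParams)
    duplex: methyl.DuplexParams = field(default_factory=methyl.DuplexParams)
    snrna: snrna.SnRNAParams = field(default_factory=snrna.SnRNAParams)
    de: diffexpr.DEParams = field(default_factory=diffexpr.DEParams)


@dataclass
class PipelineResult:
    loci: list[loci_mod.SRNALocus]
    classifications: dict[str, str]             # locus id -> snoRNA / U1..U6 / orphan
    snorna_candidates: dict[str, snorna.CDSnoRNACandidate]
    sites: list[methyl.MethylationSite]
    snrna_reports: dict[str, list[snrna.SnRNAReport]]
    de_results: list[diffexpr.DEResult]
    report: pd.DataFrame


def run_pipeline(
    annotation: GenomeAnnotation,
    reads_by_library: dict[str, list[ReadInterval]],
    manifest: LibraryManifest,
    targets: list[SequenceRecord] | None = None,
    u6_sequence: str | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run all analysis stages on in-memory inputs and join the results."""
    p = params or PipelineParams()

    try:
        coverage = loci_mod.build_coverage(reads_by_library, annotation)
        called = loci_mod.call_loci(coverage, annotation, p.locus)
        for l in called:
            loci_mod.infer_cap_status(l, coverage, manifest)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("call-loci", str(exc)) from exc
    log.info("called %d loci", len(called))

    seqs = {
        l.id: annotation.subsequence(l.chrom, l.start, l.end, l.strand) for l in called
    }

    # snoRNA detection
    cands: dict[str, snorna.CDSnoRNACandidate] = {}
    try:
        for l in called:
            found = snorna.assemble_cd_candidates(seqs[l.id], l.id, p.cd)
            if found:
                cands[l.id] = found[0]
    except Exception as exc:
        raise PipelineError("find-snorna", str(exc)) from exc

    # snRNA evaluation; a called locus passing the U6 rules can serve as the
    # U6 partner when none is supplied
    reports: dict[str, list[snrna.SnRNAReport]] = {l.id: [] for l in called}
    try:
        if u6_sequence is None:
            for l in called:
                if l.id in cands:
                    continue
                rep = snrna.evaluate_snrna_candidate(
                    seqs[l.id], "U6", params=p.snrna, locus_id=l.id
                )
                if rep.verdict:
                    u6_sequence = seqs[l.id]
                    log.info("using called locus %s as the U6 partner", l.id)
                    break
        for l in called:
            if l.id in cands:
                continue
            for kind in snrna.SNRNA_KINDS:
                if kind in ("U2", "U4") and u6_sequence is None:
                    continue
                reports[l.id].append(
                    snrna.evaluate_snrna_candidate(
                        seqs[l.id], kind,
                        u6_sequence=u6_sequence, params=p.snrna, locus_id=l.id,
                    )
                )
    except Exception as exc:
        raise PipelineError("find-snrna", str(exc)) from exc

    classifications: dict[str, str] = {}
    for l in called:
        if l.id in cands:
            classifications[l.id] = "snoRNA"
            continue
        passing = [r.kind for r in reports[l.id] if r.verdict]
        if passing:
            classifications[l.id] = passing[0]
            if len(passing) > 1:
                log.warning(
                    "locus %s passes multiple snRNA kinds %s; keeping %s",
                    l.id, passing, passing[0],
                )
        else:
            classifications[l.id] = "orphan"

    # methylation target prediction
    sites: list[methyl.MethylationSite] = []
    if targets:
        try:
            for cand in cands.values():
                sites.extend(methyl.predict_sites(cand, targets, p.duplex))
        except Exception as exc:
            raise PipelineError("predict-targets", str(exc)) from exc

    # differential expression
    de_results: list[diffexpr.DEResult] = []
    try:
        matrix = diffexpr.quantify(called, reads_by_library)
        de_results = diffexpr.test_de(matrix, manifest, p.de)
    except ValueError as exc:
        log.warning("differential expression skipped: %s", exc)
    except Exception as exc:
        raise PipelineError("diffexpr", str(exc)) from exc

    de_by_id = {r.locus_id: r for r in de_results}
    n_sites = {lid: 0 for lid in seqs}
    for s in sites:
        n_sites[s.snorna_id] = n_sites.get(s.snorna_id, 0) + 1
    rows = []
    for l in called:
        d = de_by_id.get(l.id)
        rows.append(
            {
                "locus": l.id, "chrom": l.chrom, "strand": l.strand,
                "start": l.start, "end": l.end, "length": len(l),
                "peak_depth": l.peak_depth,
                "class": classifications[l.id],
                "cap_status": l.cap_status,
                "overlap5": l.overlap5, "overlap3": l.overlap3,
                "n_methylation_sites": n_sites.get(l.id, 0),
                "log2fc": d.log2fc if d else float("nan"),
                "p": d.p if d else float("nan"),
                "q": d.q if d else float("nan"),
                "de_flag": d.de_flag if d else False,
            }
        )
    report = pd.DataFrame(rows)
    return PipelineResult(called, classifications, cands, sites, reports, de_results, report)


def run_from_files(
    genome: str | Path,
    gff: str | Path,
    manifest_path: str | Path,
    out_dir: str | Path,
    targets_path: str | Path | None = None,
    u6_path: str | Path | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """File-based front end: read inputs, run all stages, write result tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        sequences = {r.id: r for r in read_fasta(genome)}
        annotation = read_gff3(gff, sequences)
        manifest = read_manifest(manifest_path)
    except Exception as exc:
        raise PipelineError("load-inputs", str(exc)) from exc
    reads = {}
    for lib in manifest:
        if not lib.reads_path:
            raise PipelineError("load-inputs", f"library {lib.id} has no reads_path")
        try:
            reads[lib.id] = read_reads_bed(lib.reads_path)
        except Exception as exc:
            raise PipelineError("load-inputs", f"{lib.reads_path}: {exc}") from exc
    targets = read_fasta(targets_path) if targets_path else None
    u6_seq = read_fasta(u6_path)[0].residues if u6_path else None

    result = run_pipeline(annotation, reads, manifest, targets, u6_seq, params)
    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    _loci_table(result).to_csv(out / "loci.tsv", sep="\t", index=False)
    if result.sites:
        _sites_table(result.sites).to_csv(out / "sites.tsv", sep="\t", index=False)
    if result.de_results:
        diffexpr.de_table(result.de_results).to_csv(out / "de.tsv", sep="\t", index=False)
    return result


def _loci_table(result: PipelineResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus": l.id, "chrom": l.chrom, "strand": l.strand,
                "start": l.start, "end": l.end, "peak_depth": l.peak_depth,
                "cap_status": l.cap_status,
                "overlap5": l.overlap5, "overlap3": l.overlap3,
            }
            for l in result.loci
        ]
    )


def _sites_table(sites: list[methyl.MethylationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snoRNA": s.snorna_id, "box": s.box_kind, "target": s.target_id,
                "position": s.position, "label": s.label,
                "wc": s.duplex.wc_count, "gu": s.duplex.gu_count,
                "mismatch": s.duplex.mismatch_count,
            }
            for s in sites
        ]
    )


# ---------------------------------------------------------------------------
# flat key=value configuration
# ---------------------------------------------------------------------------

_SECTIONS = {
    "locus": loci_mod.LocusParams,
    "cd": snorna.CDParams,
    "duplex": methyl.DuplexParams,
    "snrna": snrna.SnRNAParams,
    "de": diffexpr.DEParams,
}


def apply_config_overrides(params: PipelineParams, overrides: dict[str, str]) -> PipelineParams:
    """Apply flat ``section.field=value`` overrides; unknown keys are rejected."""
    for key, raw in overrides.items():
        if "." not in key:
            raise ValueError(f"unknown config key {key!r} (expected section.field)")
        section, name = key.split(".", 1)
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        obj = getattr(params, section if section != "locus" else "locus")
        fields = {f.name: f for f in dataclasses.fields(obj)}
        if name not in fields:
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(obj, name)
        if isinstance(current, bool):
            value: object = raw.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            value = int(raw)
        elif isinstance(current, float):
            value = float(raw)
        else:
            value = raw
        setattr(obj, name, value)
    return params


def read_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key=value`` config file (# comments allowed)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path} line {line_no}: expected key=value")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
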