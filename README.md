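# nmsrna — small-RNA annotation for nucleomorph genomes

Nucleomorphs are the relict nuclei of algal endosymbionts retained in
cryptophytes and chlorarachniophytes. Their genomes are tiny (370–700 kb),
gene-dense, and carry a reduced but functional RNA-processing apparatus:
spliceosomal snRNAs, C/D box snoRNAs that guide ribose 2′-*O* methylation of
rRNA, and expressed "orphan" loci of unknown function. `nmsrna` is a pipeline
for annotating these small RNAs from mapped small-RNA-seq data, aimed at
researchers working with miniaturized or otherwise reduced genomes where
off-the-shelf covariance-model searches fail on diverged sequences and
rule-based, structure-aware annotation is the practical alternative.

## What it does

* **Locus calling** — intergenic sRNA-expressing loci from per-library read
  coverage: maximal runs of pooled depth ≥ *d*min (gaps ≤ 5 nt merged, ends
  trimmed to 10 % of peak), required in *every* library, never fully inside a
  protein/rRNA/tRNA gene, with strand-aware 5′/3′ gene-overlap annotation and
  5′-cap inference from Terminator-exonuclease (TE) treated libraries
  (TE degrades 5′-monophosphate RNAs, sparing capped snRNAs/snoRNAs).
* **Degenerate motif search** — PatScan-style matching of IUPAC patterns with
  independent mismatch/insertion/deletion budgets, plus a composite
  two-helix-with-hairpin search (the U4 snRNA architecture).
* **C/D box snoRNA detection** — box motifs (C: RUGAUGA and the compensatory
  variants AUGAUU, GUGAAG; D: CUGA/AUGA; internal D′/C′: (U/A)UGA), validated
  through the kink-turn pairing register: with 1-based indexing from each
  box's 5′ end, C3·D4 and C4·D3 must form the two sheared G·A pairs, C6–D1
  must be Watson–Crick (compensatory substitutions allowed), and C5–D2 may be
  U–U or Watson–Crick. Guide windows are the ≤ 20 nt immediately 5′ of the
  D and D′ boxes.
* **2′-O-methylation target prediction** — each guide's reverse complement is
  slid along the target RNAs; accepted duplexes (≥ len−1 paired, ≤ 1 mismatch,
  ≤ 2 G·U) predict methylation by the **+5 rule**: the target nucleotide paired
  to the guide base five residues upstream of the box, i.e. window start + 4
  (0-based). Predicted sites are mapped through rRNA multiple alignments and
  compared with snOPY-style reference tables to call conserved sites and
  putative snoRNA homologs.
* **snRNA evaluation** — per-kind mandatory rules: U1, the 5′-splice-site
  binding motif ACUUAC (antisense of the GUAAGU donor) at the 5′ end; U2, a
  GUAG branch-point interaction motif plus ≥ 2 intermolecular helices with U6;
  U4, two long U4/U6 helices with the 5′ stem-loop between them; U5, the
  invariant loop I (UGCCUUUUACY, ≤ 6 mismatches) closed by a ≥ 4 bp stem;
  U6, ACAGAGA plus a 3′ U-tract. Branch-point adenosines in introns are
  predicted from the DURAU/YURAC motif 2–6 nt upstream of the 3′ splice site
  by bulging the A that leaves the remaining bases paired to U2.
* **Differential expression** — locus counts per library, CPM/TPM, and
  light/dark testing with an exact negative-binomial test under a common
  conditional-ML dispersion (a simplified edgeR-classic engine; Welch t on
  log2-CPM available via `de.method=welch`). A locus is differentially
  expressed when |log2FC| ≥ 1.3 and BH-FDR < 0.05.
* **Synthetic data** — a generator that plants all of the above in a
  nucleomorph-like genome (geometric ~130 nt intergenic spaces, 13–43 nt
  gene overlaps, a truncated snoRNA pseudogene, one 6-fold dark-induced
  locus) and simulates replicate libraries with negative-binomial counts and
  TE retention by 5′-end class, so the full pipeline is testable offline.

## Worked example

```sh
nmsrna run --simulate --seed 42 --out demo
```

simulates the default data set (120 kb genome, 20 snoRNAs, 5 snRNAs,
5 orphans, 2×2 light/dark libraries + 1 TE library) and runs every stage.
Output (`30 loci; report -> demo/report.tsv`), summarized:

| quantity | value |
|---|---|
| loci called | 30 (recall 1.00 / precision 1.00 vs planted truth) |
| classes | 20 snoRNA, one each of U1 U2 U4 U5 U6, 5 orphan |
| cap status | 25 capped-like, 2 monophosphate-like, 3 ambiguous |
| differentially expressed | `locus_0018` (orphan), log2FC = 2.35, q = 1.3e-4 |

`demo/report.tsv` holds one row per locus (class, cap status, gene overlaps,
methylation-site count, DE statistics); `demo/sites.tsv` lists predicted
2′-O-methylation sites, e.g. `locus_0001 D 5.8S 12 5.8S-C13 12 0 0` — a
perfect 12-bp duplex predicting methylation of 5.8S rRNA C13. The only DE
locus is the planted dark-induced orphan; snoRNAs and snRNAs are
constitutive, and all capped-like calls correspond to planted capped loci.

Individual stages are available as `nmsrna simulate / call-loci / scan /
find-snorna / predict-targets / find-snrna / diffexpr`, and programmatically
through `nmsrna.pipeline.run_pipeline`.

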