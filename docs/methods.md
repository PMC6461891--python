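# Methods

This note records the models and procedures implemented in `nmsrna`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Conventions

Sequences are uppercase RNA (`ACGUN`); DNA input is converted on read and
ambiguity codes other than N become N with a warning, so degeneracy lives only
in search patterns. All intervals are 0-based half-open internally; GFF3
(1-based inclusive) and BED (0-based half-open) are converted at the format
boundary. BED6 score is reused as collapsed-read multiplicity (0/empty = 1).
Base pairs in helices, hairpins and duplexes are Watson–Crick plus G·U wobble
unless a rule says "strictly Watson–Crick".

## Locus calling

Candidate loci are maximal runs of pooled (all-library) depth ≥ `depth_min`
(default 3) with sub-threshold gaps ≤ `gap_max` (5 nt) merged; ends are
trimmed to the outermost positions with depth ≥ `end_frac` (0.1) of the run
peak. A candidate is retained only if every library contributes ≥
`support_min` (3) reads, it is ≥ `min_locus_len` (16 nt, the shortest read
length kept by typical sRNA pipelines), it is not fully contained in a
CDS/rRNA/tRNA feature, and it does not overlap an rRNA/tRNA feature at all
(rRNA/tRNA degradation fragments dominate sRNA libraries, so any overlap is
disqualifying). These thresholds are a reproducible proxy for the manual peak
curation such data normally receive and are all exposed as configuration.
Gene overlaps at locus ends are reported in transcript orientation (on the
minus strand the genomic right-hand end is the 5′ overlap).

Raising `depth_min` cannot create loci on unimodal peaks; on multimodal
plateaus a higher threshold can split one gap-merged run into two, so the
"fewer loci at higher thresholds" behaviour is a property of peak-shaped
coverage, not of arbitrary coverage (stated in the corresponding test).

Cap inference compares reads-per-million in TE-treated libraries against
untreated libraries grown under the same condition (so condition-specific
induction cancels); the ratio thresholds are 0.5 (capped-like) and 0.2
(monophosphate-like), between which a locus is ambiguous. With one TE library
and negative-binomial noise the capped-like call rate on truly capped loci is
~97 % (measured over 200 simulations); the residual ambiguity is sampling
noise in the single TE library, not a systematic bias.

## Degenerate pattern search

The matcher aligns an IUPAC pattern to subject substrings under three
*independent* budgets — mismatches, insertions (extra subject bases),
deletions (skipped pattern letters) — not a summed edit distance, following
the search-tool convention in which the three limits are stated separately.
Degenerate letters match their class at zero cost; subject N never matches.
Per start position the best alignment (minimal total cost, then fewer indels,
then leftmost end) is reported; overlapping matches from different starts all
appear. The dynamic program keeps Pareto-minimal budget triples per state;
equivalence with an exhaustive budget-state enumeration is asserted on
hundreds of random instances. The reverse-complement mirror property is exact
in the mismatch-only regime; with indels the per-start reporting convention is
start-anchored and the mirrored problem is end-anchored, so the property is
tested with indel budgets of zero.

The two-helix search (U4 architecture) looks for reverse complements of both
interaction helices, by default with the helix-II-pairing region 5′ of the
helix-I-pairing region, a spacer of 20–120 nt (the helix spacing is not
constrained by any published measurement; this envelope comfortably contains
known U4 5′ stem-loops), and a hairpin in the spacer: two antiparallel
substrings pairing base-by-base, stem ≥ 5 bp, loop ≥ 3 nt. The hairpin check
is combinatorial, not thermodynamic — the constraint being enforced is
topological (a stem-loop must exist between the helices), and rule-based
checks keep the search deterministic and dependency-free. Budgets apply per
helix.

## C/D box snoRNAs and the K-turn register

Box sets: C = {RUGAUGA, AUGAUG, AUGAUGA, AUGAUU, GUGAAG}, D = {CUGA, AUGA},
C′/D′ = {UUGA, AUGA}. The two noncanonical C entries cover compensatory
variants in which the C6–D1 pair is restored by a double substitution
(AUGAUU with a D-box 5′ A) or the U–U pair at the base of stem II is replaced
by Watson–Crick A–U (GUGAAG, whose 5′ G also matches the eukaryotic 5′-purine
consensus).

The pairing register is applied with 1-based indexing from each box's 5′ end:
(C3,D4), (C4,D3), (C5,D2), (C6,D1). Validity requires the two sheared G·A
pairs in fixed orientation (C3=G with D4=A; C4=A with D3=G), Watson–Crick at
C6–D1, and U–U or Watson–Crick at C5–D2 (a C–U pair there destabilizes
L7Ae/Snu13 binding and invalidates). A 7th C-box nucleotide is treated as
bulged and unpaired, so 6- and 7-nt C boxes validate identically.

Candidate assembly requires the C box to start within 12 nt of the locus 5′
end, the D box to end within 12 nt of the 3′ end, a valid K-turn, and a total
length of 50–250 nt (mature C/D snoRNAs are rarely shorter than ~50 nt; the
upper bound admits the long SNORD14-like class). An internal D′ with a C′
2–12 nt downstream is optional; shortened C′ motifs are accepted only at the
internal positions. No terminal stem is required. Guides are the ≤ 20 nt
immediately 5′ of D and D′, truncated at the nearest upstream box. On 100 kb
of random sequence scanned in 150-nt windows the detector emits ≈ 0–1
candidates.

## Methylation target prediction

Duplexes are contiguous and antiparallel (no bulges): the guide's reverse
complement is slid along the target and a window is accepted with
wc + gu ≥ len(guide) − 1, ≤ 1 mismatch, ≤ 2 G·U, and a strictly Watson–Crick
pair at the +5 position. Guides shorter than 9 nt are rejected (too little
specificity to call a target). With the box-adjacent guide base as offset 1,
the +5 rule places the methylated nucleotide at target-window start + 4
(0-based); every emitted site carries its duplex so the invariant is
assertable on output. These strict defaults deliberately under-call relative
to permissive thermodynamic tools; loosening `min_pairs`/`max_mismatch` in
configuration trades precision for sensitivity. Bulged duplexes are a known
limitation of this version.

Cross-species conservation maps a predicted site's ungapped position to its
alignment column (one alignment per rRNA family; a site and a reference row
are only compared within the same alignment) and flags sites sharing a column
with a verified reference site. The homolog flag additionally requires ≥ 0.70
identity between the 3′-anchored (box-proximal) guide ends — a sequence-level
stand-in for covariance-model homology, chosen because guides are the most
conserved segment of homologous snoRNAs.

## snRNA rules

Mandatory rules per kind (Sm/Lsm-site hits are reported but never veto, since
the Sm consensus is weakly defined): U1 — ACUUAC starting within the first
12 nt (the motif's reverse complement is the GUAAGU donor site); U2 — GUAG in
the 5′ half plus ≥ 2 helices of ≥ 6 bp with U6 (the canonical three U2/U6
helices often merge under a contiguous-run model, hence ≥ 2); U4 — two
helices with U6 of ≥ 9 bp each plus a hairpin in the inter-helix spacer.
The U4 helix floor is higher than the generic 6 bp because natural U4/U6
helix I alone is ~11 bp and, with G·U wobble admitted, two ≥ 6 bp runs
against any U6 occur in about a third of random 120-mers; at ≥ 9 bp the
false-pass rate on random sequence is ≈ 0.1 %. U5 — loop I (UGCCUUUUACY)
with ≤ 6 mismatches *and* a flanking stem of ≥ 4 pairs: at 6 mismatches the
11-nt motif alone is nearly saturating, so specificity rests on the stem.
U6 — ACAGAGA plus ≥ 4 U in the last 10 nt (Lsm binding).

Branch points: the DURAU motif (fallback YURAC) whose 3′ end lies 2–6 nt
upstream of the intron's AG; within a window anchored at the motif 3′ end (at
most one base longer than the U2 branch-point interaction region) the branch
adenosine is the 3′-most A whose removal leaves the remaining bases exactly
reverse-complementary to a contiguous stretch of the U2 region — the bulged-A
geometry of the U2–branch-site helix. Ties resolve 3′-most, matching the
3′-proximal location of the motif.

## Differential expression

Reads are assigned to a locus when ≥ 50 % of the read overlaps it; counts are
multiplicity-weighted. CPM and TPM follow the standard formulas (TPM columns
sum to 10⁶). TE-treated libraries are excluded from the light/dark contrast
by default — the treatment is a biochemical selection, not a condition.

The default test is a simplified edgeR-classic engine: counts are scaled to
the geometric-mean library size, a single negative-binomial dispersion
(var = μ + φμ²) is estimated by maximizing the conditional likelihood given
per-condition replicate sums, condition totals are modelled as NB with
dispersion φ/n, and a two-sided conditional exact test is applied to the dark
total given the overall total. A per-locus Welch t-test on log2(CPM + 0.5) is
available (`de.method=welch`) but, unable to share dispersion information
across loci, it has roughly a quarter of the exact test's power at 3
replicates and realistic dispersion — which is why it is not the default.
The DE call itself is fixed: |log2FC| ≥ 1.3 (pseudocount 0.5 on CPM means)
and Benjamini–Hochberg FDR < 0.05.

At dispersion 0.1, about 0.3 % of constitutive locus draws genuinely exhibit
|observed log2FC| ≥ 1.3 with replicate-consistent counts (the NB right tail);
any calibrated test flags these, so a small per-experiment false-flag rate
(measured ≈ 5–15 % of simulated experiments with ~30 loci) is a property of
the data-generating process, not of the test. Type-I control is verified
separately on permuted labels (≤ 5 % of loci flagged).

## Synthetic data generator

The generator emulates: a gene-dense ~120 kb genome with geometric intergenic
spaces (mean 130 nt, minimum 20 nt); SSU/LSU/5.8S rRNA genes whose sequences
double as methylation targets; 20 planted snoRNAs (every 6th/7th carrying the
compensatory box variants) whose guides are exact antisense copies of rRNA
windows, so the +5-rule site is known by construction and self-checked at
generation time; the five snRNAs as fixed motif/helix cores joined by seeded
random padding; five orphans; a 34-nt truncated snoRNA pseudogene lacking the
C′/D boxes with zero expression (detector negative control); and a fraction
(default 0.3) of sRNAs overlapping a flanking CDS by 13–43 nt, mostly at the
3′ end, as seen for nucleomorph transcripts.

Three generator policies keep the planted truth unambiguous, and are the main
sense in which passing tests speak to pipeline correctness rather than to
real-data performance: (i) snoRNA guide windows are drawn only from rRNA
windows whose reverse complement contains no UGA, so guides can never harbour
spurious box motifs and planted box coordinates are unique; (ii) snRNA pads
are rejection-sampled so each planted snRNA passes exactly its own kind's
rules, is no accidental duplex target of a planted guide, and orphans pass no
detector; (iii) the D′–C′ spacer is padded so every planted snoRNA clears the
detector's 50-nt floor. Real loci offer no such guarantees: overlapping
genes, diverged boxes, paralogs and partial motifs will all degrade precision
and recall relative to the synthetic figures.

Libraries: per expressed locus and library, counts are negative-binomial
(mean 200, dispersion 0.1; Poisson at dispersion 0); dark-induced loci are
scaled 6-fold in dark libraries; TE libraries retain 0.9 of capped and 0.05
of 5′-monophosphate locus counts. Read lengths are uniform on 18–76 nt
clipped to the locus; 5′ offsets are geometric (p = 0.2) at the locus 5′ end
for 70 % of reads and uniform over the body for the remaining 30 %
(degradation fragments) — without the internal fraction, loci longer than the
maximum read length would never be covered at their 3′ ends. Uniform
background noise (expected depth 0.3, i.e. a tenth of the calling threshold)
is scattered genome-wide so locus calling must actually reject noise. No
sequencing errors, adapters or quality scores are simulated. All randomness
flows from one seeded generator; identical seeds give byte-identical outputs.

Default library design is 2 light + 2 dark + 1 TE (light); differential
expression power figures are quoted at 3 replicates per condition, the
smallest design where the planted 6-fold induction is recovered in ≥ 95 % of
simulated experiments.

## Problem sizes and runtimes

Test and acceptance problem sizes were chosen to exercise every rule while
keeping a full run near a minute on one CPU: oracle equivalence on 200 random
instances per scanner (subjects ≤ 200 nt, budgets ≤ 2), the default 120-kb
synthetic data set for recovery, 100 simulated experiments for DE power, 200
for cap inference, 1,000 random draws for the U4 negative control, 100 kb for
the snoRNA false-positive scan, and a 4-kb random sequence for the composed
two-helix oracle check.

## Known limitations

Contiguous (bulge-free) guide duplexes; combinatorial rather than
thermodynamic structure checks; no H/ACA snoRNA or pseudouridylation-site
detection; no minor-spliceosome snRNAs; single-chromosome synthetic genomes;
pre-mapped read intervals as input (no alignment or trimming); multi-mapping
reads are whatever the upstream mapper collapsed them to.
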