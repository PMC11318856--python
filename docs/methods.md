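# Methods

This note documents the models and procedures implemented in
`prophagekit`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where the
underlying biology leaves the formalization open.

## Scope and inputs

The pipeline consumes *annotations*, never nucleotide sequence: an
annotated chromosome (feature-table TSV, GenBank or GFF3) in which each ORF
carries a functional category (one of the PHROG-style families:
integration/excision, transcription regulation, replication,
packaging/capsid, connector, tail, lysis, moron/accessory, other, unknown)
and optional trait flags naming specific gene identities (integrase, large
terminase, tail sheath, anti-CRISPR, ...).  Gene calling, functional
annotation, promoter prediction and completeness estimation are upstream
tools' jobs; their outputs are this package's inputs.  Coordinates are
1-based and inclusive everywhere (`region_length(s, e) = e − s + 1`).

Reverse-packaged prophages are mirrored into a canonical
packaging-forward frame (`canonicalize_orientation`, an idempotent,
span-preserving reflection that also applies to promoter positions) before
any pattern matching, so all grammars below are written left-to-right.

## Module conformance and hit confirmation

A candidate hit is confirmed as a prophage or prophage remnant iff it
contains a gene cluster conforming to at least one of the five classical
phage modules.  A module cluster is ≥ 2 ORFs of the module's category
family, co-oriented, with at most 2 interspersed ORFs of any other kind
between members; tail and lysis additionally accept single-gene evidence,
because genuine single-tail-gene phages exist.  Both the 2-ORF minimum and
the 2-ORF gap tolerance are `CurationConfig` parameters.

The gap rule deliberately allows *any* interspersed ORF rather than only
unannotated ones: the canonical lysogeny arrangement
integrase(+) / cI(−) / cro(+) places a divergent family-category gene
between co-oriented members, and a stricter rule would dissolve the
cluster that makes the region recognizable in the first place.

Candidate hits are first unified with an interval union: two hits merge
when separated by at most `max_gap` intervening bases.  The default is
`max_gap = 0` (overlap/abutment only).  Distinct prophages can sit within
a handful of base pairs of one another — in the packaged fixture two
adjacent prophages are 8 bp apart — so any permissive gap fuses real
regions, whereas duplicate detector hits overlap their parent region and
merge at gap 0.

## Defect taxonomy

Defects are read from gene architecture alone:

* **split_integrase** — two adjacent co-oriented integrase ORFs, each
  below the truncation threshold, in a region with no full-length
  recombinase: the fragments are read as one gene split by a frameshift.
* **truncated_integrase** — every integrase ORF is below threshold and no
  split call was made.  A full-length (≥ threshold) recombinase elsewhere
  in the region is what *discriminates* the two calls: when independent
  integration machinery exists, small adjacent integrase ORFs are read as
  truncated relics rather than as the region's sole, split integrase.
* **missing_terminase_or_portal** — a packaging/capsid module is present
  but no ORF carries the large-terminase or portal trait.
* **intron_split_gene** — a reverse-transcriptase/maturase ORF immediately
  flanked by two co-oriented ORFs sharing a helicase or DNA-polymerase
  trait (a group II intron inserted into a replication gene).
* **misoriented_late_orf** — an ORF strictly inside a tail or lysis
  cluster span oriented against the cluster strand, breaking the late
  operon.
* **mosaic_region** — two or more disjoint lysogeny-control or
  DNA-replication clusters: the signature of consecutive integration /
  recombination events stacking phage remnants.

The integrase truncation threshold defaults to 200 aa: functional phage
integrases run roughly 300–450 aa, and observed truncation products sit
in the 150–200 aa range, so 200 separates the two populations cleanly.

## Categorization

`categorize(completeness, defects)` maps the upstream 0–100 completeness
score through fixed bands: exactly 100 and defect-free → functional;
exactly 100 with any defect → unknown (manual-override demotion);
strictly between 60 and 100 → unknown; 60 or below → defective; missing →
unclassified.  The published bands (">60–<100", "<60") leave the value 60
itself unassigned; it resolves low (defective), and functional requires
*exactly* 100.  The function is monotone: lowering the score or adding a
defect never promotes a region (property-tested).

## Mosaic delineation

Mosaic regions are scanned left-to-right in the canonical frame.  An ORF
with a Mu-transposase or integrase trait, or of replication category,
*opens* a phage sequence; a tail-category or recombinase-trait ORF is a
*closer*.  When a new opener appears after at least one closer, the
current sub-region ends at its last closer and the next sub-region adopts
every ORF after that closer — so the repressor/Ner switch genes that
precede a Mu transposase belong to the phage that follows, and consecutive
phages tile the mosaic.  When a new opener appears with *no* closer seen
(a remnant that lost its tail end), the boundary falls immediately before
the opener, provided the opener is a fresh event (more than
`opener_gap_orfs` = 25 ORFs past the previous opener; smaller spacings are
module structure inside one phage).  Sub-regions partition the ORFs they
cover and are lettered in phage order; each is then profiled, typed and
categorized with its own completeness score.  Sub-region base-pair spans
may overlap by a few bp where ORFs at a junction overlap; the partition
invariant applies to ORF sets.

## Lysogeny-switch typing

Three grammars, evaluated in specificity order (first match wins):

1. **ImmR/ImmA** — an ImmA-like metallo-endopeptidase adjacent (≤ 1
   intervening ORF) and co-oriented with an HTH regulator (ImmR), whose
   next downstream HTH is opposite-oriented.  ImmA is the most specific
   marker, so this is tested first.
2. **C/Ner** — a divergently transcribed HTH pair whose downstream partner
   is ≤ 80 aa (Mu's Ner is 76 aa), with a Mu-transposase ORF within 10
   ORFs downstream.  The repressor-to-Ner window also tolerates up to 10
   inserted ORFs, since real Mu-type regions interleave hypothetical genes
   between the two.  Mu-transposase adjacency is what separates C/Ner from
   a generic divergent HTH pair.
3. **CI/Cro** — the fallback for divergent-pair architectures: two
   adjacent divergently transcribed ORFs within the lysogeny span (before
   the first replication/packaging/tail/lysis module member), at least one
   an HTH regulator.

Promoter calls below score 0.87 are discarded before typing.  Where at
least two retained promoters fall in the pair's shared intergenic region,
their orientation is reported (divergent / convergent / tandem); promoters
*support* but never *gate* a call — a CI/Cro architecture without promoter
data is still CI/Cro, with geometry `none`.  All windows are
`TypingConfig` parameters.

Morphology is called by trait precedence sheath > tape measure >
baseplate/fiber (myovirus / siphovirus / podovirus), untyped when no
marker trait occurs; the evidence lists the deciding ORFs.

## Accessory screen

A leaf stage that maps ORF trait flags through an editable TSV vocabulary
to accessory classes (RM system, TA system, diversity-generating,
anti-phage defence, host adaptation); unassigned ORFs longer than 5 kb are
reported as large-polyvalent-like.  An antitoxin with a cognate toxin in
the same region forms a complete TA system (phage defence); a solitary
antitoxin is reported as anti-phage defence *or a degenerate TA system* —
the evidence cannot distinguish the two.  The summary also scans products
for classical moron keywords (exotoxins, immune-evasion factors) and flags
their absence.  Vocabulary edits cannot affect curation or typing, which
never read it.

## qPCR quantification

DNase treatment of a culture supernatant destroys free DNA but not DNA
protected inside capsids.  Per target: replicates are averaged with
non-amplifying wells imputed at the cycle cap (default 40, matching a
40-cycle protocol); ΔCq = mean treated − mean untreated; ΔΔCq subtracts
the housekeeper's ΔCq; fold change = 2^−ΔΔCq.  A target is *detected* when
its treated mean clears the no-template control by `ntc_margin` (default
0) cycles; the housekeeper is *fully degraded* when its treated mean is at
or above its NTC.  ΔΔCq is computed on condition means rather than
replicate pairs because plate-to-plate replicate pairing is generally not
recorded.  Useful identities, all property-tested: fold changes are
reciprocal in their arguments, invariant to a constant shift applied to
every Cq, and ranking by fold change under a shared housekeeper is the
inverse of ranking by ΔCq.

## Synthetic data and the study fixture

`generate_chromosome` plants prophages with specified module composition,
switch grammar, tail repertoire, packaging strand, defects (realized
literally: a split integrase is two adjacent sub-200-aa fragments, an
intron insertion is an RT ORF between two helicase halves, a mosaic is two
tandem λ-like sub-phages, and so on), accessory inventory and completeness
score, plus decoy gene clusters of household bacterial genes and
duplicate/overlapping hits — together with a ground-truth record per
region.  Everything is deterministic given the seed.  On noiseless output
the pipeline recovers every truth label exactly; the test suite asserts
100 % recovery over 100 random architectures.

What the generator does *not* emulate: nucleotide sequence (the pipeline
never reads it), annotation error (mislabelled categories/traits),
completeness-score noise (scores are planted, not computed from content),
overlapping genes, and operon structure beyond strand runs.  Passing tests
therefore demonstrate correctness of the curation logic given faithful
annotations, not robustness to upstream annotation mistakes.

The LM41 fixture reconstructs a published 15-prophage complement at
ORF-architecture level: coordinates, strands, tail-gene numbers, switch
synteny, defects, accessory inventory and completeness scores follow the
study; padding ORFs and exact gene lengths are synthetic, laid out to tile
each region's exact span.  Two deliberate quirks are preserved: one
region's printed size (41,690 bp) disagrees with its own coordinates
(which imply 41,886 bp) and is excluded from size checks; and two mosaic
sub-regions overlap by 14 bp at a junction.  The 29-hit candidate list
splits 15 true / 8 non-phage / 6 duplicates; the published account gives
only the total of 14 discarded hits, so the 8/6 split is an assumption.
Fixture Cq replicates are synthetic, constrained to the published ΔCq
values and orderings and the NTC relationships; published fold-change
means cannot be reproduced without the unpublished raw Cq values and are
deliberately not asserted.  Band-interior completeness scores (regions
reported only as ">60–<100" or "<60") are representative values inside
the reported band.

## Numerical and degenerate-input choices

* Interval code validates 1-based inclusive coordinates and rejects
  start > end everywhere; `merge_hits` treats gap = next.start − prev.end
  − 1, merges abutting intervals at `max_gap = 0`, and equals a
  brute-force pairwise union oracle on random inputs.
* ORF ordering is by start, ties by end then id; all scans use this order.
* Cq values must lie in (0, cap]; empty replicate lists are errors;
  `fold_change` matches the closed form 2^−(a−b) to 1e-12 relative.
* Degenerate typing inputs (no HTH, no promoters, empty regions) yield
  `undetermined` / geometry `none` rather than errors; delineation on a
  non-mosaic region is a contract error by design.

## Known limitations

* Completeness is consumed, never computed: the package deliberately does
  not reimplement AAI/CheckV-style completeness estimation, and the
  optional module-coverage heuristics one might imagine are out of scope.
* The defect taxonomy formalizes exactly the architectural anomalies
  described for curated prophages; "unusual features affecting viability"
  beyond these six patterns will not be flagged.
* Switch typing is synteny-based; a CI/Cro call does not prove repressor
  function, and regions whose switch genes are annotated only as
  hypothetical proteins will come back `undetermined`.
* The qPCR stage performs no amplification-efficiency correction and no
  significance testing; it quantifies and ranks, nothing more.
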