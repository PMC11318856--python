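# prophagekit

Curation, typing and release quantification of prophages in annotated
bacterial genomes.

Temperate phages integrate into bacterial chromosomes as prophages, and
many gut commensals are poly-lysogens carrying a dozen or more of them.
Raw prophage detectors (PHASTER-style scanners) over-call: their hit lists
mix real prophages, fragments of the same prophage reported twice, and
chromosomal gene clusters that merely look phage-like.  `prophagekit`
implements the downstream curation a phage biologist performs by hand, as a
tested, reusable pipeline for anyone characterizing the prophage complement
of a sequenced strain:

1. **Hit curation** — merge overlapping candidate hits, then confirm a hit
   as a prophage (or remnant) only if it carries a gene cluster conforming
   to at least one of the five classical phage functional modules
   (lysis–lysogeny control, DNA replication, packaging and capsid, tail,
   lysis).
2. **Completeness categorization** — combine an upstream AAI-based
   completeness score *c* with architectural defect flags:
   *c* = 100 with a clean architecture → *functional*; 60 < *c* < 100 →
   *unknown*; *c* ≤ 60 → *defective*; *c* = 100 but defect-flagged →
   demoted to *unknown*.  Detected defects: frameshift-split and truncated
   integrases, missing large terminase/portal, group II intron insertions
   splitting a replication gene, late-module ORFs flipped against their
   operon, and mosaic stacking of several phage remnants.
3. **Mosaic delineation** — recombination hotspots holding several
   consecutive Mu-type prophage remnants are split into sub-regions using a
   boundary grammar (transposase / replication protein opens a phage
   sequence; tail or recombinase closes it).
4. **Typing** — virion morphology from tail-gene content (sheath ⇒
   myovirus; tape measure without sheath ⇒ siphovirus; baseplate/fiber
   only ⇒ podovirus) and lysogeny-switch class from repressor synteny plus
   promoter orientation: λ-like CI/Cro (adjacent divergent HTH pair with
   divergent promoters), ICE*Bs*1-like ImmR/ImmA (metallo-endopeptidase
   co-oriented with its HTH repressor, next HTH divergent), and phage
   Mu-like C/Ner (divergent HTH pair with a small Ner-like partner and a
   Mu transposase just downstream).
5. **Accessory screen** — vocabulary-driven inventory of
   restriction–modification components, toxin–antitoxin systems,
   diversity-generating retroelements, anti-phage-defence factors
   (anti-CRISPRs, Mom/DarB-like, restriction alleviation) and candidate
   host-adaptation genes.
6. **qPCR release quantification** — DNase-protection qPCR analysis of
   spontaneously released phage: replicate aggregation with a 40-cycle cap
   for non-amplifying wells, ΔCq = Cq(treated) − Cq(untreated), the
   2^−ΔΔCq fold change normalized to a chromosomal housekeeper, and
   NTC-floor detection calls.

A synthetic-data generator plants prophage architectures with full ground
truth (modules, switch grammar, tail repertoire, defects, accessory genes,
decoy gene clusters, duplicate hits), so every stage is testable without
any downloads.  The package also ships a study fixture reconstructing the
15-prophage complement of the poly-lysogenic gut commensal *Clostridium
clostridioforme* LM41, against which the whole pipeline is validated.

## Worked example

Write the packaged study fixture, then run the full pipeline on its
candidate hits:

```sh
prophagekit fixture --out fx
prophagekit run \
    --annotations fx/lm41_feature_table.tsv \
    --hits fx/lm41_candidate_hits.tsv \
    --completeness fx/lm41_completeness.tsv \
    --promoters fx/lm41_promoters.tsv \
    --qpcr fx/lm41_qpcr_cq.csv \
    --out out
# 15 confirmed regions; outputs in out
```

The 29 candidate hits (15 prophages + 8 non-phage gene clusters + 6
duplicate hits) collapse to exactly 15 confirmed regions, categorized
4 functional / 2 defective / 9 unknown.  `out/region_summary.tsv` holds one
row per region plus one per mosaic sub-region; the 136-kb mosaic phi13 is
split into five sub-regions:

```text
region  start    end      length  ... completeness defects       category  morphology lysogeny_system
phi13   6632999  6769447  136449  ... 100.0        mosaic_region unknown   myovirus   c_ner
phi13a  6632999  6684039   51041  ...  99.65                     unknown   siphovirus undetermined
phi13b  6684149  6706426   22278  ...  49.4                      defective untyped    c_ner
phi13c  6706413  6714990    8578  ...  18.8                      defective untyped    undetermined
phi13d  6715266  6749468   34203  ...  94.11                     unknown   myovirus   c_ner
phi13e  6750116  6769447   19332  ...  41.2        missing_...   defective siphovirus undetermined
```

`out/qpcr_report.tsv` carries the DNase-protection analysis.  The
housekeeper's treated signal falls below its no-template control (fully
degraded bacterial DNA), while protected (encapsidated) phage targets stay
detectable; the smaller a phage's ΔCq, the more of its DNA was inside
capsids:

```text
target  treated_mean_cq  untreated_mean_cq  delta_cq  ddcq    fold_change  detected  fully_degraded
s10p    26.800           17.000             9.800      0.000   1           False     True
phi1    27.510           22.400             5.110     -4.690  25.81        True      False
phi2    31.470           23.100             8.370     -1.430   2.694       True      False
phi4    30.960           22.900             8.060     -1.740   3.34        True      False
```

phi1 ranks first by 2^−ΔΔCq fold change — the most abundant spontaneously
released phage in the culture supernatant.  (The fixture's raw Cq
replicates are synthetic; only their ΔCq differences, ordering and NTC
relationships are anchored to published measurements.)

The same stages are available as library functions
(`prophagekit.curate_chromosome`, `call_morphology`, `call_lysogeny`,
`screen_accessory`, `QpcrPanel.analyze`, `generate_chromosome`, ...) for
use on your own annotation tables (feature-table TSV, GenBank or GFF3).

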