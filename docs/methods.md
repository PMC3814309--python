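# Methods

This note documents the model behind `uvloh`, its default parameters, the
numerical conventions of the caller/classifier/statistics chain, and what
the synthetic-data generator does and does not emulate.

## Genome model

The default genome is a 16-chromosome diploid of 12.0 Mb with fixed
chromosome lengths loosely following the budding-yeast karyotype.  The two
homologs are abstract parental roles `P1` and `P2` (displayed red and
black); ~13,000 heterozygous SNPs are placed uniformly at random (seeded)
outside 20 kb terminal exclusion zones and outside the rDNA-like cluster, a
single 1.2 Mb interval (10% of the genome) on the right arm of chr12.  The
resulting mean inter-SNP spacing is ~0.87 kb, matching an array resolution
of about 1 kb.  Coordinates are 1-based inclusive internally; BED exports
are 0-based half-open.  chr05 carries the colony-color marker (an
ochre-suppressor-style insertion) at 33 kb on the `P2` homolog with the
centromere at 152 kb, defining a 119 kb selected interval; 0/1/2 marker
copies produce red/pink/white colonies.  The rDNA is one annotation
interval, not repeat units: events inside it are resolved only at interval
level (it carries no SNPs, as on the real arrays, which exclude repeats).
The exact per-chromosome repetitive exclusions of the real platform are
unknown; a uniform 20 kb per end stands in for them.

## Lesion and break model

UV dose *D* (J/m²) produces `Poisson(D × dimers_per_jm2)` pyrimidine-dimer
lesions uniformly over the diploid genome (both homologs, both strands);
the default 500 dimers per J/m² gives ~7,500 lesions at 15 J/m².  Dimer
placement is sequence-independent by default; `clustered_dimer_excess`
optionally places a fraction of lesions within the closely-opposed window
of an earlier lesion on the opposite strand, emulating the reported
dose-independent excess of near-opposed dimers (default 0, which keeps the
dose-scaling analysis clean).

Breaks derive from lesions in two ways:

* an opposite-strand pair on the same (unreplicated, G1) homolog separated
  by ≤ 75 bp becomes a **DSCB** at the pair midpoint with probability
  `dscb_from_opposed` (default 0.05) — excision of closely-opposed dimers
  leaves an unstable duplex whose breakage, after replication, yields two
  sisters broken at the same position;
* each remaining lesion independently becomes an **SCB** with probability
  `scb_rate_per_dimer` (default 0.012) — replication across an unrepaired
  excision gap or dimer breaks one sister.

SCB counts therefore scale linearly and DSCB counts roughly quadratically
with dose, which is the mechanism behind the dose dependence of the
SCB/DSCB balance.  The closed form for the expected number of
closely-opposed pairs under uniform placement is
`C(n,2) · ½ · (2dG − d²)/G²` (opposite strands, window d, genome length G);
at n = 7,500 on the 24 Mb diploid it evaluates to ~88.  Smaller published
estimates of this quantity depend on unstated assumptions (haploid vs
diploid length, one- vs two-sided window, strand handling); the operation
exposes these as parameters rather than tuning to any particular figure.

Sister-chromatid repair produces no LOH, so S/G2 breaks that would be
sister-repaired are pruned at generation: SCBs are retained with
`interhomolog_prob` (default 0.05).  DSCBs have no intact sister and are
always repaired off the homolog.  A Poisson-thinning cap
(`max_breaks_per_cell`, default 25) bounds pathological cells.  With these
defaults a 15 J/m² cell carries ~8 interhomolog repair events, red/white
sectored colonies arise at ~1%, and the DSCB share of breaks rises from
<1% at 1 J/m² to ~50% of events at 15 J/m².

## Repair model

The broken homolog is always the conversion **recipient**.  Each break
samples a pathway: SDSA (p = 0.40), double-Holliday-junction repair
(p = 0.545, resolving as a crossover with probability 0.578), or BIR
(p = 0.055); the implied per-break outcome mix (NCO 0.63 / CO 0.315 /
BIR 0.055) reproduces the detection-corrected published event ratios.
Conversion tracts are gamma-distributed (shape 2) around the break with a
uniformly random split of the length across the two sides.  Mismatch repair
is conversion-type (donor overwrites recipient) by default;
`restoration_prob` (0.05) restores the whole tract (no LOH), and
`patchy_repair_prob` (0.10) converts a random per-SNP subset, producing the
complex multi-transition classes at roughly the observed ~15% frequency.
A DSCB repairs both sisters: one follows the sampled pathway, the other
always converts without a crossover; with `dscb_equal_tract_prob` (0.5) the
second sister reuses the first's tract bounds (coincident resection ends →
a clean 4:0 tract), otherwise it draws independently (→ 3:1/4:0 hybrid).
Crossovers exchange all linkage distal to the tract with one donor
chromatid; BIR copies the donor from the break to the telomere.

**Tract-median calibration.** The drawn medians are per-chromatid
heteroduplex tracts.  The measured tract of an event merges the two
sisters' tracts (and, for crossovers, the whole conversion region proximal
of the exchange), which inflates measured lengths by ~25–30%.  The defaults
(3.85 kb non-crossover, 6.0 kb crossover-associated) are therefore
calibrated so the *measured* medians land near 4.9 kb (conversions
unassociated with crossovers), 7.6 kb (crossover-associated) and ~5.4 kb
overall — the regime this package targets.

## Segregation and readout

Each daughter receives one sister of each homolog; the two segregation
patterns are equiprobable, so a crossover yields reciprocal distal LOH (and
a red/white colony when it spans the marker interval) in exactly half of
simulations — the factor-2 detection correction used throughout the
statistics.  Chromosome loss can be injected (`lose_chromosome`) and yields
pink/red colonies.  Damage persisting into the second division is off by
default (most events occur before the first division); a flag adds
tri-sector (pink/white/red) color patterns without modeling granddaughter
genotypes.  The array readout emits per-SNP ratio pairs — heterozygous
(1, 1), homozygous (1.8, 0.2) for the retained parent — with truncated
Gaussian noise (`noise_sd`, default 0.10, chosen so that miscalls are rare
but NOCALLs occur at a realistic few percent).

Every simulated event is annotated post-segregation with its *observable*
label: what an ideal reader of the two noise-free sector tracks would
report, accounting for SNP support (≥ 2 SNPs to register, mirroring the
caller's min-run rule; 1 SNP suffices for a crossover chromatid's tract,
which reads contiguously with its exchanged terminal segment), crossover
segregation, conversion tracts that run into the terminal SNP (indistinct
from BIR), and min-run smoothing of patchy tracts.  An `obs_simple` flag
marks textbook patterns (non-patchy, non-fragmented, with a shared core for
two-sister tracts); classifier recovery is evaluated against events that
are alone on their chromosome, because in-isolation ground truth is
undefined when events overlap (such colonies are the field's complex
classes).

## Caller

`HOM_P1` requires ratio_P1 ≥ 1.4 and ratio_P2 ≤ 0.6 (symmetric for
`HOM_P2`); `HET` requires both ratios in [0.7, 1.3]; anything else is
`NOCALL`.  The real platform's numeric cutoffs are unpublished; these
defaults are calibrated on the simulator (≥ 99% of called SNPs correct at
noise 0.15) and exposed as parameters.  Segmentation relabels runs of
< `min_run` SNPs (default 2) as NOCALL and absorbs them, shortest first;
NOCALL never breaks a run.  Transitions carry inner/outer bounds — the last
called SNP of the left segment and the first of the right — the min/max
convention used for array breakpoints.  No HMM or smoothing window is
applied by default, keeping every call auditable.

## Classifier

LOH segments from the two sectors are clustered per chromosome; clusters
separated by more than 15 kb of shared heterozygosity are independent
events.  Decision rules, in order: whole-chromosome homozygosity in one
sector with the other fully heterozygous → chromosome loss; terminal LOH in
both sectors on the same arm with opposite parents → crossover (with
conversion if LOH extends proximal of the point where both terminal
segments have begun; the conversion SNPs' joint states give the pattern —
any both-homozygous-same-parent SNP ⇒ 4:0 evidence, one-sided ⇒ 3:1,
both ⇒ hybrid); terminal LOH in exactly one sector with nothing else →
BIR; interstitial LOH in one sector → 3:1 conversion; same-direction
interstitial LOH in both sectors → 4:0 when boundaries coincide within one
SNP (array resolution makes exact coincidence unobservable), hybrid when
overlapping with extension; everything else → complex, which absorbs all
leftover transitions so none are dropped.  Mechanism follows the pattern:
any 4:0 segment ⇒ DSCB, pure 3:1 ⇒ SCB.  The recipient homolog is the one
whose alleles were overwritten (the parent that became homozygous is the
donor); pure crossovers are ambiguous.  Tract bounds merge 3:1 and 4:0
segments and internal het gaps into a single tract: the minimal span is
first-to-last LOH SNP, the maximal span runs to the flanking called SNPs
(for crossovers, to the first SNP of the reciprocal region); the length
estimate is their mean, and midpoints for spatial statistics are taken on
the maximal span.  Crossovers with conversion on the unexpected sector and
similar two-break geometries are labeled complex with mechanism DSCB, one
event per cluster.

## Statistics

Median confidence limits use binomial order statistics (ranks
n/2 ± z·√n/2), the construction behind the standard printed tables.
Mann-Whitney is two-sided: exact for tie-free samples with n₁+n₂ ≤ 20
(verified against a brute-force enumeration oracle), otherwise the normal
approximation with tie correction.  Detection correction doubles observed
crossovers and reassigns the hidden half from the conversion tally.
Control normalization subtracts untreated counts scaled by the ratio of
colonies examined; per-kb frequencies divide by interval length after
applying the detection factor (2 for crossovers, 1 for BIR/conversions),
with rounding to two significant figures applied only at reporting.
Regional expectation tests report both the exact binomial and chi-square
(no continuity correction) p-values.  Element enrichment is a permutation
test: tracts of the observed lengths are re-placed uniformly on the
SNP-covered genome (length-weighted chromosome choice) — observed tracts
can only exist where the array sees — with a two-sided empirical p-value
with the +1 correction and Benjamini-Hochberg adjustment across classes;
a permutation scheme was chosen over an analytic expectation because it
conditions on the observed tract-length distribution.  AA/TT dinucleotide
frequencies count overlapping dinucleotides with both strands collapsed
(AA and TT together); regional comparisons use Fisher's exact test on the
dinucleotide counts.

## rDNA marker assay

Marker phase: homolog H1 carries HYG (immediately centromere-proximal to
the cluster) and TRP1 (inside it); H2 carries URA3 (immediately distal);
CEN12–HYG is 300 kb and HYG–URA3 1170 kb.  Phenotypes are derived by
propagating marker content through the event geometry; 5-FOA separates
URA3/URA3 crossover products (no papillae) from heterozygous BIR products
(papillae).  Classification inverts the prediction over all categories.
Exhaustive enumeration shows the three BIR-U classes (BIR initiated on the
URA3 homolog, one per interval) produce *identical* phenotype pairs on the
four scoring media, so their interval cannot be recovered from phenotype
alone: `classify_colony` returns the event kind exactly and lists all three
intervals as candidates.  The BIR-H class in TRP1–URA3 differs from the
parental pattern only on 5-FOA and is treated as phenotypically silent, so
its count is imputed as equal to the BIR-U count in the same interval.
Intrachromosomal-event subtypes (single-strand annealing, pop-out, unequal
sister exchange) are not distinguished.  Normalization and per-kb
crossover rates use the machinery above with detection factor 2.

## What the generator does and does not emulate

It emulates: dose-proportional lesion loads; the linear/quadratic origin of
SCBs and DSCBs; the repair-pathway mix, tract-length regime, patchy-repair
complexity fraction and multi-event-per-cell load of heavily irradiated
G1 cells; half-detection of crossovers; colony color genetics; and
array-like two-channel ratios with Gaussian noise.  It does not emulate:
real sequence (so sequence-dependent damage distributions, AA/TT effects
and the rDNA's compositional coldness are only representable through the
optional weight track and the composition utilities on user-supplied
sequence); transcription-coupled repair, checkpoint signaling or
replication-fork geometry; repeat-mediated rearrangements (Ty-Ty events);
and probe-level array artifacts (spatial effects, GC bias).  Passing tests
therefore demonstrate correctness of the calling/classification/statistics
machinery under realistic event geometries and noise, not fidelity to any
particular array platform's error structure.

To analyze real composition data, supply sequence to
`dinucleotide_freq` / `compare_dinucleotide_regions` (e.g. whole-genome vs
rDNA sequence reproduces a genome-wide AA/TT frequency near 0.217 against
~0.190 in the rDNA); to test damage-repair region hypotheses, supply the
regions as an annotation class to `element_enrichment`.

## Problem sizes and determinism

The test suite simulates cohorts of 100–500 colonies and the acceptance
script 300 colonies with 10,000 segregation replicates and 60 paired
dose-response replicates — sizes at which the reported medians and
fractions are stable to a few percent across seeds.  All randomness flows
from one root seed through `numpy.random.SeedSequence` spawning, so every
simulation, permutation test and acceptance run is exactly reproducible
from its seed.
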