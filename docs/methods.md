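# Methods

This note documents the models, rules and numerical choices behind
`polyforge`, and what the bundled simulator does and does not emulate.

## The biological setting

A young allotetraploid carries two subgenomes, AA and BB, inherited from
diploid progenitors that diverged around 0.034 synonymous substitutions per
site before hybridization. Only the A-lineage diploid survives; the BB
donor is unknown. Incipient diploidization shows up as (i) de novo point
mutations accumulating faster in the tetraploid than in the diploid
(polyploid masking relaxes selection), (ii) homeologous exchanges that
replace chromosomal regions with their counterpart from the other
subgenome, (iii) asymmetric gene loss (fractionation) favouring one
subgenome, and (iv) mild expression dominance of the retained subgenome.

## Subgenome partition

Diploid reads mapped onto the tetraploid cover only AA-derived regions, so
per-window depth is bimodal. The genome peak depth is estimated as the
mode of the integer-binned histogram over windows with positive depth, ties
broken toward the larger depth; the source method says only "genome peak
depth" without naming an estimator, so the integer-mode choice is ours and
is covered by tests. A window is provisionally AA when depth is strictly above half
the peak ("higher than" is read as strict; a window at exactly half-peak
goes BB). Runs shorter than `min_run = 5` windows are flipped to the
opposite origin; flipping is applied left to right and repeated to a fixed
point. The iteration order is not specified by the underlying method; the
left-to-right choice is documented and the alternating-label worst case is
tested (it converges to a single block). Junction refinement to base-pair
resolution (originally done by re-aligning junction intervals) is out of
scope; block boundaries are window-resolution.

## Conserved-interval construction

Four-way alignment blocks are cut wherever any row carries a contiguous
gap run of ≥ 100 bp; the union of overlapping long runs across rows is
excised once. Surviving intervals are kept when the *shortest ungapped
row* exceeds 500 bp (lengths are measured in bp, not alignment columns)
and four-way identity is at least 0.80. "Overall identity across the four
sequences" is not defined more precisely in the source method; we define
it as the fraction of gap-free columns in which all four rows carry the
same base, with N never matching. The 80% threshold is applied
inclusively (an interval at exactly 0.80 is kept); both the definition and
the inclusivity are flags.

## Mutation calling and the 96-context spectrum

A column yields a call iff all four rows hold a plain base, exactly one
row differs from the other three identical rows (the 1:3 ancestral
genotype rule), and the five columns on each side are gap-free and
identical across all rows. The flank guard suppresses alignment-error
artifacts; two true variants within 5 bp of each other are both rejected
(no MNV handling — the method scores single-nucleotide events). Context
bases are read at the immediately flanking columns, which the flank rule
guarantees to be unanimous. Classification reverse-complements the
(5′, anc→der, 3′) triple when the ancestral base is a purine, yielding six
pyrimidine classes × 16 contexts = 96 bins ordered alphabetically within
class. A flanking N leaves the call but excludes it from both spectra.

Calls are tallied for all four rows, but B-subgenome-carrier calls are
flagged non-interpretable: with no BB diploid in the alignment, a
progenitor-divergence site (BB base vs three AA bases) produces exactly
the same 1:3 pattern as a true BB de novo mutation, with the ancestral
state mis-polarized. Lineage contrasts therefore use the tetraploid-A row
against the first diploid. The paired *t*-test pairs counts per
homeologous chromosome by default (per block behind a flag); the original
pairing unit is unstated.

## Homeologous exchanges

Depth ratios are per-window depth over the sample's genome-wide mean
(mean, not mode — resequencing samples cover both subgenomes). Candidate
duplications are maximal runs inside the open band (1.5, 3); boundary
values are excluded ("higher than"/"less than"). Runs separated by at most
two out-of-band windows are merged — at 16× coverage roughly 8% of
windows of a true 2× segment fall out of band by Poisson noise alone, and
without gap tolerance long events fragment below the size threshold. A
candidate becomes a segmental call only if its homeologous interval (from
the synteny map) averages below 0.5× and either interval spans ≥ 20 kb;
the deletion requirement is what keeps precision high despite the
permissive run merging. Sub-20 kb events are scored per homeologous gene
pair with the same bands; window means cannot resolve sub-window events,
so gene-level depth comes from per-gene read counts (the simulator emits
them directly). Balanced 2:2 swaps leave sample depth flat and are found
as origin islands in the diploid-coverage partition whose mapped partner
interval is a reciprocal island; the flanking tracts must each span
`min_flank = 10` windows (the source describes "long tracts" without a
number). 3:1 events are scored on candidate non-homeologous interval
pairs with acceptance bands (1.25, 1.75) and (0.25, 0.75). Event identity
across samples is reciprocal interval overlap ≥ 0.8 (cross-sample matching
is not defined in the source). The chi-squared on direction totals is
emitted with an explicit ambiguity flag: the original test's table
construction is unstated, and ours (a goodness-of-fit on occurrence
totals) is labelled non-equivalent. Junction-spanning read confirmation
is out of scope; evidence is depth-only.

## Gene curation

The guide model's CDS columns are projected onto a target row. If less
than 20% of guide CDS columns are alignable the copy is deleted — the
alignable-fraction rule separating deletion from pseudogene is not stated
in the source; 0.2 is our declared, configurable default. Otherwise the
target CDS (including target insertions inside the CDS span) is translated
in the guide frame: any indel run with length ≢ 0 (mod 3) is a frameshift
defect, any stop strictly before the terminal codon a premature stop;
either makes the copy a pseudogene, and a 6 bp in-frame deletion leaves a
copy structurally intact (structural intactness is not functionality — a
known in-frame variant of a pigmentation gene is a functional candidate
despite classifying intact). Heterozygous-variant rescue is out of scope:
inputs are haploid consensus rows. Fractionation is a 2×2 chi-squared of
lost (pseudogene + deleted) vs retained per subgenome, no continuity
correction; p-values below 2.2e-16 are reported with the conventional
floor label plus an analytic log10 p.

## dS and dating

NG86 counting: per-codon synonymous site fractions (changes to stop codons
count as non-synonymous), averaged over both sequences; observed
differences in multi-difference codons are averaged over all orderings of
the changes with equal weights, orderings through stop codons excluded
(all orderings kept if every one is blocked); Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), saturated at p ≥ 3/4. NG86 replaces a
maximum-likelihood estimator deliberately: it is self-contained and
path-enumerable, and at dS ≤ 0.05 — the regime of interest here — the two
nearly coincide. An exhaustive brute-force path enumerator over all 2- and
3-difference codon pairs is the test oracle. Dating is the clock relation
t = dS / (2r) with r = 7.1e-9 substitutions/site/year by default. The dS
histogram uses 0.005 bins; the zero-dS mass is reported separately from
the positive-dS mode.

## Expression bias

Per pair, replicate TPMs are averaged before the pseudo-count rule
(per-replicate ratios behind a flag). The rule triggers when the *minimum*
of the pair is below 1 and then adds 1 to both values — the source legend
("for any paired TPM values of <1, a pseudo-count of 1 was added to both")
is ambiguous between "either" and "both"; "either" is chosen and flagged.
Histogram bins (0.05 wide) are centred on multiples of the bin width so
that 0 and round shift values are bin centres. The secondary peak is the
highest local maximum outside the global mode ± 1 bin whose prominence
over its larger neighbour exceeds 3·√(count+1) — a Poisson-scale
significance guard that returns "no peak" on smooth unimodal data.

## The simulator

What it emulates: a common ancestor (GC 0.38) split into A and B lineages
by spectrum-driven substitutions totalling 0.034/site; four extant
lineages (tetraploid A and B rows, two diploid accessions) each
accumulating post-polyploidization mutations at per-bp rates matched to
the genome-scale study (diploid 1.5e-3/bp over the conserved space,
tetraploid 1.10× that); a six-type spectrum with the C>T class at 40% of
mutations and Ts/Tv 1.8 (transversions split equally — the source reports
only the two summary statistics), optional 16-context modifiers per class;
telomere-biased exchanges of all three dosage classes snapped to the depth
window grid, with at least one segmental event above and one below the
caller's 20 kb minimum as positive/negative controls; asymmetric gene
fates (A: 2.9% pseudogene / 3.1% deleted; B: 6.6% / 19.6% — the published
loss counts over 22,865 models); Poisson depth (negative-binomial
overdispersion behind a config switch, default off); and a two-component
expression-ratio mixture (broad N(0, 0.15) plus a 6% minority at
N(+0.2, 0.015)) with small replicate noise. The minority component's
weight and widths are ours: they are set so that the +0.2 dominance
shoulder is a resolvable histogram peak at the published pair count
(n = 15,484), which is the feature being emulated.

Deliberate simplifications, hence what passing tests do *not* show about
real data: substitutions are independent-site with no indels in the
mutation channel (indels exist only as planted gene-fate defects), so the
four-way "alignments" are exact column stacks and alignment error is
absent; planted mutations keep ≥ 5 bp clear of every other variant and of
block edges, so caller recall is 1.0 by construction (a flag disables the
spacing rule to exercise the flank filter's rejection path, and every
resulting miss is audited as a flank violation); the gene/CDS channel is
generated codon-aware and separately from the chromosome channel, so gene
fates are exactly recoverable and are not perturbed by the genomic
mutation channel; depth has no mappability or GC structure; the diploid
track puts no reads on BB windows (real mismapping background is a config
knob, default 0). Chromosomes default to 5 Mb so that a telomere window
is meaningful at desk scale; the 2 Mb window is capped at 10% of the
chromosome length per end. Balanced events are forced to ≥ 6 windows with
≥ 12-window flanks so they are detectable under the 5-window block rule —
a smaller swap is invisible to the partition-based caller by design.
Determinism: all draws flow from one seeded generator; identical configs
give byte-identical outputs.

## Problem sizes

The test suite exercises 2 × 500 kb systems (seconds each). The spectrum
recovery experiment uses 4 × 5 Mb chromosome pairs, which yields ≈ 63,000
interpretable calls at the study rates — comfortably above the 50,000-call
floor at which the six-type fractions stabilize within ±0.02 — and runs in
about a minute. Stochastic assertions use 3-standard-error bands around
the planted values at the realized call counts.

## Known limitations

No BB diploid means B-carrier mutation calls stay non-interpretable, as in
the real study design. The HE caller's evidence is depth-only; 3:1 calls
would need junction reads for confirmation. The NG86 mode of a dS
distribution can sit a bin away from an ML estimate at higher divergences.
The pipeline's genic-HE stage reads simulator-emitted per-gene depth;
computing it from window tracks is supported but resolution-limited, and
the function warns accordingly.
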