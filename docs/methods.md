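# Methods

## Scope and model

`mircds` analyses how microRNAs engage sites in protein-coding regions
(CDS) as well as 3'UTRs. The working model, supported by reporter
dose-response data, is that repression through a CDS site requires an
extensive, seed-inclusive binding interface and operates through
AGO2-mediated target cleavage: contiguous pairing of miRNA nt 2-12
licenses slicing; a single central disruption still permits repression; a
2-nt central bulge severely weakens it; 3 nt or more abolishes it; and
pairing of the miRNA 3'-terminal bases is dispensable. The package
implements four computational stages around that model:

1. **Duplex prediction** — optimal intermolecular pairing between a miRNA
   and a target window.
2. **Zone profiling + classification** — summarising an interface over the
   seed (nt 2-8), seed+cleavage (2-12), central (9-12), supplementary
   (13-17) and 3'-terminal (last 3 nt) zones, then mapping the profile to
   one of SLICING / REPRESSIVE / WEAK / NONFUNCTIONAL.
3. **Transcriptome scanning** — anchor-and-extend search for extensively
   complementary candidate sites in CDS/3'UTR.
4. **CLASH hybrid-read analysis** — interval expansion, region annotation,
   duplicate collapsing, per-hybrid duplex calls, region summaries and
   anchored pairing matrices.

A seeded synthetic-data generator provides transcriptomes, implanted
response elements and CLASH-like reads with full ground truth, so every
stage is testable without external downloads.

## Duplex model

The default engine is an exact dynamic program over antiparallel,
non-crossing intermolecular pairings. Scoring is a dimensionless integer
model:

* pair weights GC = 3, AU = 2, GU = 1 (wobble pairs count);
* interior loops/bulges carry an affine penalty `open + extend*(len-1)`
  with `open = 2`, `extend = 1`, where `len` is the total number of
  unpaired nucleotides enclosed between two pairs;
* dangling ends are free;
* every helix must contain at least 2 stacked pairs (no isolated pairs).

The weights order pair stabilities the way nearest-neighbour models do
(G:C > A:U > G:U) at integer resolution; the loop penalty makes a 1-nt
bulge cost one A:U pair and a symmetric mismatch slightly more. Integer
scoring permits an exact lexicographic tie-break — maximise score, then
the number of paired miRNA bases, then prefer the 5'-most paired target
start — so outputs are bit-reproducible. The DP runs in O(m·n) per window
using 2D prefix maxima over gap-adjusted helix scores; it is validated
against exhaustive enumeration of all legal pairings for short sequences.

An adapter mode ingests two-part dot-bracket strings and free energies
produced by an external nearest-neighbour folder (RNAduplex dialect,
including its interval-scoped output, via `pad_dot_bracket`). Adapter
energies are kcal/mol (lower = more stable) and are never mixed with
internal scores in one run; downstream classification consumes only the
pairing map, which both modes provide. Absolute free energies depend on
the external parameter set and are not asserted anywhere.

## Zone profiling

Profiles are computed from the pairing map by miRNA position. Seed and
seed+cleavage pairing require every position in the range to be paired
*and* the target partners to be strictly consecutive, so a single-nt
target-side insertion inside the seed counts as a seed imperfection. The
central bulge is the number of unpaired miRNA nt within 9-12 plus any
target-side insertions whose 5'-flanking pair lies at nt 8-11. Assigning
insertions by their 5'-flanking pair (rather than requiring both flanks
inside 9-12) keeps two properties that matter for a classifier: full
contiguous nt 2-12 pairing always implies central bulge zero, and deleting
any single pair from an interface can never raise the assigned class.

## Classifier

Thresholds live in a `RuleSet` because the underlying evidence is a
dose-response, not a sharp cut-off:

| parameter | default | meaning |
|---|---|---|
| `max_outside_mismatches` | 3 | unpaired miRNA nt tolerated outside nt 2-12 |
| `central_bulge_weak` | 2 | central disruption at which repression becomes weak |
| `central_bulge_dead` | 3 | central disruption that abolishes function |
| `require_three_prime_terminal` | False | optionally demand pairing of the last 3 nt |

Classification: NONFUNCTIONAL on a blown mismatch budget or (when enabled)
an unpaired 3' terminus; otherwise SLICING when nt 2-12 are contiguously
paired; otherwise NONFUNCTIONAL when the seed is imperfect; otherwise
REPRESSIVE / WEAK / NONFUNCTIONAL as the central bulge crosses the weak
and dead thresholds. The function is total and deterministic, and class
rank is monotone under removal of pairs.

A packaged fixture (`mircds/data/binding_models.tsv`) transcribes 19 named
reporter binding models (CDS1/1a/2/2a, CDS3/3a-c, the C-miR2 bulge and
3'-end series, and the siR2 series) as pairing-pattern templates with
their observed repressed / weak / not-repressed outcomes;
`fixture_validation` re-derives every outcome from the classifier. Where
only a figure defines a model's exact mismatch placement the template is an
approximation consistent with all textual descriptions of that construct.

One known model-vs-observation discrepancy is retained deliberately: a
modest repression of NOTCH2 by miR-221/222 has been observed despite a
2-nt target-side insertion in the seed-binding region; such interfaces
classify NONFUNCTIONAL here, and the package makes no attempt to model
that exception.

## Transcriptome scan

The scan requires an exact match to the reverse complement of the anchor
(nt 2-12, an 11-mer; strict Watson-Crick, no wobble) within the selected
region, then extends gaplessly and antiparallel across the full miRNA and
counts mismatches at the remaining positions, with G:U counted as a match
by default (flaggable). Operating points: mismatch budgets 2 and 3, with
an optional requirement of perfect pairing at the three 3'-terminal
nucleotides. The anchor must lie inside the chosen region; the extension
may spill across a region boundary, in which case the site label follows
the UTR3-first priority rule. Sites whose extension would overhang the
transcript are discarded (their pairing is undefined). Bulged candidates
are deliberately out of scope for the scanner — enumerating bulges would
change the mismatch combinatorics silently; bulged interfaces belong to
the duplex module.

Candidate sites (and implanted sites in simulations, whose register is
ground truth) are profiled on the gapless **in-register** duplex
(`scan.site_duplex`). Unconstrained refolding is not used for site
classification because a free hybridisation optimum can slip the 3' helix
around an engineered central bulge — paying two small loops instead of one
wide one — whereas AGO geometry anchors the register at the seed. This is
also why free-energy-optimal folds systematically overstate central
pairing; the limitation is inherent to hybridisation-only models.

## CLASH pipeline

Order of operations: expand every target interval by 3 nt per end (clamped
to the reference) to compensate nuclease nibbling; collapse duplicates on
identical (reference, interval, miRNA), summing counts; annotate each
entry against all transcript models. Expansion precedes collapsing so that
"identical interval" is evaluated deterministically on the final
coordinates. Region flags are the union over all overlapping transcripts
(intronic / exonic / utr3 / utr5); the label resolves by priority UTR3 >
CDS (exonic without a UTR flag) > UTR5 > intron, and reads overlapping no
transcript are discarded as intergenic. Fragments from minus-strand
transcripts are reverse-complemented into mRNA orientation before
duplexing with `predict_duplex`; hybrids naming an unknown miRNA are
flagged and excluded from matrices.

Pairing matrices hold one boolean per-position vector per hybrid,
count-weighted by default (unweighted toggle available), anchored either
at the miRNA 5' end (slot k = miRNA nt k; aligns seeds across miRNAs of
different length) or the 3' end (right-aligned). The two anchorings are
informationally identical per read — each 3'-anchored row is the
5'-anchored row shifted by `width - L` — which the tests assert exactly.

## Synthetic data

The generator emulates processed CLEAR-CLIP input. Transcripts have three
exons coinciding with the 5'UTR, CDS and 3'UTR, separated by two introns,
laid head-to-tail on one synthetic chromosome with intergenic gaps; 30% of
transcripts sit on the minus strand. Default region lengths are uniform:
5'UTR 60-200 nt, CDS 300-1200 nt (forced divisible by 3), 3'UTR 200-700
nt, introns 80-200 nt; background composition is i.i.d. at GC 0.45;
miRNAs are 20-23 nt at GC 0.5. Placing region boundaries on intron
boundaries keeps every implant inside one exon, so its genomic interval is
contiguous and fragments cover it exactly.

Implants write the reverse complement of a miRNA into a chosen region and
mutate the bases facing template-specified positions to bases that can
neither Watson-Crick nor wobble pair in register. Templates transcribe the
reporter construct families: `perfect`, `central_bulge_{1,2,4}`,
`seed_only`, `seedless_3prime`, `terminal_mm_{2,3}`. Implant reads cover
the site exactly, are truncated independently at each end by
Uniform{0..3} (matching the pipeline's fixed +3 compensation), and are
duplicated with Geometric(p = 0.5) multiplicity; decoys are placed
uniformly inside a region drawn from a configurable mix (default
0.5/0.3/0.1/0.1 for UTR3/CDS/UTR5/intron) with fragment lengths
25-40 nt. All randomness flows from a single integer seed through
`numpy.random.default_rng`, and identical configurations produce
byte-identical FASTA/BED12/TSV output.

What the generator does **not** model — and therefore what passing
recovery tests do not demonstrate about real data: codon structure,
secondary structure of targets (a hairpin context is known to reduce site
efficacy), sequencing error, miRNA expression abundance, chimera-ligation
biases, and overlapping gene models. Recovery results here bound pipeline
behaviour on ideal data.

## Problem sizes and numerical choices

The test suite and the acceptance script regenerate all inputs at run
time: duplex-oracle comparisons use 500 random pairs of length ≤ 8 plus a
4-mer panel; scanner-oracle equivalence and scan recovery run on ~100 kb
of synthetic transcriptome (80 transcripts) with 10 miRNAs over 10 seeds;
region-fraction recovery uses 5,000 reads (tolerance ±0.03, the ~3-sigma
multinomial envelope); nibbling re-coverage uses 1,000 reads. Degenerate
inputs are defined rather than erroneous where a meaning exists: empty
scan regions yield empty results, empty matrix classes yield empty
matrices, non-coding BED12 records (thickStart == thickEnd) become
non-coding models, and malformed hybrid rows are rejected row-wise with a
warning.

## Known limitations

* Hybridisation-only duplexes: no target accessibility, intramolecular
  structure, partition function or temperature dependence.
* The internal duplex score is dimensionless; free energies are available
  only through the external adapter and are parameter-set dependent.
* The scanner's gapless extension cannot find bulged sites by design.
* Classifier thresholds encode reporter outcomes as sharp cut-offs of what
  is biologically a dose-response.
* The region annotator supports BED12-derived models only (no GFF3/GTF),
  and hybrid tables must be mapped through the configurable column
  dialect; no raw-read processing (trimming, mapping, chimera detection)
  is included.
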