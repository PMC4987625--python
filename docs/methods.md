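# Methods

## Reference model and coordinates

The reference is a single fusion-antigen CDS; its translation must be
stop-free (inserts are displayed as internal capsid fusions). Residue and
nucleotide coordinates are 1-based and inclusive. Two residue numbering
systems coexist: fusion-wide positions and the antigen's own ("local")
numbering used by the epitope literature, related by a single integer
offset supplied by the user (`fusion = local + offset`). The offset is
deliberately explicit configuration rather than inferred by alignment: the
exact residue bookkeeping of a fusion construct is rarely published, and an
explicit offset makes span conversion an exact bijection on the covered
region. Antibody contact points are optional user annotation (they come
from structural work outside any sequencing experiment); the package never
embeds a contact list.

## Frame classification

An insert is *natural frame* iff it maps forward, starts on a codon
boundary (`frame5 = (start−1) mod 3 = 0`), has length ≡ 0 (mod 3), and its
displayed translation contains no stop codon. Exactly one of the 18
(orientation × frame5 × len mod 3) cloning configurations satisfies the
first three conditions, giving the 1/18 expectation for random cloning; the
stop screen removes clones that won the lottery but cannot display peptide.

Mapping is exact-substring first (forward, then reverse complement), then
an infix edit-distance alignment (edlib) with tolerance
`max_mismatch_frac × length` (default 0.02). Ties keep the leftmost
placement and are logged. Flank location for insert excision uses a
sliding-window Hamming search with `max_mismatch` substitutions (default
2): the contract is substitution counts, so edit distance is the wrong
metric there. Reported `fraction_natural` uses insert-bearing, mappable
reads as denominator (empty and unmapped reads excluded). Read pairs can
be merged by 3′ overlap; unmergeable pairs fall back to read 1 (logged).

## Enrichment statistics

Fragment identity is the encoded residue span (different nucleotide
placements encoding the same span collapse). Per-residue occurrence is the
read-weighted coverage divided by the library's natural-frame read total.
The enrichment factor applies the pseudocount (default 1) to the raw
tallies *before* depth normalization:

    EF[i] = ((Csel[i] + pc) / Nsel) / ((Cunsel[i] + pc) / Nunsel)

so EF is finite and positive everywhere; residues covered in neither
library sit at the defined baseline Nunsel/Nsel. A raw-count mode
(`depth_normalize=False`) is provided for sensitivity checks, since the
verbal definition of "occurrence" admits both readings; the normalized
form is the default because it is comparable across sequencing depths.
The significance rule takes the frequency distribution over *unique
fragments* of the unselected library and flags selected fragments above
mean + 5 sample SD. Ranking ties break by longer span, then smaller start.

## Hot-spot detection

Jump scores between adjacent residues are either EF differences or log
ratios (default log ratio — EF is a ratio quantity, and the log makes the
detector invariant to global rescaling). A boundary is called when
|score| > median(|score|) + k·MAD(|score|); nearby calls within
`min_separation` (default 5) keep the largest score. `k = 7` is the
default: for Gaussian profile noise the median + k·MAD threshold sits at
≈ (0.674 + 0.37·k)·σ, so k = 7 (≈ 3.3 σ) keeps the expected false-call
count on a ~440-residue noise profile below one, while k = 6 (≈ 2.9 σ)
would not. If MAD is zero on a non-constant profile (e.g. an ideal step),
the scale falls back to the standard deviation (logged).

When the profile carries raw tallies, log-ratio scores are standardized by
a delta-method standard error, `SE² = Σ 1/(C+pc)` over the four tallies
involved, treating them as independent Poisson counts. Adjacent tallies
share most of their reads, so this overestimates mid-profile variance and
is conservative. Standardized calls must also exceed an absolute floor
(`z_min = 4`): jump-score variance scales inversely with local coverage,
and without standardization a MAD threshold calibrated on deep mid-protein
coverage fires on sampling noise at the sparsely covered protein termini.

The candidate binding-required region extends from an increase boundary
while EF stays above the pre-jump level (mirror-image for decreases). No
structural claim is attached: a called stretch may act through folding
rather than antibody contact.

## Simulator

The generator emulates library construction from a single amplified CDS:
fragment length uniform on 100–400 bp (the gel cut used for DNase-digested
fragment libraries), start uniform over positions where the fragment fits.
Drawing the length first and then a valid start — rather than truncating
overhanging fragments at the gene end — matches uniform fragmentation of a
linear molecule and keeps junction frame and length mod 3 independent;
truncation would couple them (a truncated in-frame fragment automatically
has length ≡ 0 mod 3) and push the natural-frame fraction visibly above
1/18. Under the default range P(len ≡ 0 mod 3) = 100/301, so the expected
classified natural fraction is 0.5 × ~1/3 × 100/301 ≈ 5.54%, within
sampling error of 1/18. An optional truncated-normal length mode
(165 ± 54 bp ≈ 55 ± 18 aa) emulates the shorter displayed-fragment
distributions observed in real libraries. Defaults: 10% empty clones,
substitution errors at 0.001/base (no indels, constant quality), arbitrary
fixed 20 bp synthetic vector flanks.

Selection is multinomial: each round draws `reads_per_round` clones with
probability ∝ abundance × weight and the next round resamples the output.
A clone is a *binder* (truth) when natural frame and covering every residue
of every planted required set; binders get `w_binder` (default 100),
everything else `w_background` (default 1). An optional per-set
partial-credit mode gives each covered set a multiplicative boost of
`(w_binder/w_background)^(1/n_sets)`, motivated by real epitopes where a
fragment carrying only the contact stretch binds weakly but detectably.
The strict conjunctive model remains the default. All randomness flows
from one seed (library, selection and resampling use distinct child
streams), so simulate → classify → enrich → hotspot chains are
bit-reproducible.

What the simulator does *not* model: PCR duplicates and amplification
bias, platform-specific error profiles, indels, quality variation, chimera
formation, clone fitness differences. Tests passing on simulated data
therefore show the statistics behave as designed under the stated
generative model, not that real libraries satisfy that model.

### A geometric limit on boundary localization

With uniform random fragmentation, EF change-points cannot localize a
planted set *start* exactly: the enriched clones' left endpoints are spread
over every start compatible with covering the required sets, so the EF
rise is a ramp whose sharp edge sits at the minimal compatible start
(set by the maximum fragment length), not at the set boundary. Likewise a
required set adjacent to the gene end produces no EF feature at its own
start, because every clone covering it must run to the gene end and their
coverage is identical over the whole terminal window. Exact-boundary
recovery would require fragment endpoints concentrated at the set edges,
which uniform fragmentation cannot produce; on idealized step profiles
(where the jump *is* at the boundary) the detector recovers boundaries
exactly, as the unit tests show.

## Affinity estimation

The Friguet estimator drops non-inhibiting points (A ≥ A0; y is undefined
there), requires at least two informative points, warns when a0 < 10 × i0
(antigen excess) or when the fitted intercept deviates from 1 by more than
0.2, and reports a series with no informative point as "no binding" rather
than an error. Replicates are the series at the different plate-coating
concentrations; the aggregate is their mean and sample SD (single
replicate → SD 0), and fold changes are ratios of unrounded means — ratios
of rounded table values will differ slightly. The competitor grid used by
the synthetic series is a doubling series 7.5–480 nM (seven points; the
source protocol states only the 7–480 nM range). The exact-quadratic
solver exists to quantify the excess-approximation bias; with i0 = 0.7 nM
and a0 ≥ 7.5 nM that bias is within typical assay precision.

## Problem sizes

Test and acceptance runs use simulations sized for signal, not realism of
scale: 100,000 clones for the natural-fraction check (3 binomial SE ≈
±0.22 percentage points around 5.56%), 50,000 clones for planted-epitope
selection (binder probability ≈ 8 × 10⁻⁵ under the default geometry, so
the library holds a handful of binders), 500 clones × 5,000 reads for null
controls (sequencing depth above diversity so the unselected frequency
distribution has non-zero spread, as the mean + 5 SD rule assumes).
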