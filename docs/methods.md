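# Methods

This note records the statistical definitions the package implements,
the design decisions taken where conventions diverge, what the
synthetic-data generator does and does not emulate, and known
limitations.

## Data model and coordinates

Annotations are ordered gene tables on a circular genome: gene name from
a controlled vocabulary (13 PCGs, 22 tRNAs, srRNA/lrRNA), strand J
(majority) or N (minority), and 1-based inclusive coordinates. A feature
whose end precedes its start must be flagged as wrapping the origin and
contributes `L − start + 1 + end` to length accounting. N-strand genes
are always analyzed on their reverse complement ("sense strand").
GenBank input is converted on read; `+`/`−` are accepted as strand
aliases; gene labels are normalized through an editable synonym table
(`COX1 → COI`, `16S → lrRNA`, …) because annotation pipelines disagree
on spelling.

Where a published gene table is internally inconsistent (printed length
or printed intergenic value vs printed coordinates), the coordinates are
treated as authoritative; the shipped reference table preserves the
printed columns so tests can pin both.

## Composition and skews

Composition partitions report %T/%C/%A/%G over counted residues (N
excluded from the denominator), A+T, and

    AT skew = (A − T)/(A + T)        GC skew = (G − C)/(G + C)

Zero denominators yield an explicit undefined marker, never 0. Reporting
rounds percentages to 1 decimal and skews to 3 decimals using half-up
rounding (published tables round 0.125 to 0.13; Python's default
banker's rounding would not). Codon-position partitions are computed on
each gene's sense strand; the J-strand/N-strand partitions pool each
gene's sense-strand counts grouped by which strand encodes it — this is
what produces the characteristic GC-skew sign flip between the two
strand classes. Note that recomputing a skew from 1-decimal percentages
can differ from the count-based value by up to ~0.02 when the
denominator is small (G+C below ~10%); count-based and printed-input
paths are therefore kept distinct in the tests.

## Geometry

For consecutive features u, v on the circle (including the wrap-around
pair) the signed spacer is `v.start − u.end − 1`: negative = overlap,
zero = abutting, positive = intergenic. Non-negative gaps of at least
`control_region_min` (default 1,000 bp; the reference genome's two
control regions are 2,350 and 2,453 bp while its true spacers are
≤ 72 bp) are classified as control regions and excluded from spacer
counts and ranges. The wrap-around gap is counted as a control region
even though published tables usually have no row for it. The identity
`Σ gene lengths + Σ signed gaps = genome length` holds exactly on a
circular annotation and is asserted in the closed-loop tests. In the
tabular report the intergenic column gives each row's gap to the
previous feature, with the first row printed as 0 by convention.

## Codon-usage bias

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial): UGA = Trp, AGA/AGG = Ser, so the synonymous families are
twelve 2-fold, six 4-fold, one 6-fold (Leu) and one 8-fold (Ser) — 62
sense codons. The 6-codon Leu family is used as one family even where
published tables typeset UUR and CUN separately (the printed RSCU values
are only reproducible under the joint family).

* **RSCU**: `n_i · k / N` for codon i in a family of size k with total
  N; undefined for unobserved families. Stop codons (UAA/UAG) form a
  2-codon family included in RSCU output — published tables tabulate
  stop RSCU — but are excluded from ENC, CBI, GC and GC3, which are
  amino-acid-based (codonW behavior).
* **ENC** (Wright 1990), generalized to the code's family structure:
  per-family homozygosity `F̂ = (nΣp̂² − 1)/(n − 1)`, averaged within
  family-size classes; `ENC = Σ_classes N_c/F̄_c`, capped at 62. Families
  with n < 2 (or F̂ ≤ 0) are imputed with their size-class mean; if an
  entire class is unobserved it is dropped and the result rescaled by
  total families / represented families. Bounds: 20 (one codon per
  amino acid) to 62 (uniform).
* **CBI**: `(N_opt − N_rand)/(N_tot − N_rand)` with
  `N_rand = Σ N_family/k_family`; the optimal set defaults to each
  family's most frequent codon in the analyzed table itself (ties broken
  alphabetically), which is a declared convention — published analyses
  rarely state theirs. 0 for uniform usage, 1 for purely optimal usage.
* **Correlations** across a genome panel default to Spearman (the
  expected trends are monotone, not linear); Pearson by flag. Constant
  inputs give NaN, not an error.

## Ka/Ks

Pairwise Ka/Ks uses Nei–Gojobori (1986) counting with equal-weight
averaging over minimal substitution pathways (stop-traversing pathways
excluded; if all pathways hit a stop, all are used so the pair still
contributes) and Jukes–Cantor correction `d = −¾ ln(1 − 4p/3)`;
`p ≥ ¾` is reported as saturated (NaN), and Ka/Ks is undefined when
Ks = 0. Synonymous site fractions exclude stop neighbors from the
per-position denominator; sites are averaged over the two sequences, so
the estimator is symmetric and N + S equals the nucleotide length.

This is a deliberate substitution: the analysis this package descends
from used a codon-model maximum-likelihood estimator (FMutSel) that
corrects for mutational bias — important in extremely AT-rich genomes,
where counting methods can misallocate sites. NG86 is transparent,
dependency-free and adequate for the qualitative claim the package
tests (ratios ≪ 1 under purifying selection); absolute values should
not be compared against FMutSel outputs. Alignment is an input
contract: sequences must be codon-aligned and gap-free; the
trim-to-shorter convenience mode exists for simulated (indel-free) data
and warns loudly otherwise.

## tRNA cloverleaf classification

Given a tRNA gene sequence and its annotated anticodon position, the
classifier anchors the 7-nt anticodon loop on the triplet, then seeks:
the anticodon stem as complementary pairs walking outward from the loop;
the acceptor stem as pairs walking inward from the 5′/3′ termini
(allowing an unpaired 3′ discriminator overhang of up to 3 nt); a
D-hairpin in the region between acceptor 5′ side and anticodon stem; a
T-hairpin between anticodon stem and acceptor 3′ side. A hairpin needs
≥ `min_stem_pairs` (default 3) pairs and a 3–11 nt loop; the acceptor
needs ≥ 4 pairs; G·U wobble counts as a pair. Class = full / D-armless /
T-armless / minimal from the two side-arm flags. Defaults were chosen to
recognize designed canonical cloverleafs on constructed fixtures.

This is a transparent heuristic for sequences whose anticodon is already
annotated — not a covariance-model detector, and no substitute for
curation of real structures. Genes down to ~40 nt classify without
error; classification is strand-invariant (N-strand genes are
reverse-complemented first) and stable under a ≤ 3 nt unpaired 3′
extension.

## Gene order

Orders are circular signed permutations; the canonical form rotates the
anchor gene (default COI) to the front with positive sign, flipping the
whole order if needed, so equality is rotation- and reflection-stable.
The breakpoint distance counts signed adjacencies of one order absent
from the other, identifying x→y with −y→−x; it is a pseudometric
(non-negative, symmetric, triangle inequality). Inversion distance
(Hannenhalli–Pevzner) is deliberately not implemented — breakpoint
distance suffices for descriptive comparison. Cluster search reports
inverted occurrences (reversed order, flipped signs) separately.

The clade-diagnostic scan reports, per candidate cluster and group, the
presence fraction plus two flags: `fixed_in` (present in every member of
one group, absent elsewhere) and `diagnostic_for` (present in at least
one member of exactly one group). The weaker exclusivity form is the
operative one: in rearrangement hotspots even genuinely derived clusters
keep being overwritten within a clade, so clade-level apomorphies are
cited on exclusivity, not fixation — the shipped scale-insect order set
is the worked example, where the four derived ND2-flanking clusters are
each exclusive to (but not fixed in) the neococcoid group.

The shipped order fixture is partly synthetic: the ancestral
pancrustacean arrangement and the reference taxon's order are real, and
the diagnostic clusters of the other 17 taxa are as reported in the
literature, but the rest of those 17 orders is synthetic filler. Their
pairwise distances and the NJ tree on them are therefore illustrative
plumbing, not evidence.

## Synthetic mitogenome generator

The generator emulates the reference genome's statistical structure with
these defaults: 18,830 bp circular genome; 90.7% A+T; the reference
37-gene order; PCG lengths from the reference table; PCG sequences drawn
codon-by-codon from the reference codon-usage frequencies with an ATN
start and a TAA stop (stop codons are excluded from the interior draw,
so internal stops cannot occur); tRNAs built from cloverleaf templates
in the reference 8 full / 8 T-armless / 5 D-armless / 1 minimal split;
rRNAs and spacers as AT-biased noise; 15 overlaps in 1–22 bp and 14
spacers in 1–72 bp; one fixed 2,350 bp control region placed before the
last rRNA and a closing control region absorbing the remaining length
(the generator refuses configurations where that remainder falls below
the control-region threshold).

Overlapping genes share sequence, with the downstream gene owning the
shared bases. Overlaps are only placed where the upstream feature
tolerates losing its tail: a tRNA (at most 4 bp, confined to the
acceptor 3′ side and discriminator, which cannot change its arm class)
or an rRNA (any length within range). The assembled genome is then
re-verified: every tRNA is re-classified in place and every PCG's start
and stop re-read; the rare tRNA whose ceded tail context mimics an extra
arm is redrawn and the genome reassembled (deterministically, from a
dedicated retry stream). The overall A+T level is steered by choosing
the control-region base composition analytically after all genes are
generated, which lands the realized genome within a fraction of a
percent of the request.

One integer seed drives a named substream per sub-generator (PCGs,
tRNAs, rRNAs, layout, background, retries), so adding a generator never
shifts another's draws and identical configs are byte-identical.

What the generator does **not** emulate: real codon autocorrelation
along genes, rRNA secondary structure, control-region repeats, origin
of replication signals, and strand-specific mutational pressure beyond
what the codon-frequency table encodes. Passing closed-loop tests
therefore demonstrates that the pipeline measures what the generator
wrote — not that the heuristics (e.g. the tRNA arm finder) would agree
with curated structures on real sequences.

The codon-pair evolver is a per-codon continuous-time chain: single
nucleotide exchanges, transitions scaled by κ (default 2), amino-acid
changing exchanges scaled by ω, stop codons unreachable. `t` is the raw
rate × time product; `t = 0.05` yields a synonymous divergence around
Ks ≈ 0.25 at the defaults — far from both zero and saturation — and is
what the recovery tests use (500 codons, 20 replicates, fixed seeds).
NG86 point estimates under the chain recover the rank order of
ω ∈ {0.1, 0.5, 1.0} and give ratios ≪ 1 under ω = 0.1, though with the
expected downward compression at high ω (counting methods shrink toward
the mutation-weighted average).

## Numerical and edge-case conventions

* Half-up decimal rounding for all reported values.
* Undefined quantities (zero-denominator skew, unobserved RSCU family,
  Ks = 0, saturated Jukes–Cantor, constant correlation input) are
  explicit markers (None/NaN), never silently 0.
* Ties: CBI optimal codons break alphabetically; D/T-arm candidates are
  assigned by position (5′ region → D, 3′ region → T); NJ ties follow
  input order.
* Empty inputs (no tRNAs, empty annotation) return empty tables, not
  errors; malformed inputs (bad strand token, non-IUPAC residue,
  CDS length not divisible by 3) raise with the offending gene or line
  named.

## Limitations

* Ka/Ks by counting, not codon-model ML; see above.
* The tRNA classifier requires an annotated anticodon and cannot find
  tRNAs de novo.
* Breakpoint distance only; no rearrangement-event inference or
  ancestral-order reconstruction.
* The NJ tree on gene-order distances is descriptive plumbing, not a
  phylogenetic inference method.
* Sliding-window skews and origin-of-replication inference are out of
  scope.
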