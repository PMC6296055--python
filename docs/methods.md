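# Methods

This note documents the probability model, the numerical and design
choices behind `varsieve`, what the synthetic fixtures do and do not
emulate, and the known limitations.

## The window probability model

All scoring reduces to localized s-mers: length-s strings ⟨s,l⟩
realizable at offset l by a combination of REF/ALT alleles of the
variants *starting* in [l, l+s). The probability that a random haplotype
drawn from the population realizes a given combination is

* **unphased**: the product of marginal allele frequencies — ALT
  frequency where the combination carries ALT, 1 − AF where it carries
  REF (linkage equilibrium assumed);
* **phased**: the fraction of panel haplotypes whose alleles match the
  combination at every window variant (co-occurrence counted directly).

The offset prior is uniform over the W *valid* window offsets. Two
deliberate choices here:

1. **W is the exact offset count**, Σ_chrom max(0, len − s + 1) minus
   N-containing windows, rather than the genome length that approximates
   it. With the exact W the combination probabilities at each offset
   partition to 1, so the population coverage of the complete augmented
   genome is C(G\*) = 1 *exactly* (to float accumulation error, tested at
   1e−9) rather than approximately. Every downstream statement about C is
   then sharp.
2. **Windows whose reference substring contains N are excluded** from W,
   from probability sums, and from all counting. Assembly gaps would
   otherwise dominate multiplicity tables with meaningless N-mers.

Counting is forward-strand only: the genome model is single-stranded, and
collapsing reverse complements would double-count palindromic contexts
without changing any ranking at fixture scale.

### The per-window cap

A window with n variants has 2^n combinations. Everywhere — probability
sums, s-mer counting, hybrid scoring, and enhanced-segment construction —
windows with more than k_cap variants (default 15, hard bound 24) are
restricted to the *leftmost* variant plus the k_cap − 1 highest-frequency
others; the rest are held at REF. Using one blowup policy for counting
and for segment construction keeps the count table and the augmented
FASTA export in exact one-to-one correspondence. In phased mode,
haplotype matching is performed over the capped set only, so the
per-offset probabilities still sum to 1.

## Scores

**Pop Cov** is the ALT allele frequency. Under the complete-graph
assumption (score each variant as if all others are present), removing an
interior SNV from G\* lowers C by s·AF/W — proportional to AF — so the
raw frequency is used directly and edge variants and indels rank
identically. Phasing cannot change this quantity.

**Hybrid** sums, over every ALT-carrying ⟨s,l⟩-mer of the variant,
ΔH = (p − ā)/(n + 1), with n = f_G\*(seq) − 1 the sequence's other
occurrences in the complete graph. For n = 0 (the dominant regime in
real catalogs) ΔH = p exactly. For n > 0 the average probability ā of the
other occurrences is approximated by the weighted mean
(1/f_G\*)[(f_G\* − f_ref)·p̄_\* + f_ref·p̄_ref], where p̄_ref and p̄_\*
are the precomputed global means over reference and ALT-carrying s-mers.
Two ambiguities in this averaged form were resolved as follows:

* the denominator of the average includes the candidate's own occurrence
  (division by f_G\*, as the formula is written); the alternative
  (division by n) is switchable via
  `HybridContext.own_occurrence_in_average` for sensitivity analysis;
* p̄_\* is computed globally, not per multiplicity class.

The approximation is applied as written even where its distinct-sequence
independence assumption fails; the exact mode exists to quantify the
error. The **exact oracle** computes H(G\*) − H(G\* ∖ {v}) from one
global enumeration: dropping v removes exactly its ALT-carrying
occurrences (the cap is held fixed at the full-catalog cap, and excluded
variants keep contributing their REF-match probability factors), so the
difference is a per-sequence ratio update. This is itself cross-checked
in the tests against a naive double enumeration of H on tiny genomes. On
the standard fixture the approximate and exact scores agree exactly in
the unique-s-mer regime and to Spearman ≈ 1.0 overall.

**Uniqueness** is exposed only as a genome statistic U(G): as a variant
ranking it cannot discriminate among the (majority of) variants whose
added s-mers are all unique.

Hybrid scoring supports SNVs only and fails loudly on indels; Pop Cov
handles indels, since it needs no sequence enumeration.

## Selection

Selection is greedy with an optional penalty: after each pick, unselected
variants within s nt on the same chromosome (start-position distance,
boundary inclusive, symmetric) have their current score multiplied by w.
Penalties accumulate multiplicatively when several selected variants
neighbor one candidate. Ties are broken by chromosome order in the
reference, then left offset — the single tie-break authority for all
models. The implementation is a lazily invalidated max-heap (safe because
penalties only decrease scores) and is tested for exact sequence
equality against a stepwise recompute-argmax oracle up to 2,000-variant
catalogs for w ∈ {0, 0.25, 0.5, 1}. w = 1 reproduces the static ranking;
w = 0 (accepted as a diagnostic mode, outside the configured (0, 1]
range) defers every neighbor of a selected variant until no
positive-score isolated variant remains. Fraction budgets are resolved
against the catalog after multi-allelic splitting, rounded to nearest
with a minimum of one.

## Enhanced segments and the major-allele reference

Each enhanced segment is owned by its leftmost ALT variant: for anchor v,
the co-window set is the variants starting within r − 1 bases to v's
right (any two of which are then also mutually co-windowed), capped to v
plus the k − 1 highest-AF members when it exceeds k. One segment is
emitted per subset containing v, spanning r − 1 flanking bases on each
side, clipped at chromosome ends (never padded). This reproduces the
2^n − 1 total for a cluster of n ≤ k and guarantees every ALT at least
one segment for any k ≥ 1; both properties are verified by brute-force
subset enumeration.

The major-allele reference sets each site to its most frequent allele
(REF frequency taken as 1 − Σ ALT frequencies at multi-allelic sites);
ties keep REF. Indel edits shift coordinates, recorded in an offset map
with one row per applied indel. The transform applies the stated edits
without re-validating REF against the partially edited sequence, which
makes a second application with the same SNV catalog a no-op.

## Synthetic fixtures

The generator is the package's test bed and defines its study
conditions. Defaults: one 10 kb chromosome, 200 SNVs, a panel of 20
phased haplotypes, repeat fraction 0.2, uniform allele-frequency
spectrum, cluster rate 0.1, s = 25. Choices worth noting:

* **Repeats** are planted by overwriting a target fraction of the genome
  with copies of earlier blocks of length 2s — the minimal mechanism that
  produces s-mers of multiplicity ≥ 2 at controllable density.
* **Frequencies**: each haplotype carries the ALT independently with a
  target probability drawn from the configured spectrum (uniform by
  default; beta and a spiked rare/common mixture are available), and the
  *realized* panel fraction is recorded as AF. Realized AF can be 0;
  such records are retained and score 0.
* **Clustering**: with probability `cluster_rate` a variant is placed
  within s nt of the previous one, otherwise uniformly; collisions are
  re-drawn.

What the fixtures do **not** emulate: linkage disequilibrium beyond what
finite panels induce (haplotypes are drawn independently per site), real
repeat families and their length spectrum, mutation-rate heterogeneity,
sequencing error, and genome-scale catalogs (3×10^6 variants). Passing
tests therefore demonstrate correctness of the computations and the
combinatorics, not that any particular inclusion fraction is optimal for
real data — the latter depends on aligner behavior that is out of scope
here.

## Problem sizes and tolerances

The default suite runs on genomes of 2–100 kb with 30–2,000 variants;
the exact-oracle comparisons use the 10 kb / 200-SNV fixture and the
selector oracle uses 2,000 variants, sizes at which the quadratic
reference implementations are comfortable. Probability normalization and
oracle equalities are asserted at 1e−9 absolute; allele frequencies read
from VCF INFO fields are 32-bit floats (htslib), so tests derive expected
values from the parsed frequencies rather than their decimal literals,
and a genotype panel, when present, is the authoritative frequency
source. Rank agreement between approximate and exact hybrid scores is
asserted at Spearman ≥ 0.9.

## Known limitations

* Hybrid scores for indels are not defined (fatal), matching the SNV
  scope of the enumeration; Pop Cov accepts indels.
* Window membership is by variant start position; a deletion starting
  left of a window is not enumerated within it.
* No canonical (strand-collapsed) counting.
* The selected-VCF writer preserves source lines verbatim for fully
  selected records; partially selected multi-allelic records are
  re-emitted per-ALT with only ALT, AF, and GT columns rewritten (other
  per-ALT INFO fields are copied unchanged).
* No index construction or read alignment; the package stops at the
  artifacts an indexer consumes.
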