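# varsieve

Variant prioritization for augmented (graph) reference genomes.

Read aligners that represent known population variants alongside the
linear reference recover reads from diverged haplotypes that a plain
reference would mis-place or lose — but every added variant also makes the
reference more repetitive and the index larger, and densely clustered
variants blow up exponentially (2^n allele combinations in a window with
n variants). In practice, alignment accuracy peaks when only a modest,
well-chosen fraction of a population catalog is included. `varsieve`
implements the offline stage of that workflow: it scores every variant in
a VCF catalog against a FASTA reference, selects a budgeted top subset,
and emits the artifacts a downstream graph or linear aligner consumes —
the selected VCF, an enhanced-reference FASTA, and a major-allele linear
reference. It is aimed at people building graph-genome indexes (or
ERG-style augmented references for linear aligners) from population
callsets.

## Models

Let G_ref be the linear reference, G\* the augmented genome containing all
catalog variants, and G a selected subset. A *localized s-mer* ⟨s,l⟩ is a
length-s string realizable at offset l by some combination of REF/ALT
alleles; its population probability factors as

```
p(⟨s,l⟩) = p_l · p_s(⟨s,l⟩)
```

with p_s the probability that a random haplotype's alleles match the
combination (a product of marginal allele frequencies, or a phased-panel
co-occurrence fraction) and p_l the uniform prior over the W valid window
offsets.

* **Population coverage** `C(G) = Σ_{⟨s,l⟩∈G} p(⟨s,l⟩)`, with
  `C(G_ref) ≤ C(G) ≤ C(G*) = 1`. The *Pop Cov* model scores each variant
  by its effect on C under the *complete-graph assumption* (all other
  variants treated as present), which reduces to the ALT allele frequency.
* **Uniqueness** `U(G) = Σ_{⟨s,l⟩∈G} 1/f_G(seq)`, where f_G is the s-mer
  multiplicity; it falls as the genome gets more repetitive. Exposed as a
  genome statistic.
* **Hybrid** `H(G) = Σ_{⟨s,l⟩∈G} p(⟨s,l⟩)/f_G(seq)` weighs frequency and
  repetitiveness together. A variant's score sums, over every ALT-carrying
  ⟨s,l⟩-mer overlapping it, `ΔH = (p − ā)/(n+1)` where n counts the other
  occurrences of the same sequence in G\* and ā is their average
  probability, approximated from the precomputed means p̄_ref and p̄_\*.
  An exact brute-force oracle (`hybrid_score_exact`) is provided for
  validating the approximation on small inputs.
* **Blowup avoidance** (the `popcov+` / `hybrid+` selection modes):
  during greedy selection, each time a variant is chosen the scores of
  unselected variants within s nt are multiplied by a penalty w
  (default 0.5), deferring clustered variants.

The enhanced-reference builder emits one segment per ALT subset of each
co-windowed variant cluster (2^n − 1 segments for a cluster of n),
anchored at the leftmost ALT; windows with more than k variants keep the
leftmost plus the k−1 highest-frequency others (default k = 15), which
still guarantees every ALT appears in at least one segment.

## Worked example

Generate a seeded synthetic bundle, score it with the hybrid model,
select the top 10% with blowup avoidance, and build both references:

```
$ varsieve fixture --seed 1 --length 4000 --n-variants 60 --window 20 --out demo
$ varsieve score --fasta demo/ref_seed1.fa --vcf demo/variants_seed1.vcf \
      -s 20 --model hybrid --out demo/scores.tsv
wrote 60 scores to demo/scores.tsv

$ head -4 demo/scores.tsv
chrom   pos     ref     alt     alt_freq        score
chr1    28      T       A       0.45    0.00226073850791
chr1    85      A       T       0.6     0.00301431801055
chr1    211     C       G       0.3     0.00150715900528

$ varsieve select --fasta demo/ref_seed1.fa --vcf demo/variants_seed1.vcf \
      --scores demo/scores.tsv --model hybrid+ --pct 10 -s 20 \
      --out-vcf demo/selected.vcf --report demo/report.tsv
selected 6 variants -> demo/selected.vcf (min AF 0.95)

$ varsieve build-erg --fasta demo/ref_seed1.fa --vcf demo/selected.vcf \
      --erg-window 20 --out demo/erg.fa
wrote reference + 6 enhanced segments to demo/erg.fa

$ varsieve build-major --fasta demo/ref_seed1.fa \
      --vcf demo/variants_seed1.vcf --out demo/major.fa
wrote major-allele reference to demo/major.fa (37 candidate substitutions)
```

Each score row is the variant's ΔH summed over its overlapping windows:
an isolated SNV with unique ALT 20-mers scores s·AF/W (here
0.00226 = 20 × 0.45 / 3981), so frequency dominates until an ALT
duplicates existing sequence, which pushes the score down or negative.
The selection report records, per chosen variant, its original score, its
score at selection time, and how many neighbor penalties it had absorbed.
The six selected variants here are all isolated and high-frequency — the
reported minimum AF (0.95) is the frequency threshold this 10% budget
implies. The ERG output contains the reference plus one segment per
selected-variant ALT combination (six isolated variants → six segments);
the major-allele FASTA substitutes the 37 sites whose ALT frequency
exceeds 0.5.

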