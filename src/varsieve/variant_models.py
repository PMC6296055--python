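"""Per-variant scoring models: Population Coverage, Uniqueness, Hybrid.

Population coverage of an augmented genome G is the probability mass of
population localized s-mers representable by G:

    C(G) = Σ_{⟨s,l⟩ ∈ G} p(⟨s,l⟩),        C(G_ref) ≤ C(G) ≤ C(G*) = 1.

Uniqueness sums the reciprocal multiplicity of every s-mer occurrence,

    U(G) = Σ_{⟨s,l⟩ ∈ G} 1 / f_G(seq),

and the hybrid score weights each reciprocal by the occurrence's
population probability,

    H(G) = Σ_{⟨s,l⟩ ∈ G} p(⟨s,l⟩) / f_G(seq).

All scores are computed under the *complete-graph assumption*: each
variant's score is its effect on removing it from G*, the augmented genome
containing every catalog variant, which yields a single static score list
with no re-scoring during model evaluation.  A variant's hybrid score sums
the ΔH of every ALT-carrying ⟨s,l⟩-mer overlapping it,

    ΔH = (p − ā) / (n + 1),

with n the number of other occurrences of the same sequence in G* and ā
their average probability — zero when the sequence is unique, otherwise
approximated by a weighted average of the precomputed means p̄_ref (over
reference s-mers) and p̄_* (over ALT-carrying s-mers).  The exact-oracle
mode computes H(G*) − H(G* ∖ {v}) by direct enumeration instead.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_io import HaplotypePanel, ReferenceGenome, VariantRecord
from .smer_engine import (
    LocalizedSMer,
    ModelConfig,
    SMerCountTable,
    SmerError,
    SmerSpace,
    window_offsets,
)

log = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Static per-variant model scores."""

    model: str  # "pop_cov" or "hybrid"
    scores: dict[int, float]
    config: ModelConfig

    def __post_init__(self) -> None:
        for vid, sc in self.scores.items():
            if not np.isfinite(sc):
                raise ValueError(f"non-finite score for variant {vid}")


@dataclass
class HybridContext:
    """Precomputed state for the approximate hybrid score.

    Holds the s-mer multiplicities of G_ref and G*, the average
    probabilities p̄_ref / p̄_*, and the shared enumerator.
    """

    counts_ref: SMerCountTable
    counts_star: SMerCountTable
    p_bar_ref: float
    p_bar_star: float
    space: SmerSpace
    phased: bool = False
    config: Optional[ModelConfig] = None
    # Open question in the printed averaged approximation: whether the
    # candidate's own occurrence sits in the average's denominator.  True
    # reproduces the printed formula (divide by f_G*); False divides the
    # non-candidate mass by n.
    own_occurrence_in_average: bool = True


# -- Population coverage -----------------------------------------------------

def pop_cov_score(variant: VariantRecord) -> float:
    """Population-coverage model score: the ALT allele frequency.

    Removing an interior variant from G* decreases C by
    |window offsets| · AF / W, proportional to AF; the raw AF is used so
    edge variants and indels rank identically.  Phasing is irrelevant under
    the complete-graph assumption.
    """
    return variant.alt_freq


def pop_cov_scores(variants: Sequence[VariantRecord],
                   config: Optional[ModelConfig] = None) -> ScoreTable:
    cfg = config or ModelConfig(s=100)
    return ScoreTable(model="pop_cov",
                      scores={v.vid: pop_cov_score(v) for v in variants},
                      config=cfg)


def population_coverage(ref: ReferenceGenome,
                        included: Optional[Iterable[int]],
                        all_variants: Sequence[VariantRecord],
                        s: int, k_cap: int = 15,
                        panel: Optional[HaplotypePanel] = None,
                        phased: bool = False) -> float:
    """C(G) for the augmented genome including the given variant subset.

    Enumerates every valid window offset and every allele combination
    realizable with the included variants (excluded variants held at REF),
    summing p(⟨s,l⟩) computed against the full population frequencies.
    ``included=None`` means all catalog variants (G*).
    """
    space = SmerSpace(ref, all_variants, s, k_cap=k_cap, panel=panel)
    inc = None if included is None else frozenset(included)
    total = 0.0
    for sm in space.iter_smers(included=inc, phased=phased,
                               need_seq=False, need_p=True):
        total += sm.p
    return total


# -- Uniqueness ---------------------------------------------------------------

def uniqueness(counts: SMerCountTable) -> float:
    """U(G): sum over s-mer occurrences of 1/multiplicity.

    Computed as the occurrence sum Σ count·(1/count); the identity with the
    number of distinct sequences serves as a self-test.  Exposed as a
    genome statistic, not a per-variant ranking model.
    """
    return float(sum(c * (1.0 / c) for c in counts.counts.values()))


# -- Hybrid -------------------------------------------------------------------

def compute_p_bars(ref: ReferenceGenome, all_variants: Sequence[VariantRecord],
                   s: int, k_cap: int = 15,
                   panel: Optional[HaplotypePanel] = None,
                   phased: bool = False,
                   space: Optional[SmerSpace] = None) -> tuple[float, float]:
    """Average probabilities (p̄_ref, p̄_*) over (offset, combination) occurrences.

    p̄_ref averages p over the all-REF ⟨s,l⟩-mers (the s-mers of G_ref);
    p̄_* over the ALT-containing ones (in G* but not G_ref).  With no
    variants p̄_* is undefined and returned as 0 with a warning.
    """
    if space is None:
        space = SmerSpace(ref, all_variants, s, k_cap=k_cap, panel=panel)
    ref_sum = ref_n = star_sum = star_n = 0
    for sm in space.iter_smers(phased=phased, need_seq=False, need_p=True):
        if sm.allele_combo:
            star_sum += sm.p
            star_n += 1
        else:
            ref_sum += sm.p
            ref_n += 1
    p_bar_ref = ref_sum / ref_n if ref_n else 0.0
    if star_n == 0:
        log.warning("no ALT-carrying s-mers; p_bar_* undefined, returning 0")
        return p_bar_ref, 0.0
    return p_bar_ref, star_sum / star_n


def build_hybrid_context(ref: ReferenceGenome, all_variants: Sequence[VariantRecord],
                         config: ModelConfig,
                         panel: Optional[HaplotypePanel] = None) -> HybridContext:
    """Count s-mers of G_ref and G* and precompute the average probabilities."""
    phased = config.phased and panel is not None
    space = SmerSpace(ref, all_variants, config.s, k_cap=config.k_cap, panel=panel)
    counts_star = space.count_table()
    ref_space = SmerSpace(ref, [], config.s, k_cap=config.k_cap)
    counts_ref = ref_space.count_table()
    p_bar_ref, p_bar_star = compute_p_bars(ref, all_variants, config.s,
                                           k_cap=config.k_cap, panel=panel,
                                           phased=phased, space=space)
    return HybridContext(counts_ref=counts_ref, counts_star=counts_star,
                         p_bar_ref=p_bar_ref, p_bar_star=p_bar_star,
                         space=space, phased=phased, config=config)


def hybrid_delta(smer: LocalizedSMer, ctx: HybridContext) -> float:
    """ΔH for adding one ALT-carrying ⟨s,l⟩-mer to the genome.

    With n = f_G*(seq) − 1 other occurrences: ΔH = p when n = 0 (a unique
    s-mer contributes its full probability), else (p − ā)/(n+1) where ā is
    the weighted average of p̄_* and p̄_ref by the occurrence counts in G*
    outside vs. inside G_ref.  May be negative: duplicating an existing
    sequence dilutes the uniqueness of its other occurrences.
    """
    if not smer.allele_combo:
        raise SmerError("hybrid_delta requires an ALT-carrying s-mer")
    f_star = ctx.counts_star.get(smer.seq)
    if f_star == 0:
        raise SmerError(f"sequence {smer.seq!r} absent from the G* count table")
    n = f_star - 1
    if n == 0:
        return smer.p
    f_ref = ctx.counts_ref.get(smer.seq)
    mass = (f_star - f_ref) * ctx.p_bar_star + f_ref * ctx.p_bar_ref
    denom = f_star if ctx.own_occurrence_in_average else n
    a_bar = mass / denom
    return (smer.p - a_bar) / (n + 1)


def _alt_smers_of(variant: VariantRecord, ctx: HybridContext) -> Iterable[LocalizedSMer]:
    """Every ⟨s,l⟩-mer overlapping the variant and carrying its ALT allele."""
    if variant.is_indel:
        raise SmerError(f"hybrid model supports SNVs only; variant {variant.vid} "
                        f"at {variant.chrom}:{variant.pos + 1} is an indel")
    space = ctx.space
    for l in window_offsets(variant, space.s, space.ref):
        if not space.offset_valid(variant.chrom, l):
            continue
        for sm in space.enumerate_at(variant.chrom, l, phased=ctx.phased):
            if variant.vid in sm.allele_combo and sm.valid:
                yield sm


def hybrid_score(variant: VariantRecord, ctx: HybridContext) -> float:
    """Approximate hybrid score: Σ ΔH over the variant's ALT-carrying s-mers.

    Phased probabilities are used when the context was built with a panel.
    A variant capped out of a crowded window contributes nothing at that
    offset (its ALT never appears there), mirroring the counting policy.
    """
    return float(sum(hybrid_delta(sm, ctx) for sm in _alt_smers_of(variant, ctx)))


def hybrid_scores(variants: Sequence[VariantRecord], ctx: HybridContext) -> ScoreTable:
    """Approximate hybrid scores for a whole catalog in one enumeration pass.

    Each ALT-carrying s-mer's ΔH is credited to every variant whose ALT it
    contains, so a single sweep over all (offset, combination) pairs scores
    every variant.
    """
    for v in variants:
        if v.is_indel:
            raise SmerError(f"hybrid model supports SNVs only; variant {v.vid} "
                            f"at {v.chrom}:{v.pos + 1} is an indel")
    scores = {v.vid: 0.0 for v in variants}
    for sm in ctx.space.iter_smers(phased=ctx.phased, need_seq=True, need_p=True):
        if not sm.allele_combo or not sm.valid:
            continue
        dh = hybrid_delta(sm, ctx)
        for vid in sm.allele_combo:
            scores[vid] += dh
    cfg = ctx.config or ModelConfig(s=ctx.space.s, k_cap=ctx.space.k_cap)
    return ScoreTable(model="hybrid", scores=scores, config=cfg)


# -- Exact hybrid oracle ------------------------------------------------------

class ExactHybridOracle:
    """Brute-force H(G*) − H(G* ∖ {v}) by full enumeration.

    One global pass over every (offset, combination) of G* records, per
    distinct sequence, its total probability mass and multiplicity, plus
    the occurrences each variant's ALT participates in.  Dropping v removes
    exactly those occurrences (the per-window cap is held fixed at the
    full-catalog cap), leaving the p of surviving s-mers unchanged, so the
    exact score is a per-sequence difference of ratios.
    """

    def __init__(self, ref: ReferenceGenome, all_variants: Sequence[VariantRecord],
                 s: int, k_cap: int = 15,
                 panel: Optional[HaplotypePanel] = None,
                 phased: bool = False,
                 max_occurrences: int = 10 ** 6) -> None:
        self.space = SmerSpace(ref, all_variants, s, k_cap=k_cap, panel=panel)
        self.phased = phased
        self._p_mass: dict[str, float] = defaultdict(float)
        self._mult: Counter = Counter()
        self._removed: dict[int, list[tuple[str, float]]] = defaultdict(list)
        n_occ = 0
        for sm in self.space.iter_smers(phased=phased, need_seq=True, need_p=True):
            if not sm.valid:
                continue
            n_occ += 1
            if n_occ > max_occurrences:
                raise SmerError(f"exact-oracle enumeration exceeds {max_occurrences} "
                                "occurrences")
            self._p_mass[sm.seq] += sm.p
            self._mult[sm.seq] += 1
            for vid in sm.allele_combo:
                self._removed[vid].append((sm.seq, sm.p))

    def h_star(self) -> float:
        """H(G*) itself."""
        return float(sum(mass / self._mult[seq]
                         for seq, mass in self._p_mass.items()))

    def score(self, variant: VariantRecord) -> float:
        """Exact hybrid score H(G*) − H(G* ∖ {v})."""
        delta_p: dict[str, float] = defaultdict(float)
        delta_f: Counter = Counter()
        for seq, p in self._removed.get(variant.vid, ()):
            delta_p[seq] += p
            delta_f[seq] += 1
        total = 0.0
        for seq, dp in delta_p.items():
            f = self._mult[seq]
            before = self._p_mass[seq] / f
            f_after = f - delta_f[seq]
            after = (self._p_mass[seq] - dp) / f_after if f_after > 0 else 0.0
            total += before - after
        return total


def hybrid_score_exact(variant: VariantRecord, ref: ReferenceGenome,
                       all_variants: Sequence[VariantRecord],
                       config: ModelConfig,
                       panel: Optional[HaplotypePanel] = None) -> float:
    """Exact hybrid score of one variant (convenience wrapper)."""
    oracle = ExactHybridOracle(ref, all_variants, config.s, k_cap=config.k_cap,
                               panel=panel,
                               phased=config.phased and panel is not None)
    return oracle.score(variant)


def hybrid_scores_exact(variants: Sequence[VariantRecord], ref: ReferenceGenome,
                        config: ModelConfig,
                        panel: Optional[HaplotypePanel] = None) -> ScoreTable:
    """Exact hybrid scores for a whole catalog (shared global enumeration)."""
    oracle = ExactHybridOracle(ref, variants, config.s, k_cap=config.k_cap,
                               panel=panel,
                               phased=config.phased and panel is not None)
    return ScoreTable(model="hybrid",
                      scores={v.vid: oracle.score(v) for v in variants},
                      config=config)


def hybrid_total(ref: ReferenceGenome, all_variants: Sequence[VariantRecord],
                 included: Optional[Iterable[int]], s: int, k_cap: int = 15,
                 panel: Optional[HaplotypePanel] = None,
                 phased: bool = False) -> float:
    """H(G) of a subset genome by direct double enumeration (test oracle).

    Enumerates the (offset, combination) occurrences of the subset genome,
    builds their multiplicity table, and sums p/f.  Quadratic-ish and meant
    for tiny fixtures only.
    """
    space = SmerSpace(ref, all_variants, s, k_cap=k_cap, panel=panel)
    inc = None if included is None else frozenset(included)
    occurrences = [(sm.seq, sm.p) for sm in
                   space.iter_smers(included=inc, phased=phased,
                                    need_seq=True, need_p=True) if sm.valid]
    mult = Counter(seq for seq, _ in occurrences)
    return float(sum(p / mult[seq] for seq, p in occurrences))
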