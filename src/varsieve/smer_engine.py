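"""Localized s-mer enumeration, population probabilities, and count tables.

A *localized s-mer* ⟨s,l⟩ is a length-s string realizable at genome offset
l by some combination of REF/ALT alleles of the variants starting inside
the window [l, l+s).  Its population probability is

    p(⟨s,l⟩) = p_l · p_s(⟨s,l⟩),

where p_s is the probability a random haplotype's alleles match the
combination (independent-allele product, or a phased-panel co-occurrence
fraction), and the offset prior p_l is uniform over the W valid window
offsets of the genome.  Using the exact W (rather than the genome length
it approximates) makes the probabilities at each offset sum to one, so the
population coverage of the complete augmented genome is exactly 1.

Windows whose reference substring contains N are excluded from W and from
all enumeration and counting: assembly gaps would otherwise dominate.
Counting is forward-strand only.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .genome_io import HaplotypePanel, ReferenceGenome, VariantRecord

log = logging.getLogger(__name__)

_ENUM_BOUND = 2 ** 24


class SmerError(Exception):
    """Fatal enumeration error (bad configuration or inconsistent inputs)."""


@dataclass(frozen=True)
class ModelConfig:
    """Scoring/selection configuration.

    s        window size (s-mer length); typically the maximum read length.
    k_cap    per-window variant cap: windows with more variants keep the
             leftmost plus the k_cap-1 highest-AF others (default 15).
    phased   use haplotype co-occurrence for window probabilities.
    w        blowup-avoidance penalty factor in (0, 1] (default 0.5).
    erg_r    enhanced-segment context window r; defaults to s.
    """

    s: int
    k_cap: int = 15
    phased: bool = False
    w: float = 0.5
    erg_r: Optional[int] = None

    def __post_init__(self) -> None:
        if self.s < 2:
            raise SmerError(f"window size s must be >= 2, got {self.s}")
        if not 1 <= self.k_cap <= 24:
            raise SmerError(f"k_cap must be in [1, 24], got {self.k_cap}")
        if not 0 < self.w <= 1:
            raise SmerError(f"penalty w must be in (0, 1], got {self.w}")

    @property
    def erg_window(self) -> int:
        return self.erg_r if self.erg_r is not None else self.s


@dataclass
class LocalizedSMer:
    """A length-s sequence anchored at an offset, with its probability.

    ``allele_combo`` is the set of variant ids set to ALT; ``window_ids``
    the (capped) variant ids considered at this offset.  ``valid`` is False
    when an indel combination runs off the chromosome end and no full-length
    sequence exists.
    """

    chrom: str
    l: int
    seq: str
    allele_combo: tuple[int, ...]
    window_ids: tuple[int, ...]
    p_s: float
    p: float
    valid: bool = True


@dataclass
class SMerCountTable:
    """Multiplicity f_G(seq) of every length-s sequence in a genome."""

    s: int
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, seq: str, default: int = 0) -> int:
        return self.counts.get(seq, default)

    def __getitem__(self, seq: str) -> int:
        return self.counts[seq]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seq in sorted(self.counts):
                fh.write(f"{seq}\t{self.counts[seq]}\n")


def window_offsets(variant: VariantRecord, s: int, ref: ReferenceGenome) -> list[int]:
    """All window offsets l whose ⟨s,l⟩-mers overlap the variant.

    SNVs and insertions: windows overlapping the anchor base
    (l <= pos < l+s).  Deletions: windows overlapping the anchor or any
    deleted base (l <= pos+len(REF)-1 and l+s > pos).  Offsets are clipped
    to [0, chrom_len - s]; a chromosome shorter than s yields none.
    """
    chrom_len = len(ref.chromosomes[variant.chrom])
    if chrom_len < s:
        log.warning("chromosome %s shorter than window %d", variant.chrom, s)
        return []
    span_last = variant.pos
    if len(variant.ref_allele) > len(variant.alt_allele):  # deletion
        span_last = variant.pos + len(variant.ref_allele) - 1
    lo = max(0, variant.pos - s + 1)
    hi = min(span_last, chrom_len - s)
    return list(range(lo, hi + 1))


def _edited_window(chrom_seq: str, l: int, s: int,
                   alt_vars: Sequence[VariantRecord]) -> Optional[str]:
    """Length-s prefix of the window at l with the given ALT edits applied.

    Extends rightward in reference coordinates as deletions consume bases.
    Returns None when the chromosome ends before s edited bases exist.
    """
    if not alt_vars:
        return chrom_seq[l:l + s]
    pieces: list[str] = []
    cursor = l
    length = 0
    for v in alt_vars:
        if v.pos < cursor:
            continue  # overlapping edit already consumed (rejected upstream)
        pieces.append(chrom_seq[cursor:v.pos])
        length += v.pos - cursor
        pieces.append(v.alt_allele)
        length += len(v.alt_allele)
        cursor = v.pos + len(v.ref_allele)
        if length >= s:
            break
    if length < s:
        pieces.append(chrom_seq[cursor:cursor + (s - length)])
        length += min(len(chrom_seq) - cursor, s - length)
    if length < s:
        return None
    return "".join(pieces)[:s]


class SmerSpace:
    """Enumerator over the localized s-mers of a genome and its variants.

    Centralizes the window-offset universe (N-free offsets, W), the
    per-window variant cap, combination enumeration, probabilities, and
    count tables, so that scoring, counting, and ERG export all share one
    blowup policy.
    """

    def __init__(self, ref: ReferenceGenome, variants: Sequence[VariantRecord],
                 s: int, k_cap: int = 15,
                 panel: Optional[HaplotypePanel] = None) -> None:
        if not 1 <= k_cap <= 24:
            raise SmerError(f"k_cap must be in [1, 24], got {k_cap}")
        self.ref = ref
        self.s = s
        self.k_cap = k_cap
        self.panel = panel
        self.variants = list(variants)
        self.by_id = {v.vid: v for v in self.variants}
        self._by_chrom: dict[str, list[VariantRecord]] = {}
        for v in sorted(self.variants, key=lambda v: (v.pos, v.vid)):
            self._by_chrom.setdefault(v.chrom, []).append(v)
        self._pos_arrays = {c: np.array([v.pos for v in vs], dtype=np.int64)
                            for c, vs in self._by_chrom.items()}
        # Valid (N-free) window offsets per chromosome.
        self._valid: dict[str, np.ndarray] = {}
        total = 0
        for name, seq in ref.chromosomes.items():
            n_off = len(seq) - s + 1
            if n_off <= 0:
                self._valid[name] = np.zeros(0, dtype=bool)
                continue
            has_n = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
            cum = np.concatenate(([0], np.cumsum(has_n)))
            ok = (cum[s:] - cum[:-s]) == 0
            self._valid[name] = ok
            total += int(ok.sum())
        if total == 0:
            raise SmerError("genome has no valid window offsets (too short or all N)")
        self.n_offsets = total  # W, the p_l denominator

    # -- window machinery -------------------------------------------------

    def offset_valid(self, chrom: str, l: int) -> bool:
        ok = self._valid.get(chrom)
        return ok is not None and 0 <= l < len(ok) and bool(ok[l])

    def iter_offsets(self) -> Iterator[tuple[str, int]]:
        for chrom, ok in self._valid.items():
            for l in np.flatnonzero(ok):
                yield chrom, int(l)

    def window_variants(self, chrom: str, l: int) -> list[VariantRecord]:
        """Capped variants starting in [l, l+s): leftmost + top-AF others."""
        pos = self._pos_arrays.get(chrom)
        if pos is None or len(pos) == 0:
            return []
        lo = int(np.searchsorted(pos, l, side="left"))
        hi = int(np.searchsorted(pos, l + self.s, side="left"))
        win = self._by_chrom[chrom][lo:hi]
        if len(win) <= self.k_cap:
            return win
        rest = sorted(win[1:], key=lambda v: (-v.alt_freq, v.pos, v.vid))
        kept = [win[0]] + rest[:self.k_cap - 1]
        kept.sort(key=lambda v: (v.pos, v.vid))
        return kept

    # -- probabilities -----------------------------------------------------

    def _combo_probability(self, capped: Sequence[VariantRecord],
                           bits: Sequence[int], phased: bool) -> float:
        if not capped:
            return 1.0
        if phased:
            cols = [v.panel_column for v in capped]
            if any(c is None for c in cols):
                raise SmerError("phased probabilities requested without a panel")
            match = np.ones(len(cols[0]), dtype=bool)
            for col, bit in zip(cols, bits):
                match &= col == bit
            return float(match.sum()) / len(match)
        p = 1.0
        for v, bit in zip(capped, bits):
            p *= v.alt_freq if bit else 1.0 - v.alt_freq
        return p

    def enumerate_at(self, chrom: str, l: int,
                     included: Optional[frozenset] = None,
                     phased: bool = False,
                     need_seq: bool = True,
                     need_p: bool = True) -> list[LocalizedSMer]:
        """All ⟨s,l⟩-mers at one offset, one per REF/ALT combination.

        ``included`` restricts the genome to a subset of variant ids:
        excluded variants are held at REF but still contribute their
        REF-match probability (the probability model is always the full
        population).  2^n combinations for n capped window variants.
        """
        capped = self.window_variants(chrom, l)
        choices = []
        for v in capped:
            if included is not None and v.vid not in included:
                choices.append((0,))
            else:
                choices.append((0, 1))
        n_combos = 1
        for c in choices:
            n_combos *= len(c)
        if n_combos > _ENUM_BOUND:
            raise SmerError(f"combination blowup at {chrom}:{l}: {n_combos} combos")
        chrom_seq = self.ref.chromosomes[chrom]
        out: list[LocalizedSMer] = []
        window_ids = tuple(v.vid for v in capped)
        for bits in itertools.product(*choices):
            alt_vars = [v for v, b in zip(capped, bits) if b]
            seq = ""
            valid = True
            if need_seq:
                built = _edited_window(chrom_seq, l, self.s, alt_vars)
                if built is None:
                    valid = False
                else:
                    seq = built
            p_s = self._combo_probability(capped, bits, phased) if need_p else 0.0
            out.append(LocalizedSMer(
                chrom=chrom, l=l, seq=seq,
                allele_combo=tuple(v.vid for v in alt_vars),
                window_ids=window_ids, p_s=p_s,
                p=p_s / self.n_offsets, valid=valid))
        return out

    def iter_smers(self, included: Optional[frozenset] = None,
                   phased: bool = False, need_seq: bool = True,
                   need_p: bool = True) -> Iterator[LocalizedSMer]:
        """All ⟨s,l⟩-mers of the (sub)genome, every valid offset."""
        for chrom, l in self.iter_offsets():
            yield from self.enumerate_at(chrom, l, included=included,
                                         phased=phased, need_seq=need_seq,
                                         need_p=need_p)

    # -- counting ----------------------------------------------------------

    def count_table(self, included: Optional[frozenset] = None) -> SMerCountTable:
        """Multiplicity of every ⟨s,l⟩-mer, once per (offset, combination)."""
        counts: Counter = Counter()
        for chrom, ok in self._valid.items():
            chrom_seq = self.ref.chromosomes[chrom]
            pos = self._pos_arrays.get(chrom)
            for l in np.flatnonzero(ok):
                l = int(l)
                if pos is None or len(pos) == 0 or not (
                        np.searchsorted(pos, l, side="left")
                        < np.searchsorted(pos, l + self.s, side="left")):
                    counts[chrom_seq[l:l + self.s]] += 1
                    continue
                for sm in self.enumerate_at(chrom, l, included=included,
                                            need_p=False):
                    if sm.valid:
                        counts[sm.seq] += 1
        return SMerCountTable(s=self.s, counts=counts)


# -- functional wrappers ----------------------------------------------------

def enumerate_smers_at(ref: ReferenceGenome, variants: Sequence[VariantRecord],
                       l: int, s: int, k_cap: int = 15, chrom: Optional[str] = None,
                       panel: Optional[HaplotypePanel] = None,
                       phased: bool = False) -> list[LocalizedSMer]:
    """One-shot enumeration of the ⟨s,l⟩-mers at a single offset."""
    if chrom is None:
        chrom = next(iter(ref.chromosomes))
    space = SmerSpace(ref, variants, s, k_cap=k_cap, panel=panel)
    return space.enumerate_at(chrom, l, phased=phased)


def smer_probability(smer: LocalizedSMer, variants: Sequence[VariantRecord],
                     n_offsets: int,
                     panel: Optional[HaplotypePanel] = None,
                     phased: bool = False) -> float:
    """Recompute p(⟨s,l⟩) = p_s / W for a localized s-mer.

    ``variants`` must contain the smer's window variants.  Phased mode
    counts the panel haplotypes whose alleles match the combination at all
    window variants; unphased mode multiplies marginal frequencies.
    """
    by_id = {v.vid: v for v in variants}
    capped = [by_id[i] for i in smer.window_ids]
    bits = [1 if v.vid in smer.allele_combo else 0 for v in capped]
    if phased:
        if panel is None or any(v.panel_column is None for v in capped):
            raise SmerError("phased probability requested without a panel")
        if not capped:
            return 1.0 / n_offsets
        match = np.ones(panel.n_haplotypes, dtype=bool)
        for v, bit in zip(capped, bits):
            match &= v.panel_column == bit
        return float(match.sum()) / panel.n_haplotypes / n_offsets
    p_s = 1.0
    for v, bit in zip(capped, bits):
        p_s *= v.alt_freq if bit else 1.0 - v.alt_freq
    return p_s / n_offsets


def count_smers(ref: ReferenceGenome, variants: Sequence[VariantRecord],
                s: int, k_cap: int = 15) -> SMerCountTable:
    """Count every ⟨s,l⟩-mer of the augmented genome, forward strand only.

    With ``variants`` empty this is plain s-mer counting of the linear
    reference.  Equivalent to counting the length-s substrings of the
    linear FASTA plus the per-window enhanced FASTA export.
    """
    space = SmerSpace(ref, variants, s, k_cap=k_cap)
    return space.count_table()


def external_counter_export(ref: ReferenceGenome, variants: Sequence[VariantRecord],
                            s: int, k_cap: int = 15,
                            out: str | Path = "augmented.fa") -> int:
    """Write the ALT-carrying windows as a FASTA for an external k-mer counter.

    The length-s substrings of this file, together with the reference
    FASTA's, reproduce :func:`count_smers` exactly once per
    (offset, combination).  Records are named ``chrom:l:mask`` where the
    mask lists the ALT variant ids.  Returns the number of records written.
    """
    space = SmerSpace(ref, variants, s, k_cap=k_cap)
    n = 0
    with open(out, "w") as fh:
        for chrom, l in space.iter_offsets():
            if not space.window_variants(chrom, l):
                continue
            for sm in space.enumerate_at(chrom, l, need_p=False):
                if not sm.allele_combo or not sm.valid:
                    continue
                mask = "-".join(str(i) for i in sm.allele_combo)
                fh.write(f">{chrom}:{l}:{mask}\n{sm.seq}\n")
                n += 1
    return n
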