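"""Enhanced Reference Genome segments and the major-allele baseline.

The Enhanced Reference Genome (ERG) extends a linear reference with
*enhanced segments*: ALT-carrying reference substrings with r−1 bases of
flanking context, so a linear aligner can match length-r reads that
overlap variants.  A cluster of n variants that can co-occur within one
length-r window yields 2^n − 1 segments, one per non-empty ALT subset.

Segments are anchored at their leftmost ALT variant: each variant owns the
subsets in which it is the leftmost member, which realizes the 2^n − 1
total while deduplicating overlapping windows.  When a window holds more
than k variants, the anchor keeps itself plus the k−1 highest-frequency
others (default k = 15); anchoring guarantees every variant's ALT still
appears in at least one segment.

The major-allele baseline is a linear reference with every variant site
set to its most frequent allele.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .genome_io import ReferenceGenome, VariantRecord, write_reference

log = logging.getLogger(__name__)


class ErgError(Exception):
    pass


@dataclass(frozen=True)
class EnhancedSegment:
    """One ALT-carrying reference substring with flanking context."""

    chrom: str
    start: int  # reference span [start, end), clipped to the chromosome
    end: int
    alt_ids: frozenset
    seq: str
    anchor_id: int  # leftmost ALT variant id

    def name(self) -> str:
        mask = "-".join(str(i) for i in sorted(self.alt_ids))
        return f"{self.chrom}:{self.start}:{mask}"


def _apply_edits(chrom_seq: str, start: int, end: int,
                 alt_vars: Sequence[VariantRecord]) -> str:
    """Reference span [start, end) with the given ALT edits applied."""
    pieces: list[str] = []
    cursor = start
    for v in sorted(alt_vars, key=lambda v: v.pos):
        if v.pos < cursor:
            log.warning("edit at %s:%d overlaps previous edit; skipped",
                        v.chrom, v.pos + 1)
            continue
        pieces.append(chrom_seq[cursor:v.pos])
        pieces.append(v.alt_allele)
        cursor = v.pos + len(v.ref_allele)
    pieces.append(chrom_seq[cursor:end])
    return "".join(pieces)


def build_enhanced_segments(ref: ReferenceGenome,
                            variants: Sequence[VariantRecord],
                            r: int, k: int = 15) -> list[EnhancedSegment]:
    """Enumerate enhanced segments with leftmost-ALT anchoring.

    For each variant v, the co-window set holds the variants starting
    within r−1 bases to v's right (all mutually co-windowed with v in a
    length-r read).  If the set including v exceeds k, it is restricted to
    v plus the k−1 highest-AF members (AF ties broken leftmost).  One
    segment is emitted per subset containing v, spanning
    [pos(v)−(r−1), rightmost ALT end+(r−1)) clipped to the chromosome.
    """
    if r < 2:
        raise ErgError(f"ERG window r must be >= 2, got {r}")
    if k > 24:
        raise ErgError(f"ERG variant cap k={k} exceeds the enumeration bound 24")
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in sorted(variants, key=lambda v: (v.pos, v.vid)):
        by_chrom.setdefault(v.chrom, []).append(v)

    segments: list[EnhancedSegment] = []
    seen: set[tuple[int, frozenset]] = set()
    for chrom in ref.names:
        vs = by_chrom.get(chrom, [])
        chrom_seq = ref.chromosomes[chrom]
        for i, anchor in enumerate(vs):
            co = [u for u in vs[i + 1:] if u.pos - anchor.pos <= r - 1]
            if 1 + len(co) > k:
                co = sorted(co, key=lambda u: (-u.alt_freq, u.pos, u.vid))[:k - 1]
                co.sort(key=lambda u: (u.pos, u.vid))
            for size in range(len(co) + 1):
                for subset in itertools.combinations(co, size):
                    members = (anchor,) + subset
                    start = max(0, anchor.pos - (r - 1))
                    end = min(len(chrom_seq),
                              max(m.end for m in members) + (r - 1))
                    key = (start, frozenset(m.vid for m in members))
                    if key in seen:
                        continue
                    seen.add(key)
                    segments.append(EnhancedSegment(
                        chrom=chrom, start=start, end=end,
                        alt_ids=key[1],
                        seq=_apply_edits(chrom_seq, start, end, members),
                        anchor_id=anchor.vid))
    return segments


def write_erg_fasta(segments: Sequence[EnhancedSegment], ref: ReferenceGenome,
                    out: str | Path, width: int = 70) -> None:
    """Write the original reference records followed by one record per segment."""
    with open(out, "w") as fh:
        for name, seq in ref.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
        for seg in segments:
            fh.write(f">{seg.name()}\n")
            for i in range(0, len(seg.seq), width):
                fh.write(seg.seq[i:i + width] + "\n")


def build_major_allele_reference(
        ref: ReferenceGenome,
        variants: Sequence[VariantRecord],
) -> tuple[ReferenceGenome, list[tuple[str, int, int]]]:
    """Linear reference with every variant site set to its most frequent allele.

    Per site (grouped by chromosome, position, and REF), the single most
    frequent allele among {REF, ALTs} wins, with REF frequency
    1 − Σ ALT frequencies; ties keep REF.  For a biallelic site this is
    simply "ALT iff AF > 0.5".  Indels shift coordinates; the returned
    offset map holds one (chrom, ref_pos, shifted_pos) row per applied
    indel, giving the mapping at the first base after the edit (0-based).
    Overlapping winning ALTs: the leftmost is applied, the conflict warned.
    """
    sites: dict[tuple[str, int, str], list[VariantRecord]] = {}
    for v in variants:
        sites.setdefault((v.chrom, v.pos, v.ref_allele), []).append(v)

    winners: dict[str, list[VariantRecord]] = {}
    for (chrom, pos, ref_allele), alts in sites.items():
        ref_freq = max(0.0, 1.0 - sum(a.alt_freq for a in alts))
        best = max(alts, key=lambda a: (a.alt_freq, -a.vid))
        if best.alt_freq > ref_freq and best.alt_freq > 0.5:
            winners.setdefault(chrom, []).append(best)

    chroms: dict[str, str] = {}
    offset_map: list[tuple[str, int, int]] = []
    for name, seq in ref.chromosomes.items():
        edits = sorted(winners.get(name, []), key=lambda v: v.pos)
        pieces: list[str] = []
        cursor = 0
        shift = 0
        for v in edits:
            if v.pos < cursor:
                log.warning("major-allele edit at %s:%d overlaps previous edit; "
                            "leftmost kept", name, v.pos + 1)
                continue
            pieces.append(seq[cursor:v.pos])
            pieces.append(v.alt_allele)
            cursor = v.pos + len(v.ref_allele)
            if len(v.alt_allele) != len(v.ref_allele):
                shift += len(v.alt_allele) - len(v.ref_allele)
                offset_map.append((name, cursor, cursor + shift))
        pieces.append(seq[cursor:])
        chroms[name] = "".join(pieces)
    return ReferenceGenome(chroms), offset_map


def write_offset_map(offset_map: Sequence[tuple[str, int, int]],
                     out: str | Path) -> None:
    """Write the indel coordinate-shift map as TSV (1-based positions)."""
    with open(out, "w") as fh:
        fh.write("chrom\tref_pos\tshifted_pos\n")
        for chrom, ref_pos, shifted in offset_map:
            fh.write(f"{chrom}\t{ref_pos + 1}\t{shifted + 1}\n")
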