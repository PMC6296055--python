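"""Ranking and budgeted greedy selection with blowup avoidance.

Static selection takes the top-scoring variants directly.  The
blowup-avoiding variants ("+" models) run a greedy loop: after each
selection, every unselected variant within s nt on the same chromosome has
its current score multiplied by the penalty factor w (0 < w ≤ 1; w = 0 is
accepted as a diagnostic mode).  Penalties accumulate multiplicatively
when several selected variants neighbor the same candidate.  w = 1 leaves
scores untouched, reproducing the static ranking; w near 0 defers every
clustered variant until the isolated ones are exhausted.

Ties are broken positionally: the variant on the lower-numbered chromosome
(reference order), then with the smaller offset, wins.
"""

from __future__ import annotations

import heapq
import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .genome_io import VariantRecord
from .smer_engine import ModelConfig
from .variant_models import ScoreTable

log = logging.getLogger(__name__)


class SelectionError(Exception):
    pass


@dataclass
class SelectionResult:
    """Ordered chosen variants with penalized scores and penalty provenance."""

    ordered_ids: list[int]
    final_scores: dict[int, float]     # score at selection time (selected ids)
    original_scores: dict[int, float]  # model scores for the full catalog
    penalty_counts: dict[int, int]     # penalties received before selection
    budget: Union[int, float]
    w: float = 1.0
    s: int = 0

    def __post_init__(self) -> None:
        if len(set(self.ordered_ids)) != len(self.ordered_ids):
            raise SelectionError("duplicate id in selection order")


def _chrom_ranks(variants: Sequence[VariantRecord]) -> dict[str, int]:
    ranks: dict[str, int] = {}
    for v in variants:
        if v.chrom not in ranks:
            ranks[v.chrom] = len(ranks)
    return ranks


def _tie_key(v: VariantRecord, ranks: Mapping[str, int]) -> tuple:
    return (ranks[v.chrom], v.pos, v.alt_index, v.vid)


def rank_variants(scores: Union[ScoreTable, Mapping[int, float]],
                  variants: Sequence[VariantRecord]) -> list[int]:
    """Variant ids in descending score order, ties broken positionally."""
    table = scores.scores if isinstance(scores, ScoreTable) else scores
    ranks = _chrom_ranks(variants)
    by_id = {v.vid: v for v in variants}
    return sorted(table, key=lambda vid: (-table[vid], _tie_key(by_id[vid], ranks)))


def _resolve_budget(budget: Union[int, float], n: int) -> int:
    """Count budgets pass through; fraction budgets round to nearest, min 1."""
    if n == 0:
        return 0
    if isinstance(budget, float):
        if not 0 < budget <= 1:
            raise SelectionError(f"fraction budget must be in (0, 1], got {budget}")
        return max(1, min(n, int(math.floor(budget * n + 0.5))))
    count = int(budget)
    if count <= 0:
        raise SelectionError(f"count budget must be positive, got {budget}")
    return min(count, n)


def select_variants(variants: Sequence[VariantRecord],
                    scores: Union[ScoreTable, Mapping[int, float]],
                    budget: Union[int, float],
                    w: float = 0.5,
                    s: int = 100) -> SelectionResult:
    """Greedy budgeted selection with the w-penalty re-scoring scheme.

    Repeatedly takes the maximum current score (positional tie-break),
    then multiplies the current score of every unselected variant within
    s nt on the same chromosome by w.  Implemented with a lazily
    invalidated priority queue — safe because penalties only ever decrease
    scores.  ``budget`` is an integer count or a float fraction in (0, 1].
    """
    table = dict(scores.scores if isinstance(scores, ScoreTable) else scores)
    if not 0 <= w <= 1:
        raise SelectionError(f"penalty w must be in [0, 1], got {w}")
    catalog = [v for v in variants if v.vid in table]
    n_take = _resolve_budget(budget, len(catalog))
    ranks = _chrom_ranks(catalog)
    by_id = {v.vid: v for v in catalog}

    # Same-chromosome neighbor lookup by start position.
    chrom_sorted: dict[str, list[VariantRecord]] = {}
    for v in sorted(catalog, key=lambda v: (v.pos, v.vid)):
        chrom_sorted.setdefault(v.chrom, []).append(v)
    chrom_pos = {c: [v.pos for v in vs] for c, vs in chrom_sorted.items()}

    current = dict(table)
    penalties = {vid: 0 for vid in table}
    selected: set[int] = set()
    heap = [(-table[vid], _tie_key(by_id[vid], ranks), vid, table[vid])
            for vid in table]
    heapq.heapify(heap)

    ordered: list[int] = []
    final: dict[int, float] = {}
    while len(ordered) < n_take and heap:
        neg, _, vid, score_at_push = heapq.heappop(heap)
        if vid in selected or score_at_push != current[vid]:
            continue  # stale entry
        selected.add(vid)
        ordered.append(vid)
        final[vid] = current[vid]
        v = by_id[vid]
        positions = chrom_pos[v.chrom]
        lo = bisect_left(positions, v.pos - s)
        hi = bisect_right(positions, v.pos + s)
        for u in chrom_sorted[v.chrom][lo:hi]:
            if u.vid in selected:
                continue
            current[u.vid] *= w
            penalties[u.vid] += 1
            heapq.heappush(heap, (-current[u.vid], _tie_key(u, ranks),
                                  u.vid, current[u.vid]))
    return SelectionResult(ordered_ids=ordered, final_scores=final,
                           original_scores=table, penalty_counts=penalties,
                           budget=budget, w=w, s=s)


def select_variants_bruteforce(variants: Sequence[VariantRecord],
                               scores: Union[ScoreTable, Mapping[int, float]],
                               budget: Union[int, float],
                               w: float = 0.5,
                               s: int = 100) -> list[int]:
    """Reference implementation: recompute the argmax at every step.

    Independent oracle for :func:`select_variants`; quadratic, test-only.
    """
    table = dict(scores.scores if isinstance(scores, ScoreTable) else scores)
    catalog = [v for v in variants if v.vid in table]
    n_take = _resolve_budget(budget, len(catalog))
    ranks = _chrom_ranks(catalog)
    by_id = {v.vid: v for v in catalog}
    current = dict(table)
    remaining = set(table)
    ordered: list[int] = []
    while len(ordered) < n_take and remaining:
        best = min(remaining,
                   key=lambda vid: (-current[vid], _tie_key(by_id[vid], ranks)))
        remaining.discard(best)
        ordered.append(best)
        b = by_id[best]
        for vid in remaining:
            u = by_id[vid]
            if u.chrom == b.chrom and abs(u.pos - b.pos) <= s:
                current[vid] *= w
    return ordered


def selection_report(result: SelectionResult,
                     variants: Sequence[VariantRecord],
                     out: str | Path) -> None:
    """TSV report: one row per selected variant, in selection order."""
    by_id = {v.vid: v for v in variants}
    with open(out, "w") as fh:
        fh.write("rank\tchrom\tpos\tref\talt\toriginal_score\tfinal_score\t"
                 "n_penalties\n")
        for rank, vid in enumerate(result.ordered_ids, start=1):
            v = by_id[vid]
            fh.write(f"{rank}\t{v.chrom}\t{v.pos + 1}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t{result.original_scores[vid]:.12g}\t"
                     f"{result.final_scores[vid]:.12g}\t"
                     f"{result.penalty_counts[vid]}\n")


def write_snp_list(selected: Sequence[VariantRecord], out: str | Path) -> None:
    """One line per selected SNV in a graph-aligner SNP-list dialect.

    Columns: id, type ("single"), chrom, 0-based pos, alt.  Mirrors common
    graph-indexer inputs; bit-exactness with any particular tool is not
    claimed.  Non-SNVs are skipped with a warning.
    """
    with open(out, "w") as fh:
        for v in selected:
            if not v.is_snv:
                log.warning("snp list skips non-SNV at %s:%d", v.chrom, v.pos + 1)
                continue
            fh.write(f"v{v.vid}\tsingle\t{v.chrom}\t{v.pos}\t{v.alt_allele}\n")
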