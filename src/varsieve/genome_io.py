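"""FASTA/VCF input and output, coordinate normalization, and haplotype panels.

Internal coordinates are 0-based, half-open everywhere; conversion to and
from the 1-based conventions of VCF and the score TSV happens only at the
file boundary.  Multi-allelic VCF records are split into independent
biallelic :class:`VariantRecord` objects, each carrying a single ALT allele
and its frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_ALLELE_BASES = frozenset("ACGT")


class GenomeIOError(Exception):
    """Fatal input/output error (malformed or inconsistent files)."""


@dataclass
class ReferenceGenome:
    """Named chromosome sequences; houses the linear reference G_ref.

    ``chromosomes`` is an ordered mapping of chromosome name to uppercase
    sequence over {A,C,G,T,N}.
    """

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise GenomeIOError(f"empty sequence for chromosome {name!r}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def chrom_order(self, name: str) -> int:
        """Rank of a chromosome in reference order (tie-break authority)."""
        return self.names.index(name)


@dataclass
class VariantRecord:
    """One biallelic variant (multi-allelic sites are split upstream).

    ``pos`` is the 0-based offset of the first REF base.  ``panel_column``
    is an optional 0/1 vector over the H panel haplotypes (1 = carries ALT).
    ``source_record``/``alt_index`` locate the record in its source VCF so
    a selected subset can be written back out.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_freq: float
    vid: int
    panel_column: Optional[np.ndarray] = None
    source_record: int = -1
    alt_index: int = 0

    @property
    def end(self) -> int:
        """0-based end of the REF span (half-open)."""
        return self.pos + len(self.ref_allele)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv


@dataclass
class HaplotypePanel:
    """Phased haplotype panel; the per-variant bit vectors live on the records."""

    n_haplotypes: int
    sample_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise GenomeIOError("haplotype panel needs H >= 2")


@dataclass
class VcfReadStats:
    """Bookkeeping of accepted and rejected records during VCF parsing."""

    n_source_records: int = 0
    n_accepted: int = 0
    n_ref_mismatch: int = 0
    n_symbolic: int = 0
    n_overlap_rejected: int = 0
    n_bad_allele: int = 0

    @property
    def n_rejected(self) -> int:
        return (self.n_ref_mismatch + self.n_symbolic
                + self.n_overlap_rejected + self.n_bad_allele)


def read_reference(path: str | Path) -> ReferenceGenome:
    """Read a (multi-record) FASTA into a :class:`ReferenceGenome`.

    Sequences are uppercased (soft-masking discarded); record order is
    preserved.  Duplicate record names and empty files are fatal.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise GenomeIOError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise GenomeIOError(
                f"record {rec.id!r} contains non-ACGTN characters: {sorted(bad)}")
        chroms[rec.id] = seq
    if not chroms:
        raise GenomeIOError(f"no FASTA records in {path}")
    return ReferenceGenome(chroms)


def write_reference(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    """Write a :class:`ReferenceGenome` as FASTA, ``width`` bases per line."""
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _allele_ok(allele: str) -> bool:
    return bool(allele) and set(allele) <= _ALLELE_BASES


def read_variants(
    path: str | Path,
    ref: ReferenceGenome,
    use_gt: bool = False,
) -> tuple[list[VariantRecord], Optional[HaplotypePanel], VcfReadStats]:
    """Read a VCF into split biallelic :class:`VariantRecord` objects.

    Each ALT of a multi-allelic record becomes its own record.  ``alt_freq``
    comes from the per-ALT ``AF`` INFO value or, when ``use_gt`` is set (or
    AF is absent but phased genotypes are present), from the fraction of
    ALT-carrying haplotypes.  Positions are converted to 0-based.  Records
    whose REF disagrees with the reference are dropped and counted, as are
    symbolic ALTs and indels overlapping a previously accepted record.
    Records with ``alt_freq == 0`` are retained (they simply score 0).

    Returns ``(variants, panel, stats)``; ``panel`` is ``None`` when no
    fully phased genotype columns are available.
    """
    vf = pysam.VariantFile(str(path))
    sample_names = list(vf.header.samples)
    phasing_ok = bool(sample_names)
    stats = VcfReadStats()
    variants: list[VariantRecord] = []
    # REF span of the most recent accepted record per chromosome, used to
    # reject overlapping indels; siblings of one source record are exempt.
    last_span: dict[str, tuple[int, int, bool, int]] = {}

    for ordinal, rec in enumerate(vf):
        stats.n_source_records += 1
        chrom = rec.chrom
        pos = rec.start  # pysam is already 0-based
        ref_allele = (rec.ref or "").upper()
        alts = [a.upper() if a else "" for a in (rec.alts or ())]

        if chrom not in ref.chromosomes:
            log.warning("record %s:%d on unknown chromosome, dropped", chrom, pos + 1)
            stats.n_ref_mismatch += len(alts)
            continue
        if not _allele_ok(ref_allele):
            log.warning("record %s:%d has non-ACGT REF, dropped", chrom, pos + 1)
            stats.n_bad_allele += len(alts)
            continue
        if ref.chromosomes[chrom][pos:pos + len(ref_allele)] != ref_allele:
            log.warning("REF mismatch at %s:%d (VCF %s), record dropped",
                        chrom, pos + 1, ref_allele)
            stats.n_ref_mismatch += len(alts)
            continue

        af_info = rec.info.get("AF", None)
        if af_info is not None and not isinstance(af_info, (tuple, list)):
            af_info = (af_info,)

        gt_matrix = None  # per-ALT haplotype carrier columns
        if sample_names:
            alleles: list[int] = []
            rec_phased = True
            for sm in rec.samples.values():
                gt = sm.get("GT", None)
                if gt is None or any(a is None for a in gt):
                    rec_phased = False
                    gt = tuple(0 for _ in (gt or (0, 0)))
                if len(gt) > 1 and not sm.phased:
                    rec_phased = False
                alleles.extend(int(a) if a is not None else 0 for a in gt)
            if not rec_phased and phasing_ok:
                log.warning("unphased genotypes at %s:%d; phasing disabled genome-wide",
                            chrom, pos + 1)
                phasing_ok = False
            gt_matrix = np.asarray(alleles, dtype=np.int16)

        for alt_index, alt in enumerate(alts):
            if not alt or alt == "*" or alt.startswith("<") or "[" in alt or "]" in alt:
                log.warning("symbolic/unsupported ALT %r at %s:%d, dropped",
                            alt, chrom, pos + 1)
                stats.n_symbolic += 1
                continue
            if not _allele_ok(alt):
                log.warning("non-ACGT ALT %r at %s:%d, dropped", alt, chrom, pos + 1)
                stats.n_bad_allele += 1
                continue

            is_indel = len(ref_allele) != 1 or len(alt) != 1
            prev = last_span.get(chrom)
            if prev is not None:
                p_start, p_end, p_indel, p_ordinal = prev
                if pos < p_end and (is_indel or p_indel) and p_ordinal != ordinal:
                    log.warning("indel at %s:%d overlaps previous record, dropped",
                                chrom, pos + 1)
                    stats.n_overlap_rejected += 1
                    continue

            column = None
            if gt_matrix is not None:
                column = (gt_matrix == alt_index + 1).astype(np.uint8)

            if use_gt:
                if column is None:
                    raise GenomeIOError(
                        "use_gt requested but VCF has no genotype columns")
                freq = float(column.mean())
            elif column is not None:
                # A genotype panel is authoritative when present: the exact
                # haplotype fraction keeps panel_column and alt_freq
                # consistent to machine precision (htslib stores AF as a
                # 32-bit float).  AF INFO is cross-checked against it.
                freq = float(column.mean())
                if af_info is not None and alt_index < len(af_info) and \
                        abs(float(af_info[alt_index]) - freq) > 1e-6:
                    log.warning("AF INFO %.6g disagrees with GT-derived %.6g at "
                                "%s:%d; using GT", float(af_info[alt_index]),
                                freq, chrom, pos + 1)
            elif af_info is not None and alt_index < len(af_info):
                freq = float(af_info[alt_index])
            else:
                raise GenomeIOError(
                    f"record {chrom}:{pos + 1} has no AF INFO and no genotypes "
                    "(pass use_gt or add AF)")
            if not 0.0 <= freq <= 1.0:
                raise GenomeIOError(f"allele frequency {freq} out of [0,1] at "
                                    f"{chrom}:{pos + 1}")

            variants.append(VariantRecord(
                chrom=chrom, pos=pos, ref_allele=ref_allele, alt_allele=alt,
                alt_freq=freq, vid=len(variants), panel_column=column,
                source_record=ordinal, alt_index=alt_index))
            stats.n_accepted += 1
            last_span[chrom] = (pos, pos + len(ref_allele), is_indel, ordinal)

    panel: Optional[HaplotypePanel] = None
    if phasing_ok and sample_names and variants:
        n_hap = len(variants[0].panel_column)
        panel = HaplotypePanel(n_haplotypes=n_hap, sample_names=sample_names)
    else:
        for v in variants:
            v.panel_column = None
    if stats.n_rejected:
        log.warning("%d of %d split records rejected", stats.n_rejected,
                    stats.n_rejected + stats.n_accepted)
    return variants, panel, stats


def _rewrite_body_line(line: str, alt_index: int, n_alts: int) -> str:
    """Re-emit a multi-allelic VCF body line as a single-ALT record.

    Only the ALT column, the AF INFO entry, and GT allele indexes are
    rewritten; other INFO keys are copied through unchanged.
    """
    cols = line.rstrip("\n").split("\t")
    alts = cols[4].split(",")
    cols[4] = alts[alt_index]
    if len(cols) > 7 and cols[7] not in (".", ""):
        entries = []
        for entry in cols[7].split(";"):
            if entry.startswith("AF="):
                values = entry[3:].split(",")
                if alt_index < len(values):
                    entry = "AF=" + values[alt_index]
            entries.append(entry)
        cols[7] = ";".join(entries)
    if len(cols) > 9:
        for i in range(9, len(cols)):
            sub = cols[i].split(":")
            gt = sub[0]
            out = []
            for ch in gt:
                if ch in "|/":
                    out.append(ch)
                elif ch == ".":
                    out.append(ch)
                else:
                    out.append("1" if ch == str(alt_index + 1) else "0")
            sub[0] = "".join(out)
            cols[i] = ":".join(sub)
    return "\t".join(cols) + "\n"


def write_selected_vcf(
    selected: Iterable[VariantRecord],
    source: str | Path,
    out: str | Path,
) -> None:
    """Write the selected subset of a source VCF, preserving original text.

    Records keep their source order.  A multi-allelic source record is
    re-emitted verbatim only when *all* of its ALTs were selected; otherwise
    one single-ALT line is written per selected ALT.  Selecting every record
    therefore reproduces the source record set byte-for-byte.
    """
    by_ordinal: dict[int, set[int]] = {}
    for v in selected:
        if v.source_record < 0:
            raise GenomeIOError(f"variant {v.vid} has no source-record provenance")
        by_ordinal.setdefault(v.source_record, set()).add(v.alt_index)

    with open(source) as fh:
        lines = fh.readlines()
    header = [ln for ln in lines if ln.startswith("#")]
    body = [ln for ln in lines if not ln.startswith("#") and ln.strip()]
    if by_ordinal and max(by_ordinal) >= len(body):
        raise GenomeIOError("selection refers to a record absent from the source VCF")

    with open(out, "w") as fh:
        fh.writelines(header)
        for ordinal, line in enumerate(body):
            chosen = by_ordinal.get(ordinal)
            if not chosen:
                continue
            n_alts = len(line.split("\t")[4].split(","))
            if len(chosen) == n_alts:
                fh.write(line if line.endswith("\n") else line + "\n")
            else:
                for alt_index in sorted(chosen):
                    fh.write(_rewrite_body_line(line, alt_index, n_alts))


def write_scores(
    variants: Sequence[VariantRecord],
    scores: Mapping[int, float],
    out: str | Path,
) -> None:
    """Write a per-variant score table as TSV.

    Columns: chrom, pos (1-based), ref, alt, alt_freq, score; one row per
    scored variant in catalog (chromosome, position, alt) order.  NaN scores
    are fatal.
    """
    by_id = {v.vid: v for v in variants}
    rows = []
    for vid, score in scores.items():
        if vid not in by_id:
            raise GenomeIOError(f"score for unknown variant id {vid}")
        if isinstance(score, float) and math.isnan(score):
            raise GenomeIOError(f"NaN score for variant id {vid}")
        rows.append(by_id[vid])
    rows.sort(key=lambda v: (v.vid,))  # catalog order == (chrom, pos, alt)
    with open(out, "w") as fh:
        fh.write("chrom\tpos\tref\talt\talt_freq\tscore\n")
        for v in rows:
            fh.write(f"{v.chrom}\t{v.pos + 1}\t{v.ref_allele}\t{v.alt_allele}\t"
                     f"{v.alt_freq:.12g}\t{scores[v.vid]:.12g}\n")


def read_scores(path: str | Path) -> dict[tuple[str, int, str, str], tuple[float, float]]:
    """Read a score TSV back; keys are (chrom, 0-based pos, ref, alt)."""
    table: dict[tuple[str, int, str, str], tuple[float, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:6] != ["chrom", "pos", "ref", "alt", "alt_freq", "score"]:
            raise GenomeIOError(f"unrecognized score TSV header in {path}")
        for line in fh:
            chrom, pos, ref_a, alt_a, af, score = line.rstrip("\n").split("\t")
            table[(chrom, int(pos) - 1, ref_a, alt_a)] = (float(af), float(score))
    return table
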