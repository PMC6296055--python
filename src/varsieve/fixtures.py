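"""Seeded synthetic fixtures: reference genomes, phased panels, VCFs.

Emulates the structure of a population variant catalog over a reference
genome — tunable repeat content (copy-pasted blocks creating non-unique
s-mers), a phased haplotype panel inducing realized allele frequencies
from a configurable spectrum, and tunable variant clustering — so every
other module is testable without downloads.  All generators are pure
functions of the :class:`FixtureSpec` (seed included).

The *realized* panel frequency, not the drawn target frequency, is written
as the VCF AF, so phased and unphased scoring agree on marginals by
construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_io import HaplotypePanel, ReferenceGenome, VariantRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture.

    window is the s-mer length the fixture is designed around: repeat
    blocks are 2·window long and clustered variants land within window nt
    of their predecessor.
    """

    seed: int = 1
    genome_length: int = 10_000
    n_chromosomes: int = 1
    repeat_fraction: float = 0.2
    n_variants: int = 200
    n_haplotypes: int = 20
    af_distribution: str = "uniform"  # uniform | beta | spiked
    af_params: tuple[float, float] = (1.0, 3.0)
    cluster_rate: float = 0.1
    indel_fraction: float = 0.0
    window: int = 25

    def __post_init__(self) -> None:
        if self.genome_length < 10 * self.window:
            raise ValueError("genome_length must be >= 10 * window")
        if self.n_variants >= self.genome_length:
            raise ValueError("n_variants must be < genome_length")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even and >= 2")
        if self.af_distribution not in ("uniform", "beta", "spiked"):
            raise ValueError(f"unknown af_distribution {self.af_distribution!r}")


def generate_reference(spec: FixtureSpec) -> ReferenceGenome:
    """I.i.d. uniform bases, then repeat blocks copy-pasted from upstream.

    A fraction ``repeat_fraction`` of each chromosome is overwritten by
    copies of earlier blocks of length 2·window, planting non-unique
    s-mers.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    per_chrom = spec.genome_length // spec.n_chromosomes
    chroms: dict[str, str] = {}
    for c in range(spec.n_chromosomes):
        length = per_chrom if c < spec.n_chromosomes - 1 else \
            spec.genome_length - per_chrom * (spec.n_chromosomes - 1)
        arr = _BASES[rng.integers(0, 4, size=length)]
        block = 2 * spec.window
        target = int(spec.repeat_fraction * length)
        planted = 0
        while planted < target and length >= 2 * block:
            dst = int(rng.integers(block, length - block + 1))
            src = int(rng.integers(0, dst - block + 1))
            arr[dst:dst + block] = arr[src:src + block]
            planted += block
        chroms[f"chr{c + 1}"] = arr.tobytes().decode()
    return ReferenceGenome(chroms)


def _draw_target_af(rng: np.random.Generator, spec: FixtureSpec) -> float:
    if spec.af_distribution == "uniform":
        return float(rng.random())
    if spec.af_distribution == "beta":
        a, b = spec.af_params
        return float(rng.beta(a, b))
    # spiked: mostly rare alleles plus a spike of common ones
    if rng.random() < 0.8:
        return float(rng.beta(0.3, 3.0))
    return float(0.5 + 0.5 * rng.random())


def generate_panel(
    spec: FixtureSpec,
    ref: ReferenceGenome,
    out_vcf: Optional[str | Path] = None,
) -> tuple[list[VariantRecord], HaplotypePanel, Optional[Path]]:
    """Place variants, draw a phased panel, and optionally write the VCF.

    Positions follow the clustering process (with probability
    ``cluster_rate`` a variant lands within ``window`` nt of the previous
    one); position collisions are re-drawn.  Each haplotype carries the ALT
    independently with the drawn target probability; the realized panel
    fraction becomes the recorded allele frequency and the VCF AF.  Phased
    genotypes pair haplotypes (2i, 2i+1).
    """
    rng = np.random.default_rng(spec.seed + 1)
    names = ref.names
    lengths = np.array([len(ref.chromosomes[c]) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    H = spec.n_haplotypes

    used: dict[str, set[int]] = {c: set() for c in names}
    placed: list[tuple[str, int, bool]] = []
    prev: Optional[tuple[str, int]] = None
    attempts = 0
    while len(placed) < spec.n_variants:
        attempts += 1
        if attempts > 50 * spec.n_variants:
            raise RuntimeError("fixture placement failed; catalog too dense")
        is_indel = bool(rng.random() < spec.indel_fraction)
        span = 4 if is_indel else 1  # reserve room for short indels
        if prev is not None and rng.random() < spec.cluster_rate:
            chrom, p = prev
            pos = p + int(rng.integers(1, spec.window))
        else:
            chrom = names[int(rng.choice(len(names), p=weights))]
            pos = int(rng.integers(0, len(ref.chromosomes[chrom]) - span))
        if pos + span > len(ref.chromosomes[chrom]) or pos < 0:
            continue
        if any(pos + o in used[chrom] for o in range(span)):
            continue
        for o in range(span):
            used[chrom].add(pos + o)
        placed.append((chrom, pos, is_indel))
        prev = (chrom, pos)

    order = {c: i for i, c in enumerate(names)}
    placed.sort(key=lambda t: (order[t[0]], t[1]))

    variants: list[VariantRecord] = []
    for vid, (chrom, pos, is_indel) in enumerate(placed):
        seq = ref.chromosomes[chrom]
        ref_base = seq[pos]
        if not is_indel:
            alt = "ACGT"[int(rng.integers(0, 4))]
            while alt == ref_base:
                alt = "ACGT"[int(rng.integers(0, 4))]
            ref_allele, alt_allele = ref_base, alt
        elif rng.random() < 0.5:  # insertion
            ins_len = int(rng.integers(1, 4))
            ins = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=ins_len))
            ref_allele, alt_allele = ref_base, ref_base + ins
        else:  # deletion
            del_len = int(rng.integers(1, 4))
            ref_allele, alt_allele = seq[pos:pos + 1 + del_len], ref_base
        target = _draw_target_af(rng, spec)
        column = (rng.random(H) < target).astype(np.uint8)
        variants.append(VariantRecord(
            chrom=chrom, pos=pos, ref_allele=ref_allele, alt_allele=alt_allele,
            alt_freq=float(column.mean()), vid=vid, panel_column=column,
            source_record=vid, alt_index=0))

    panel = HaplotypePanel(n_haplotypes=H,
                           sample_names=[f"s{i}" for i in range(H // 2)])
    path: Optional[Path] = None
    if out_vcf is not None:
        path = Path(out_vcf)
        write_fixture_vcf(variants, panel, ref, path)
    return variants, panel, path


def write_fixture_vcf(variants: list[VariantRecord], panel: HaplotypePanel,
                      ref: ReferenceGenome, path: str | Path) -> None:
    """Write the fixture catalog as a VCF 4.2 with AF INFO and phased GTs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in ref.chromosomes.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Allele Frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_names) + "\n")
        for v in variants:
            col = v.panel_column
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}"
                            for i in range(panel.n_haplotypes // 2))
            fh.write(f"{v.chrom}\t{v.pos + 1}\tv{v.vid}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\tPASS\tAF={v.alt_freq!r}\tGT\t{gts}\n")


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate and write a full bundle: FASTA + VCF + JSON spec sidecar.

    Filenames carry the seed for reproducibility.  Returns the in-memory
    objects and the paths.
    """
    from .genome_io import write_reference

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(spec)
    fasta = out / f"ref_seed{spec.seed}.fa"
    write_reference(ref, fasta)
    vcf = out / f"variants_seed{spec.seed}.vcf"
    variants, panel, _ = generate_panel(spec, ref, out_vcf=vcf)
    sidecar = out / f"spec_seed{spec.seed}.json"
    sidecar.write_text(json.dumps(dataclasses.asdict(spec), indent=2) + "\n")
    return {"ref": ref, "variants": variants, "panel": panel,
            "fasta": fasta, "vcf": vcf, "spec_json": sidecar}


# -- worked examples ---------------------------------------------------------

#: The GATYACA toy: reference GATTACA with a T→C substitution at 0-based
#: position 3, so the 3-mers at offset 2 are TTA (REF) and TCA (ALT).
GATTACA_SEQ = "GATTACA"
GATTACA_SNV = ("toy", 3, "T", "C", 0.5)

#: A length-10 genome whose 4-mers are all distinct, with a C→T SNV of
#: frequency 0.3 at 0-based position 5 whose ALT 4-mers are also unique
#: and absent from the reference — the isolated-unique-s-mer worked case.
DECA_SEQ = "ACGTACGGTC"
DECA_SNV = ("deca", 5, "C", "T", 0.3)


def worked_example_fixture(out_dir: str | Path) -> dict:
    """Write the two worked-example bundles as FASTA + VCF files.

    Returns paths plus the parsed objects.  Both bundles have H=0 (no
    genotype columns); frequencies come from the AF INFO field.
    """
    from .genome_io import read_reference, read_variants

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles = {}
    for name, seq, (chrom, pos, ref_a, alt_a, af) in (
            ("gattaca", GATTACA_SEQ, GATTACA_SNV),
            ("deca", DECA_SEQ, DECA_SNV)):
        fasta = out / f"{name}.fa"
        fasta.write_text(f">{chrom}\n{seq}\n")
        vcf = out / f"{name}.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID={chrom},length={len(seq)}>\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"{chrom}\t{pos + 1}\t{name}_snv\t{ref_a}\t{alt_a}\t.\tPASS\tAF={af}\n")
        ref = read_reference(fasta)
        variants, panel, stats = read_variants(vcf, ref)
        assert stats.n_rejected == 0
        bundles[name] = {"fasta": fasta, "vcf": vcf, "ref": ref,
                         "variants": variants}
    return bundles
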