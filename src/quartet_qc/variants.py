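"""Variant containers and VCF/BED I/O for the quartet family design.

The quartet comprises four related donors — father F7, mother M8 and
monozygotic twin daughters D5 and D6 — whose built-in genetic truth
(twin identity, Mendelian inheritance) supports reference-free accuracy
checks on small-variant call sets.

Conventions, stated bit-exactly:

* VCF positions are 1-based; BED intervals are 0-based half-open.
* Multi-allelic rows are split into biallelic records on read; no
  left-alignment or decomposition is performed (matching downstream is
  exact-key, and the bundled simulator emits normalized records).
* Only autosomes are retained: sex-chromosome Mendelian logic (father
  hemizygous) is out of scope.
* Genotypes are unphased diploid allele pairs in {0/0, 0/1, 1/1} or
  missing (``None``, serialized as ``./.``); missing is preserved, never
  imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DONORS",
    "Genotype",
    "VariantRecord",
    "QuartetVariantSet",
    "BenchmarkSet",
    "read_quartet_vcf",
    "write_quartet_vcf",
    "read_bed_regions",
    "merge_intervals",
]

#: Canonical donor order used throughout the package.
DONORS: tuple[str, str, str, str] = ("D5", "D6", "F7", "M8")

#: Unphased diploid genotype as a sorted allele pair, or ``None`` for ./.
Genotype = Optional[tuple[int, int]]

_SEX_AND_MITO = {"X", "Y", "M", "MT"}


def _is_autosome(chrom: str) -> bool:
    return chrom.removeprefix("chr") not in _SEX_AND_MITO


def _chrom_key(chrom: str) -> tuple[int, int, str]:
    name = chrom.removeprefix("chr")
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def format_genotype(gt: Genotype) -> str:
    if gt is None:
        return "./."
    return f"{gt[0]}/{gt[1]}"


def parse_genotype(text: str) -> Genotype:
    alleles = text.replace("|", "/").split("/")
    if len(alleles) != 2 or "." in alleles:
        return None
    a, b = sorted(int(x) for x in alleles)
    return (a, b)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant with one genotype per quartet donor."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: Mapping[str, Genotype]

    def __post_init__(self) -> None:
        missing = [d for d in DONORS if d not in self.genotypes]
        if missing:
            raise ValueError(f"record {self.key} lacks genotypes for {missing}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "Indel"

    def genotype(self, donor: str) -> Genotype:
        return self.genotypes[donor]

    def is_called(self, donor: str) -> bool:
        """True iff the donor genotype is non-missing and non-reference."""
        gt = self.genotypes[donor]
        return gt is not None and gt != (0, 0)


@dataclass
class QuartetVariantSet:
    """Sorted, key-unique collection of quartet variant records."""

    records: list[VariantRecord]
    donor_order: tuple[str, ...] = DONORS
    source_label: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records, key=lambda r: (_chrom_key(r.chrom), r.pos, r.ref, r.alt)
        )
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate variant key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_key(self) -> dict[tuple, VariantRecord]:
        return {rec.key: rec for rec in self.records}

    def subset(self, vtype: str) -> list[VariantRecord]:
        return [r for r in self.records if r.vtype == vtype]


Interval = tuple[str, int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent 0-based half-open intervals."""
    ordered = sorted(intervals, key=lambda iv: (_chrom_key(iv[0]), iv[1], iv[2]))
    merged: list[Interval] = []
    for chrom, start, end in ordered:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


@dataclass
class BenchmarkSet:
    """Truth variants plus the confident regions inside which they are complete."""

    truth: QuartetVariantSet
    regions: list[Interval]

    def __post_init__(self) -> None:
        self.regions = merge_intervals(self.regions)
        for rec in self.truth:
            if not self.contains(rec.chrom, rec.pos):
                raise ValueError(
                    f"truth variant {rec.key} lies outside all benchmark regions"
                )

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position in the 0-based half-open regions."""
        zero_based = pos - 1
        for c, start, end in self.regions:
            if c == chrom and start <= zero_based < end:
                return True
        return False


def read_bed_regions(path: str | Path) -> list[Interval]:
    """Read a BED3+ file into merged, sorted 0-based half-open intervals."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    return merge_intervals(intervals)


def read_quartet_vcf(
    path: str | Path,
    sample_map: Mapping[str, str] | None = None,
    keep_filtered: bool = False,
) -> QuartetVariantSet:
    """Read a multi-sample VCF into a :class:`QuartetVariantSet`.

    Parameters
    ----------
    path:
        VCF 4.x file (plain or bgzipped) carrying at least the four quartet
        samples.
    sample_map:
        Maps donor names (D5, D6, F7, M8) to VCF sample names; defaults to
        the identity mapping.
    keep_filtered:
        When False (default), rows whose FILTER is neither PASS nor missing
        are dropped.

    Multi-allelic rows are split into one record per alternate allele, with
    genotypes recoded per allele (the focal allele becomes 1, every other
    allele 0).  Rows on sex chromosomes or the mitochondrion are excluded.
    """
    from cyvcf2 import VCF

    sample_map = dict(sample_map or {d: d for d in DONORS})
    for donor in DONORS:
        if donor not in sample_map:
            raise KeyError(f"sample_map lacks an entry for donor {donor}")

    vcf = VCF(str(path))
    try:
        col_of = {}
        for donor in DONORS:
            name = sample_map[donor]
            if name not in vcf.samples:
                raise KeyError(f"sample {name!r} (donor {donor}) absent from {path}")
            col_of[donor] = vcf.samples.index(name)

        records: list[VariantRecord] = []
        for var in vcf:
            if not _is_autosome(var.CHROM):
                continue
            if not keep_filtered and var.FILTER is not None:
                continue  # cyvcf2 maps PASS and '.' to None
            gts = var.genotypes  # [[a, b, phased], ...]
            for alt_index, alt in enumerate(var.ALT, start=1):
                if alt in {"*", "."} or alt.startswith("<"):
                    continue
                genotypes: dict[str, Genotype] = {}
                for donor, col in col_of.items():
                    raw = gts[col]
                    alleles = raw[:-1]
                    if len(alleles) != 2 or any(a < 0 for a in alleles):
                        genotypes[donor] = None
                    else:
                        coded = tuple(sorted(1 if a == alt_index else 0 for a in alleles))
                        genotypes[donor] = coded  # type: ignore[assignment]
                records.append(
                    VariantRecord(var.CHROM, var.POS, var.REF, alt, genotypes)
                )
    finally:
        vcf.close()

    return QuartetVariantSet(records=records, source_label=str(path))


def write_quartet_vcf(
    path: str | Path,
    variants: QuartetVariantSet,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal GT-only VCF 4.2 file (deterministic: no timestamp)."""
    contigs: dict[str, int] = dict(contig_lengths or {})
    for rec in variants:
        length = max(contigs.get(rec.chrom, 0), rec.pos + len(rec.ref) + 1000)
        contigs[rec.chrom] = length

    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source={variants.source_label or 'quartet-qc'}\n")
        for chrom in sorted(contigs, key=_chrom_key):
            out.write(f"##contig=<ID={chrom},length={contigs[chrom]}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(variants.donor_order)
            + "\n"
        )
        for rec in variants:
            gt_cols = "\t".join(
                format_genotype(rec.genotypes[d]) for d in variants.donor_order
            )
            out.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gt_cols}\n"
            )


def write_bed_regions(path: str | Path, regions: Sequence[Interval]) -> None:
    with open(path, "w") as out:
        for chrom, start, end in merge_intervals(regions):
            out.write(f"{chrom}\t{start}\t{end}\n")
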