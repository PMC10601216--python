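"""Pedigree-aware genomics QC: benchmark precision/recall, Mendelian
concordance over the twin quartet, and the genomics total score.

The total score is the arithmetic mean of three combined components —
precision, recall and Mendelian concordance rate (MCR) — where each
component is an F0.5 combination of its SNV and Indel values.  MCR counts
variants whose genotypes are shared by the monozygotic twins (D5, D6) and
compatible with one-allele-per-parent transmission from F7 and M8, divided
by the evaluable variants called in the quartet.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Mapping, Sequence

from .variants import DONORS, BenchmarkSet, Genotype, QuartetVariantSet, VariantRecord

__all__ = [
    "MendelStatus",
    "ComparisonCounts",
    "MendelianCounts",
    "GenomicsScoreCard",
    "check_mendelian",
    "compute_mcr",
    "compare_to_benchmark",
    "f_beta_combine",
    "genomics_total_score",
    "evaluate_genomics",
]

VTYPES = ("SNV", "Indel")


class MendelStatus(enum.Enum):
    CONCORDANT = "concordant"
    TWIN_DISCORDANT = "twin_discordant"
    TRIO_VIOLATION = "trio_violation"
    UNEVALUABLE = "unevaluable"


def check_mendelian(record: VariantRecord) -> MendelStatus:
    """Classify a biallelic autosomal site against the quartet pedigree.

    Order of precedence: any missing genotype makes the site UNEVALUABLE;
    twins disagreeing is TWIN_DISCORDANT regardless of the parents; a twin
    genotype that cannot be assembled from one paternal and one maternal
    allele is a TRIO_VIOLATION; everything else is CONCORDANT.
    """
    gts = {d: record.genotypes[d] for d in DONORS}
    if any(gt is None for gt in gts.values()):
        return MendelStatus.UNEVALUABLE
    if gts["D5"] != gts["D6"]:
        return MendelStatus.TWIN_DISCORDANT
    child = gts["D5"]
    father, mother = gts["F7"], gts["M8"]
    possible = {
        tuple(sorted((fa, ma))) for fa in father for ma in mother  # type: ignore[union-attr]
    }
    if child in possible:
        return MendelStatus.CONCORDANT
    return MendelStatus.TRIO_VIOLATION


@dataclass
class MendelianCounts:
    """Per-variant-type tallies of Mendelian-evaluable quartet sites."""

    n_total: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VTYPES})
    n_concordant: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VTYPES})
    excluded_missing: int = 0

    def mcr(self, vtype: str) -> float | None:
        total = self.n_total[vtype]
        if total == 0:
            return None
        return self.n_concordant[vtype] / total


def compute_mcr(calls: QuartetVariantSet) -> MendelianCounts:
    """Tally Mendelian concordance over all called quartet sites.

    A site enters the denominator iff at least one donor genotype is
    non-reference and none is missing; sites with any missing genotype are
    excluded entirely (counted in ``excluded_missing``).  Twin-discordant
    and trio-violating sites stay in the denominator.
    """
    if len(calls) == 0:
        raise ValueError("cannot compute MCR on an empty variant set")
    counts = MendelianCounts()
    for rec in calls:
        status = check_mendelian(rec)
        if status is MendelStatus.UNEVALUABLE:
            counts.excluded_missing += 1
            continue
        if not any(rec.is_called(d) for d in DONORS):
            continue  # all-reference site: not a called variant
        counts.n_total[rec.vtype] += 1
        if status is MendelStatus.CONCORDANT:
            counts.n_concordant[rec.vtype] += 1
    return counts


@dataclass
class ComparisonCounts:
    """True/false positive and false negative tallies per variant type."""

    tp: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VTYPES})
    fp: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VTYPES})
    fn: dict[str, int] = field(default_factory=lambda: {v: 0 for v in VTYPES})

    def precision(self, vtype: str) -> float | None:
        called = self.tp[vtype] + self.fp[vtype]
        return None if called == 0 else self.tp[vtype] / called

    def recall(self, vtype: str) -> float | None:
        truth = self.tp[vtype] + self.fn[vtype]
        return None if truth == 0 else self.tp[vtype] / truth


def compare_to_benchmark(
    calls: QuartetVariantSet,
    benchmark: BenchmarkSet,
    donor: str,
    genotype_match: bool = False,
) -> ComparisonCounts:
    """Count TP/FP/FN for one donor against the benchmark inside its regions.

    A donor "call" is a record whose donor genotype is non-missing and
    non-reference and whose position falls inside a benchmark region.  By
    default a call is a true positive iff a truth record with identical
    (chrom, pos, ref, alt) exists and the truth donor genotype is
    non-reference (allele-presence matching); ``genotype_match=True``
    additionally requires the exact genotype to agree.  Unmatched in-region
    truth records with a non-reference donor genotype are false negatives.
    """
    if donor not in DONORS:
        raise KeyError(f"unknown donor {donor!r}")
    if not benchmark.regions:
        raise ValueError("benchmark region set is empty: precision undefined")

    truth_index = benchmark.truth.by_key()
    counts = ComparisonCounts()
    matched_truth: set[tuple] = set()

    for rec in calls:
        if not rec.is_called(donor):
            continue
        if not benchmark.contains(rec.chrom, rec.pos):
            continue
        truth_rec = truth_index.get(rec.key)
        is_tp = (
            truth_rec is not None
            and truth_rec.is_called(donor)
            and (not genotype_match or truth_rec.genotype(donor) == rec.genotype(donor))
        )
        if is_tp:
            counts.tp[rec.vtype] += 1
            matched_truth.add(rec.key)
        else:
            counts.fp[rec.vtype] += 1

    for truth_rec in benchmark.truth:
        if truth_rec.is_called(donor) and truth_rec.key not in matched_truth:
            counts.fn[truth_rec.vtype] += 1
    return counts


def f_beta_combine(
    snv_score: float | None, indel_score: float | None, beta: float = 0.5
) -> float | None:
    """F-beta combination of the SNV and Indel values of one component.

    F_beta = (1 + beta^2) * s_SNV * s_Indel / (beta^2 * s_SNV + s_Indel);
    with beta = 0.5 the SNV slot (first operand) is weighted more heavily.
    If exactly one operand is undefined the other is returned verbatim with
    a warning; both undefined returns None; both zero returns 0.0 (limit
    convention).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if snv_score is None and indel_score is None:
        return None
    if snv_score is None or indel_score is None:
        present = snv_score if snv_score is not None else indel_score
        warnings.warn(
            "one variant-type score undefined; returning the other verbatim",
            stacklevel=2,
        )
        return present
    b2 = beta * beta
    denom = b2 * snv_score + indel_score
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * snv_score * indel_score / denom


@dataclass
class GenomicsScoreCard:
    """Per-type and combined genomics QC components plus the total score."""

    precision: dict[str, float | None]
    recall: dict[str, float | None]
    mcr: dict[str, float | None]
    combined_precision: float | None
    combined_recall: float | None
    combined_mcr: float | None
    total_score: float
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "mcr": dict(self.mcr),
            "combined_precision": self.combined_precision,
            "combined_recall": self.combined_recall,
            "combined_mcr": self.combined_mcr,
            "total_score": self.total_score,
        }


def genomics_total_score(
    precision: Mapping[str, float | None],
    recall: Mapping[str, float | None],
    mcr: Mapping[str, float | None],
    beta: float = 0.5,
) -> GenomicsScoreCard:
    """Combine per-variant-type components into the genomics total score.

    Each of precision, recall and MCR is F0.5-combined across SNV/Indel;
    the total is the arithmetic mean of the defined combined components
    (undefined ones are dropped with a warning).
    """
    notes: list[str] = []
    combined: dict[str, float | None] = {}
    for name, comp in (("precision", precision), ("recall", recall), ("mcr", mcr)):
        snv, indel = comp.get("SNV"), comp.get("Indel")
        if snv is None or indel is None:
            missing = [v for v in VTYPES if comp.get(v) is None]
            notes.append(f"{name}: undefined for {missing}; dropped from F-combination")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            combined[name] = f_beta_combine(snv, indel, beta=beta)

    defined = [v for v in combined.values() if v is not None]
    if not defined:
        raise ValueError("all genomics components undefined; no score possible")
    if len(defined) < 3:
        notes.append("total score averages only the defined combined components")
    return GenomicsScoreCard(
        precision=dict(precision),
        recall=dict(recall),
        mcr=dict(mcr),
        combined_precision=combined["precision"],
        combined_recall=combined["recall"],
        combined_mcr=combined["mcr"],
        total_score=mean(defined),
        warnings=notes,
    )


def _average(values: Iterable[float]) -> float | None:
    vals = list(values)
    return mean(vals) if vals else None


def evaluate_genomics(
    calls: QuartetVariantSet,
    benchmark: BenchmarkSet,
    donors: Sequence[str] = DONORS,
    genotype_match: bool = False,
    beta: float = 0.5,
) -> GenomicsScoreCard:
    """Full genomics QC pipeline: per-donor benchmark comparison (averaged
    arithmetically across donors), quartet MCR, and the combined total."""
    per_donor = {
        d: compare_to_benchmark(calls, benchmark, d, genotype_match=genotype_match)
        for d in donors
    }
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for vtype in VTYPES:
        precision[vtype] = _average(
            p for c in per_donor.values() if (p := c.precision(vtype)) is not None
        )
        recall[vtype] = _average(
            r for c in per_donor.values() if (r := c.recall(vtype)) is not None
        )
    mendel = compute_mcr(calls)
    mcr = {vtype: mendel.mcr(vtype) for vtype in VTYPES}
    card = genomics_total_score(precision, recall, mcr, beta=beta)
    if mendel.excluded_missing:
        card.warnings.append(
            f"{mendel.excluded_missing} sites excluded from MCR for missing genotypes"
        )
    return card
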