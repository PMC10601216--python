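"""Synthetic quartet batches with controllable quality defects.

Two generators close the testing loop for every QC metric without any
external data:

* :func:`simulate_quartet_variants` draws pedigree-consistent quartet
  genotypes on a synthetic autosomal contig (``chrS1``) and derives a test
  call set by deleting truth records (false negatives), injecting novel
  records (false positives, half of them pedigree-inconsistent so that
  precision and Mendelian concordance are separately exercisable) and
  perturbing genotypes (resampled from the site allele frequency).
* :func:`simulate_profile` builds a 4-donor x n-replicate abundance
  matrix from per-donor means (baseline + donor effects + planted
  differential features), Gaussian technical noise on log2 scale, an
  optional batch shift and missing-at-random cells, together with the
  matched reference ratio table and differential-abundance flags.

All randomness flows from the config seed; identical configs give
bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .profiles import PAIRS, QuantProfile, ReferenceRatioSet
from .variants import (
    DONORS,
    BenchmarkSet,
    Genotype,
    QuartetVariantSet,
    VariantRecord,
)

__all__ = [
    "QuartetSimConfig",
    "ProfileSimConfig",
    "simulate_quartet_variants",
    "simulate_profile",
]

_CONTIG = "chrS1"
_BASES = np.array(list("ACGT"))

_GT_FROM_COUNT: dict[int, Genotype] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


@dataclass
class QuartetSimConfig:
    """Settings for the pedigree variant simulator.

    Allele frequencies are drawn from Beta(af_alpha, af_beta) rescaled to
    (af_min, af_max); keeping the range away from 0/1 avoids sites where
    the whole quartet is homozygous reference.
    """

    n_variants: int = 1000
    af_alpha: float = 1.5
    af_beta: float = 1.5
    af_min: float = 0.05
    af_max: float = 0.95
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    genotype_error_rate: float = 0.0
    indel_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        for name in ("fp_rate", "fn_rate", "genotype_error_rate", "indel_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fp_rate >= 1.0 or not 0 <= self.af_min < self.af_max <= 1:
            raise ValueError("invalid rate or allele-frequency bounds")


def _draw_alleles(chars: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    return chars[rng.integers(0, len(chars), size=n)]


def _make_alleles(
    rng: np.random.Generator, n: int, indel_fraction: float
) -> tuple[list[str], list[str]]:
    refs: list[str] = []
    alts: list[str] = []
    is_indel = rng.random(n) < indel_fraction
    for flag in is_indel:
        base = str(_BASES[rng.integers(0, 4)])
        if not flag:
            alt = str(_BASES[rng.integers(0, 4)])
            while alt == base:
                alt = str(_BASES[rng.integers(0, 4)])
            refs.append(base)
            alts.append(alt)
        else:
            tail = "".join(_BASES[rng.integers(0, 4, size=int(rng.integers(1, 4)))])
            if rng.random() < 0.5:  # deletion
                refs.append(base + tail)
                alts.append(base)
            else:  # insertion
                refs.append(base)
                alts.append(base + tail)
    return refs, alts


def _transmit(parent: Genotype, rng: np.random.Generator) -> int:
    return parent[rng.integers(0, 2)]  # type: ignore[index]


def _sample_quartet(af: float, rng: np.random.Generator) -> dict[str, Genotype]:
    """Draw a pedigree-consistent quartet genotype at allele frequency af."""
    father = tuple(sorted(rng.binomial(1, af, size=2)))
    mother = tuple(sorted(rng.binomial(1, af, size=2)))
    child = tuple(sorted((_transmit(father, rng), _transmit(mother, rng))))
    return {"D5": child, "D6": child, "F7": father, "M8": mother}


def _resample_genotype(af: float, rng: np.random.Generator) -> Genotype:
    return tuple(sorted(rng.binomial(1, af, size=2)))  # type: ignore[return-value]


def simulate_quartet_variants(
    cfg: QuartetSimConfig,
) -> tuple[BenchmarkSet, QuartetVariantSet]:
    """Simulate a truth benchmark and a degraded test call set.

    Truth: ``n_variants`` biallelic autosomal records on ``chrS1`` with at
    least one non-reference donor, twins identical by construction
    (monozygosity) and children formed by one sampled transmission per
    parent.  Test set: truth minus records deleted at ``fn_rate``, with
    each retained genotype resampled from the site allele frequency at
    ``genotype_error_rate``, plus novel records at unused positions whose
    count targets a false-call fraction of ``fp_rate`` (half of them made
    pedigree-inconsistent by perturbing one twin).  Benchmark regions are
    a single interval spanning every simulated position.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_variants
    span = max(50 * n, 1000)

    # Truth sites: oversample, keep sites with at least one carrier.
    n_pool = int(n * 1.5) + 20
    positions = np.sort(rng.choice(np.arange(1, span + 1), size=min(2 * n_pool, span), replace=False))
    afs = cfg.af_min + (cfg.af_max - cfg.af_min) * rng.beta(
        cfg.af_alpha, cfg.af_beta, size=positions.size
    )

    truth_records: list[VariantRecord] = []
    truth_af: dict[int, float] = {}
    spare_positions: list[int] = []
    refs_pool, alts_pool = _make_alleles(rng, positions.size, cfg.indel_fraction)
    for pos, af, ref, alt in zip(positions, afs, refs_pool, alts_pool):
        if len(truth_records) >= n:
            spare_positions.append(int(pos))
            continue
        gts = _sample_quartet(float(af), rng)
        if not any(g != (0, 0) for g in gts.values()):
            spare_positions.append(int(pos))
            continue
        truth_records.append(VariantRecord(_CONTIG, int(pos), ref, alt, gts))
        truth_af[int(pos)] = float(af)
    if len(truth_records) < n:
        raise RuntimeError(
            "simulation could not place the requested number of variants; "
            "increase af_min or the allele-frequency bounds"
        )

    truth = QuartetVariantSet(records=list(truth_records), source_label="sim-truth")
    regions = [(_CONTIG, 0, span + 1)]
    benchmark = BenchmarkSet(truth=truth, regions=regions)

    # --- degrade into the test set -------------------------------------
    test_records: list[VariantRecord] = []
    kept = rng.random(n) >= cfg.fn_rate
    for rec, keep in zip(truth_records, kept):
        if not keep:
            continue
        gts = dict(rec.genotypes)
        af = truth_af[rec.pos]
        for donor in DONORS:
            if rng.random() < cfg.genotype_error_rate:
                gts[donor] = _resample_genotype(af, rng)
        test_records.append(VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, gts))

    # False positives: novel records at unused positions.  Their count is
    # chosen so that the expected fraction of false calls is fp_rate.
    n_retained = len(test_records)
    if cfg.fp_rate > 0.0 and n_retained > 0:
        n_fp = int(rng.binomial(n_retained, cfg.fp_rate / (1.0 - cfg.fp_rate)))
        if n_fp > len(spare_positions):
            raise RuntimeError("not enough spare positions for false positives")
        fp_positions = rng.choice(len(spare_positions), size=n_fp, replace=False)
        fp_refs, fp_alts = _make_alleles(rng, n_fp, cfg.indel_fraction)
        for idx, ref, alt in zip(fp_positions, fp_refs, fp_alts):
            pos = spare_positions[int(idx)]
            af = float(
                cfg.af_min + (cfg.af_max - cfg.af_min) * rng.beta(cfg.af_alpha, cfg.af_beta)
            )
            gts = _sample_quartet(af, rng)
            while not any(g != (0, 0) for g in gts.values()):
                gts = _sample_quartet(af, rng)
            if rng.random() < 0.5:
                # Break the pedigree: perturb one twin so the pair disagrees.
                current = gts["D5"]
                options = [g for g in _GT_FROM_COUNT.values() if g != current]
                gts["D5"] = options[int(rng.integers(0, len(options)))]
            test_records.append(VariantRecord(_CONTIG, pos, ref, alt, gts))

    if not test_records:
        raise ValueError("error rates produced an empty test set")
    test = QuartetVariantSet(records=test_records, source_label="sim-test")
    return benchmark, test


@dataclass
class ProfileSimConfig:
    """Settings for the quantitative profile simulator.

    Defaults mirror the quartet batch design: four donors, three technical
    replicates each.  Values are simulated on log2 scale; donor effects
    give the between-donor "signal", ``noise_sd`` the within-donor
    technical scatter.  A ``dam_fraction`` of the features carries a
    planted log2 fold change of ``dam_log2fc`` (random sign) for each
    donor pair, and those features are flagged in the returned reference.
    """

    n_features: int = 1000
    replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    donor_effect_sd: float = 0.5
    noise_sd: float = 0.2
    missing_rate: float = 0.0
    dam_fraction: float = 0.1
    dam_log2fc: float = 2.0
    batch_shift: float = 0.0
    batch_id: str = "sim-batch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per donor are required")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for name in ("missing_rate", "dam_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def simulate_profile(
    cfg: ProfileSimConfig,
) -> tuple[QuantProfile, ReferenceRatioSet]:
    """Simulate a log2-scale quartet profile plus its matched reference.

    The reference ratios are the *true* donor-mean differences to D6, so a
    noiseless, complete profile reproduces them exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n, reps = cfg.n_features, cfg.replicates
    features = [f"FEAT{i:05d}" for i in range(n)]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    effects = {d: rng.normal(0.0, cfg.donor_effect_sd, size=n) for d in DONORS}

    # Planted differential features per non-D6 donor: the donor effect is
    # pinned so the true ratio to D6 is exactly +/- dam_log2fc.
    n_dam = int(round(cfg.dam_fraction * n))
    dam_flags = pd.DataFrame(False, index=features, columns=list(PAIRS))
    for pair in PAIRS:
        donor = pair.split("/")[0]
        idx = rng.choice(n, size=n_dam, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_dam)
        effects[donor][idx] = effects["D6"][idx] + signs * cfg.dam_log2fc
        dam_flags.iloc[idx, dam_flags.columns.get_loc(pair)] = True

    donor_means = {d: baseline + effects[d] for d in DONORS}
    ratios = pd.DataFrame(
        {pair: donor_means[pair.split("/")[0]] - donor_means["D6"] for pair in PAIRS},
        index=features,
    )
    reference = ReferenceRatioSet(ratios=ratios, dam_flags=dam_flags)

    columns = [f"{d}_{r}" for d in DONORS for r in range(1, reps + 1)]
    data = np.empty((n, len(columns)))
    for j, col in enumerate(columns):
        donor = col.split("_")[0]
        noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        data[:, j] = donor_means[donor] + noise + cfg.batch_shift
    if cfg.missing_rate > 0:
        mask = rng.random(data.shape) < cfg.missing_rate
        data[mask] = np.nan

    profile = QuantProfile(
        data=pd.DataFrame(data, index=features, columns=columns),
        batch_id=cfg.batch_id,
        log_scale=True,
    )
    return profile, reference
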