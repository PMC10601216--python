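"""Quantitative-omics QC metrics and omics-specific total scores.

Two batch-level metrics anchor the assessment:

* **SNR** (signal-to-noise ratio, reference-independent): contrasts the
  separation of the four donor groups ("signal") with the scatter of
  technical replicates within a donor ("noise").  Samples are projected
  onto the first two principal components, each axis scaled by its
  explained-variance fraction; signal and noise are mean squared
  Euclidean distances over cross-donor and within-donor sample pairs, and
  SNR = 10*log10(signal/noise) dB, capped at 100 dB when noise underflows.
* **RC** (reference correlation, reference-dependent): Pearson correlation
  between the batch's ratio-to-D6 profile (replicate means on log2 scale)
  and the reference ratio profile, concatenated over the three donor pairs
  and restricted to overlapping features.

Omics-specific totals:

* transcriptomics: scale01(SNR) x clamp(RC, 0, 1), with SNR mapped
  linearly from [0, 100] dB to [0, 1] (the raw dB x r product is also
  reported);
* proteomics: geometric mean of six metrics (feature count, missing
  fraction, replicate correlation, median CV, SNR, RC), each min-max
  scaled against its historical distribution to [0.01, 1] with the two
  loss-type metrics (missing fraction, CV) inverted first;
* metabolomics: geometric mean of DAM recall, scale01(SNR) and
  clamp(RC, 0, 1), components floored at 0.01.  DAM recall is the
  fraction of reference differentially-abundant features rediscovered at
  raw Welch-t p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import PAIRS, QuantProfile, ReferenceRatioSet, donor_of
from .variants import DONORS

__all__ = [
    "QuantMetrics",
    "DamDetection",
    "ScoreResult",
    "compute_snr",
    "compute_ratios",
    "compute_rc",
    "compute_cv",
    "replicate_correlation",
    "missing_fraction",
    "feature_count",
    "detect_dams",
    "dam_recall",
    "scale01_snr",
    "transcriptomics_score",
    "proteomics_score",
    "metabolomics_score",
    "compute_quant_metrics",
    "PROTEOMICS_METRICS",
]

_NOISE_EPS = 1e-12
SNR_CAP_DB = 100.0
_SCORE_FLOOR = 0.01

#: The six proteomics metrics entering the geometric mean; True marks
#: loss-type metrics (lower is better) that are inverted before scaling.
PROTEOMICS_METRICS: dict[str, bool] = {
    "n_features": False,
    "missing_pct": True,
    "replicate_corr": False,
    "cv_median": True,
    "snr": False,
    "rc": False,
}


@dataclass
class QuantMetrics:
    """Batch-level quantitative QC metrics."""

    snr: float
    rc: float
    cv_median: float
    missing_pct: float
    n_features: int
    replicate_corr: float
    dam_recall: float | None = None  # metabolomics only

    def as_dict(self) -> dict:
        return {
            "snr": self.snr,
            "rc": self.rc,
            "cv_median": self.cv_median,
            "missing_pct": self.missing_pct,
            "n_features": self.n_features,
            "replicate_corr": self.replicate_corr,
            "dam_recall": self.dam_recall,
        }


def compute_snr(profile: QuantProfile) -> float:
    """Signal-to-noise ratio of donor separation vs replicate scatter, in dB.

    Requires >=2 donors and at least one donor with >=2 replicates;
    features with any missing value are dropped for this computation.
    """
    donors = [donor_of(c) for c in profile.data.columns]
    if not any(donors.count(d) >= 2 for d in set(donors)):
        raise ValueError("SNR needs at least one donor with >=2 replicates")
    if len(set(donors)) < 2:
        raise ValueError("SNR needs samples from at least two donors")

    log = profile.log2_matrix().dropna(axis=0, how="any")
    if log.shape[0] < 2:
        raise ValueError("fewer than 2 complete features; SNR undefined")

    from sklearn.decomposition import PCA

    X = log.values.T  # samples x features
    if np.allclose(X, X.mean(axis=0, keepdims=True)):
        raise ValueError("signal and noise both vanish; SNR undefined")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    coords = scores * pca.explained_variance_ratio_[np.newaxis, :]

    sq = ((coords[:, np.newaxis, :] - coords[np.newaxis, :, :]) ** 2).sum(axis=2)
    labels = np.array(donors)
    iu, ju = np.triu_indices(len(labels), k=1)
    same = labels[iu] == labels[ju]
    signal = sq[iu, ju][~same].mean()
    noise = sq[iu, ju][same].mean()

    if noise < _NOISE_EPS:
        if signal < _NOISE_EPS:
            raise ValueError("signal and noise both vanish; SNR undefined")
        return SNR_CAP_DB
    return min(10.0 * math.log10(signal / noise), SNR_CAP_DB)


def compute_ratios(profile: QuantProfile) -> pd.DataFrame:
    """Per-feature log2 ratios to D6 from replicate means on log2 scale.

    Donor means are taken over non-missing replicates; features with no D6
    measurement are excluded entirely.  A pair cell is NaN when the non-D6
    donor has no measurement for that feature.
    """
    log = profile.log2_matrix()
    means = {d: log[profile.donor_columns(d)].mean(axis=1) for d in DONORS}
    keep = means["D6"].notna()
    table = pd.DataFrame(
        {pair: means[pair.split("/")[0]] - means["D6"] for pair in PAIRS}
    )
    return table.loc[keep]


def compute_rc(query_ratios: pd.DataFrame, reference: ReferenceRatioSet) -> float:
    """Pearson correlation of batch vs reference ratios over shared features.

    The three pair columns are concatenated into one query vector and one
    reference vector over overlapping (feature, pair) entries; >=3 entries
    are required and the reference vector must not be constant.
    """
    shared = query_ratios.index.intersection(reference.ratios.index)
    q_parts, r_parts = [], []
    for pair in PAIRS:
        q = query_ratios.loc[shared, pair]
        r = reference.ratios.loc[shared, pair]
        ok = q.notna()
        q_parts.append(q[ok].values)
        r_parts.append(r[ok].values)
    qv = np.concatenate(q_parts)
    rv = np.concatenate(r_parts)
    if qv.size < 3:
        raise ValueError(
            f"only {qv.size} (feature, pair) entries overlap the reference; >=3 needed"
        )
    if np.ptp(rv) == 0.0:
        raise ValueError("reference ratio vector is constant; RC undefined")
    return float(stats.pearsonr(qv, rv).statistic)


def compute_cv(profile: QuantProfile) -> float:
    """Median coefficient of variation of technical replicates.

    CV = sample sd / mean on raw scale, per (feature, donor) with >=2
    non-missing replicates and a positive mean; the median over all such
    cells is returned.
    """
    raw = profile.raw_matrix()
    cvs: list[float] = []
    for donor in DONORS:
        block = raw[profile.donor_columns(donor)]
        n = block.notna().sum(axis=1)
        m = block.mean(axis=1)
        s = block.std(axis=1, ddof=1)
        ok = (n >= 2) & (m > 0)
        cvs.extend((s[ok] / m[ok]).tolist())
    if not cvs:
        raise ValueError("no (feature, donor) cell has >=2 replicates; CV undefined")
    return float(np.median(cvs))


def replicate_correlation(profile: QuantProfile) -> float:
    """Mean pairwise Pearson correlation of log2 abundances between
    technical replicates of the same donor (complete features only)."""
    log = profile.log2_matrix().dropna(axis=0, how="any")
    rs: list[float] = []
    for donor in DONORS:
        cols = profile.donor_columns(donor)
        for a, b in itertools.combinations(cols, 2):
            rs.append(float(stats.pearsonr(log[a], log[b]).statistic))
    if not rs:
        raise ValueError("no donor has >=2 replicates; replicate correlation undefined")
    return float(np.mean(rs))


def missing_fraction(profile: QuantProfile) -> float:
    return float(profile.data.isna().values.mean())


def feature_count(profile: QuantProfile) -> int:
    """Number of features quantified in at least one sample."""
    return int(profile.data.notna().any(axis=1).sum())


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return math.nan
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


@dataclass
class DamDetection:
    """Welch-t p-values (features x pairs) and the significance threshold."""

    pvalues: pd.DataFrame
    alpha: float = 0.05

    def significant(self, pair: str) -> set[str]:
        p = self.pvalues[pair]
        return set(p.index[p < self.alpha])

    @property
    def sets(self) -> dict[str, set[str]]:
        return {pair: self.significant(pair) for pair in PAIRS}


def detect_dams(profile: QuantProfile, alpha: float = 0.05) -> DamDetection:
    """Per-pair differential abundance by two-sided Welch t-test on log2
    values (raw p < alpha, no multiple-testing correction)."""
    log = profile.log2_matrix()
    d6 = log[profile.donor_columns("D6")].values
    pvals = pd.DataFrame(index=log.index, columns=list(PAIRS), dtype=float)
    for pair in PAIRS:
        other = log[profile.donor_columns(pair.split("/")[0])].values
        pvals[pair] = [
            _welch_p(other[i], d6[i]) for i in range(log.shape[0])
        ]
    return DamDetection(pvalues=pvals, alpha=alpha)


def dam_recall(
    detection: DamDetection,
    reference: ReferenceRatioSet,
    restrict_to_measured: bool = True,
) -> float:
    """Fraction of reference DAM (feature, pair) entries rediscovered.

    By default the denominator counts only reference DAM entries whose
    feature was testable in the profile; ``restrict_to_measured=False``
    counts every flagged reference entry.
    """
    found = 0
    total = 0
    for pair in PAIRS:
        flagged = reference.dam_flags.index[reference.dam_flags[pair]]
        sig = detection.significant(pair)
        testable = detection.pvalues[pair].dropna().index
        for feat in flagged:
            if restrict_to_measured and feat not in testable:
                continue
            total += 1
            if feat in sig:
                found += 1
    if total == 0:
        raise ValueError("no reference DAM entries are measurable; recall undefined")
    return found / total


def scale01_snr(snr: float) -> float:
    """Linear map of SNR from [0, 100] dB onto [0, 1], clamped."""
    return float(np.clip(snr / SNR_CAP_DB, 0.0, 1.0))


@dataclass
class ScoreResult:
    """An omics total score with its constituent (scaled) components."""

    omics: str
    total: float
    components: dict[str, float]
    warnings: list[str]

    def as_dict(self) -> dict:
        return {
            "omics": self.omics,
            "total_score": self.total,
            "components": dict(self.components),
            "warnings": list(self.warnings),
        }


def transcriptomics_score(snr: float, rc: float) -> ScoreResult:
    """Transcriptomics total: product of scaled SNR and clamped RC."""
    snr_scaled = scale01_snr(snr)
    rc_clamped = max(rc, 0.0)
    notes = []
    if rc < 0:
        notes.append("negative RC clamped to 0 in the total score")
    return ScoreResult(
        omics="transcriptomics",
        total=snr_scaled * rc_clamped,
        components={
            "snr_scaled": snr_scaled,
            "rc_clamped": rc_clamped,
            "raw_product": snr * rc,
        },
        warnings=notes,
    )


def _minmax_scale(value: float, history: Sequence[float], invert: bool) -> float:
    lo, hi = min(history), max(history)
    if hi == lo:
        raise ValueError("constant historical distribution")
    x = (hi - value) / (hi - lo) if invert else (value - lo) / (hi - lo)
    return float(np.clip(x, _SCORE_FLOOR, 1.0))


def proteomics_score(
    metrics: QuantMetrics, historical: Mapping[str, Sequence[float]]
) -> ScoreResult:
    """Proteomics total: geometric mean of six historically-scaled metrics.

    Each metric is min-max scaled against its historical distribution to
    [0.01, 1]; missing fraction and median CV are inverted first (lower is
    better).
    """
    values = metrics.as_dict()
    scaled: dict[str, float] = {}
    for name, invert in PROTEOMICS_METRICS.items():
        if name not in historical or len(set(historical[name])) < 2:
            raise ValueError(
                f"historical distribution for {name!r} missing or constant"
            )
        scaled[name] = _minmax_scale(float(values[name]), historical[name], invert)
    total = float(np.prod(list(scaled.values())) ** (1.0 / len(scaled)))
    return ScoreResult(
        omics="proteomics", total=total, components=scaled, warnings=[]
    )


def metabolomics_score(dam_recall_value: float, snr: float, rc: float) -> ScoreResult:
    """Metabolomics total: geometric mean of DAM recall, scaled SNR and
    clamped RC, with components floored at 0.01."""
    comps = {
        "dam_recall": dam_recall_value,
        "snr_scaled": scale01_snr(snr),
        "rc_clamped": max(rc, 0.0),
    }
    notes = [
        f"component {k} floored at {_SCORE_FLOOR}" for k, v in comps.items()
        if v < _SCORE_FLOOR
    ]
    floored = {k: max(v, _SCORE_FLOOR) for k, v in comps.items()}
    total = float(np.prod(list(floored.values())) ** (1.0 / 3.0))
    return ScoreResult(
        omics="metabolomics", total=total, components=floored, warnings=notes
    )


def compute_quant_metrics(
    profile: QuantProfile,
    reference: ReferenceRatioSet,
    alpha: float = 0.05,
    with_dam_recall: bool = False,
) -> QuantMetrics:
    """Convenience: assemble every batch metric against a reference set."""
    ratios = compute_ratios(profile)
    recall = None
    if with_dam_recall:
        recall = dam_recall(detect_dams(profile, alpha=alpha), reference)
    return QuantMetrics(
        snr=compute_snr(profile),
        rc=compute_rc(ratios, reference),
        cv_median=compute_cv(profile),
        missing_pct=missing_fraction(profile),
        n_features=feature_count(profile),
        replicate_corr=replicate_correlation(profile),
        dam_recall=recall,
    )
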