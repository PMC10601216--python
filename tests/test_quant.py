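"""Quantitative metrics: SNR, ratios, RC, CV, DAM detection and totals."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from quartet_qc.profiles import PAIRS, QuantProfile, ReferenceRatioSet
from quartet_qc.quant import (
    DamDetection,
    QuantMetrics,
    compute_cv,
    compute_ratios,
    compute_rc,
    compute_snr,
    dam_recall,
    detect_dams,
    metabolomics_score,
    proteomics_score,
    scale01_snr,
    transcriptomics_score,
)
from quartet_qc.simulate import ProfileSimConfig, simulate_profile


def make_profile(frame: pd.DataFrame, log_scale=False) -> QuantProfile:
    return QuantProfile(data=frame, log_scale=log_scale)


def snr_oracle(profile: QuantProfile) -> float:
    """Directly coded pairwise-distance SNR in the scaled PC plane,
    independent of the pipeline (plain SVD, no scikit-learn)."""
    log = profile.log2_matrix().dropna(axis=0, how="any")
    X = log.values.T
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    evr = s**2 / (s**2).sum()
    coords = (U[:, :2] * s[:2]) * evr[:2]
    donors = [c.split("_")[0] for c in log.columns]
    signal, noise, ns, nn = 0.0, 0.0, 0, 0
    for i, j in itertools.combinations(range(len(donors)), 2):
        d2 = float(((coords[i] - coords[j]) ** 2).sum())
        if donors[i] == donors[j]:
            noise, nn = noise + d2, nn + 1
        else:
            signal, ns = signal + d2, ns + 1
    signal /= ns
    noise /= nn
    if noise < 1e-12:
        return 100.0
    return min(10.0 * math.log10(signal / noise), 100.0)


class TestSnr:
    def test_pipeline_matches_independent_oracle_on_fixed_fixtures(self):
        for seed in (1, 2, 3):
            profile, _ = simulate_profile(
                ProfileSimConfig(n_features=200, noise_sd=0.5, seed=seed)
            )
            assert compute_snr(profile) == pytest.approx(
                snr_oracle(profile), abs=1e-9
            )

    def test_lower_noise_gives_higher_snr(self):
        lo, _ = simulate_profile(ProfileSimConfig(n_features=200, noise_sd=0.1, seed=1))
        hi, _ = simulate_profile(ProfileSimConfig(n_features=200, noise_sd=1.0, seed=1))
        assert compute_snr(lo) > compute_snr(hi)

    def test_zero_noise_hits_the_cap(self):
        profile, _ = simulate_profile(
            ProfileSimConfig(n_features=100, noise_sd=0.0, seed=0)
        )
        assert compute_snr(profile) == 100.0

    def test_identical_columns_are_degenerate(self, tiny_profile_frame):
        frame = tiny_profile_frame.copy()
        for c in frame.columns:
            frame[c] = [5.0, 6.0, 7.0]
        with pytest.raises(ValueError, match="vanish"):
            compute_snr(make_profile(frame, log_scale=True))

    def test_invariant_to_feature_order_and_constant_shift(self):
        profile, _ = simulate_profile(
            ProfileSimConfig(n_features=150, noise_sd=0.3, seed=4)
        )
        base = compute_snr(profile)
        permuted = QuantProfile(
            data=profile.data.sample(frac=1.0, random_state=0), log_scale=True
        )
        shifted = QuantProfile(data=profile.data + 3.5, log_scale=True)
        assert compute_snr(permuted) == pytest.approx(base, abs=1e-9)
        assert compute_snr(shifted) == pytest.approx(base, abs=1e-9)


class TestRatios:
    def test_ratio_is_difference_of_log_means(self):
        cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2)]
        frame = pd.DataFrame(
            [[8.0, 8.0, 6.0, 6.0, 7.0, 7.0, 6.5, 6.5]], index=["F1"], columns=cols
        )
        ratios = compute_ratios(make_profile(frame, log_scale=True))
        assert ratios.loc["F1", "D5/D6"] == pytest.approx(2.0)
        assert ratios.loc["F1", "F7/D6"] == pytest.approx(1.0)
        assert ratios.loc["F1", "M8/D6"] == pytest.approx(0.5)

    def test_identical_means_give_zero_ratio(self):
        cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2)]
        frame = pd.DataFrame([[5.0] * 8], index=["F1"], columns=cols)
        ratios = compute_ratios(make_profile(frame, log_scale=True))
        assert ratios.loc["F1", "D5/D6"] == 0.0

    def test_feature_missing_in_all_d6_replicates_is_excluded(self):
        cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2)]
        frame = pd.DataFrame(
            [
                [8.0, 8.0, np.nan, np.nan, 7.0, 7.0, 6.0, 6.0],
                [8.0, 8.0, 6.0, 6.0, 7.0, 7.0, 6.0, 6.0],
            ],
            index=["GONE", "KEPT"],
            columns=cols,
        )
        ratios = compute_ratios(make_profile(frame, log_scale=True))
        assert list(ratios.index) == ["KEPT"]


def _reference_from(ratios: pd.DataFrame) -> ReferenceRatioSet:
    flags = pd.DataFrame(False, index=ratios.index, columns=list(PAIRS))
    return ReferenceRatioSet(ratios=ratios.copy(), dam_flags=flags)


class TestRc:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.ratios = pd.DataFrame(
            rng.normal(size=(30, 3)), columns=list(PAIRS),
            index=[f"F{i}" for i in range(30)],
        )
        self.reference = _reference_from(self.ratios)

    def test_self_correlation_is_one(self):
        assert compute_rc(self.ratios, self.reference) == pytest.approx(1.0, abs=1e-12)

    def test_shift_and_positive_scale_invariance(self):
        assert compute_rc(self.ratios + 1.7, self.reference) == pytest.approx(
            1.0, abs=1e-12
        )
        assert compute_rc(self.ratios * 2.5 - 0.3, self.reference) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_sign_flip_gives_minus_one(self):
        assert compute_rc(-self.ratios, self.reference) == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_too_small_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            compute_rc(self.ratios.iloc[:0], self.reference)

    def test_constant_reference_rejected(self):
        const = _reference_from(self.ratios * 0.0)
        with pytest.raises(ValueError, match="constant"):
            compute_rc(self.ratios, const)


class TestCv:
    def test_hand_computed_sample_sd_convention(self):
        # Only D5 is replicated, so its CV is the sole cell: sample sd of
        # (90, 100, 110) is 10, mean 100 -> CV 0.1.
        cols = ["D5_1", "D5_2", "D5_3", "D6_1", "F7_1", "M8_1"]
        row = [90.0, 100.0, 110.0, 100.0, 100.0, 100.0]
        frame = pd.DataFrame([row], index=["F1"], columns=cols)
        cv = compute_cv(make_profile(frame))
        assert cv == pytest.approx(0.1)

    def test_identical_replicates_give_zero(self, tiny_profile_frame):
        frame = tiny_profile_frame.copy()
        for d in ("D5", "D6", "F7", "M8"):
            for r in (1, 2, 3):
                frame[f"{d}_{r}"] = [100.0, 50.0, 10.0]
        assert compute_cv(make_profile(frame)) == 0.0

    def test_single_replicate_cells_are_skipped(self):
        cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2)]
        frame = pd.DataFrame(
            [[90.0, np.nan, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]],
            index=["F1"], columns=cols,
        )
        # D5 has one replicate -> skipped entirely; remaining CVs all zero
        assert compute_cv(make_profile(frame)) == 0.0

    def test_no_replicated_cells_raises(self):
        cols = [f"{d}_1" for d in ("D5", "D6", "F7", "M8")]
        frame = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["F1"], columns=cols)
        with pytest.raises(ValueError, match="CV undefined"):
            compute_cv(make_profile(frame))


def welch_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Hand-coded Welch t-test (two-sided) used as the independent check."""
    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    tstat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2.0 * tdist.sf(abs(tstat), df))


class TestDamDetection:
    def test_pvalues_match_independent_welch_to_1e9(self):
        profile, _ = simulate_profile(
            ProfileSimConfig(n_features=50, noise_sd=0.3, seed=9)
        )
        det = detect_dams(profile)
        log = profile.log2_matrix()
        for pair in PAIRS:
            donor = pair.split("/")[0]
            for feat in log.index[:20]:
                a = log.loc[feat, profile.donor_columns(donor)].values
                b = log.loc[feat, profile.donor_columns("D6")].values
                assert det.pvalues.loc[feat, pair] == pytest.approx(
                    welch_oracle(a, b), abs=1e-9
                )

    def test_identical_groups_are_not_significant(self):
        cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2, 3)]
        frame = pd.DataFrame([[5.0] * 12], index=["F1"], columns=cols)
        det = detect_dams(make_profile(frame, log_scale=True))
        assert det.pvalues.loc["F1", "D5/D6"] == 1.0
        assert det.significant("D5/D6") == set()

    def test_planted_fourfold_change_is_detected(self):
        rng = np.random.default_rng(5)
        cols = [f"{d}_{r}" for d in ("D5", "D6", "F7", "M8") for r in (1, 2, 3)]
        base = rng.normal(8.0, 0.1, size=(1, 12))
        frame = pd.DataFrame(base, index=["F1"], columns=cols)
        frame.loc["F1", ["D5_1", "D5_2", "D5_3"]] += 2.0  # 4-fold on log2 scale
        det = detect_dams(make_profile(frame, log_scale=True))
        assert "F1" in det.significant("D5/D6")

    def test_alpha_zero_yields_empty_sets(self):
        profile, _ = simulate_profile(
            ProfileSimConfig(n_features=30, noise_sd=0.2, seed=2)
        )
        det = detect_dams(profile, alpha=0.0)
        assert all(not s for s in det.sets.values())


class TestDamRecall:
    def make_detection(self, pvals_by_feature: dict[str, float]) -> DamDetection:
        frame = pd.DataFrame(
            {pair: pd.Series(pvals_by_feature) for pair in PAIRS}
        )
        return DamDetection(pvalues=frame)

    def test_three_of_four_reference_dams_found(self):
        det = self.make_detection({"A": 0.001, "B": 0.01, "C": 0.04, "D": 0.5})
        ratios = pd.DataFrame(2.0, index=list("ABCD"), columns=list(PAIRS))
        flags = pd.DataFrame(False, index=list("ABCD"), columns=list(PAIRS))
        flags["D5/D6"] = [True, True, True, True]
        ref = ReferenceRatioSet(ratios=ratios, dam_flags=flags)
        assert dam_recall(det, ref) == pytest.approx(0.75)

    def test_boundary_recalls(self):
        det = self.make_detection({"A": 0.001, "B": 0.001})
        ratios = pd.DataFrame(1.0, index=list("AB"), columns=list(PAIRS))
        flags = pd.DataFrame(True, index=list("AB"), columns=list(PAIRS))
        ref = ReferenceRatioSet(ratios=ratios, dam_flags=flags)
        assert dam_recall(det, ref) == 1.0
        det_none = self.make_detection({"A": 0.9, "B": 0.9})
        assert dam_recall(det_none, ref) == 0.0

    def test_zero_denominator_raises(self):
        det = self.make_detection({"A": 0.001})
        ratios = pd.DataFrame(1.0, index=["A"], columns=list(PAIRS))
        flags = pd.DataFrame(False, index=["A"], columns=list(PAIRS))
        ref = ReferenceRatioSet(ratios=ratios, dam_flags=flags)
        with pytest.raises(ValueError, match="recall undefined"):
            dam_recall(det, ref)


HIST = {
    "n_features": [100.0, 1100.0],
    "missing_pct": [0.0, 1.0],
    "replicate_corr": [0.0, 1.0],
    "cv_median": [0.0, 1.0],
    "snr": [0.0, 100.0],
    "rc": [0.0, 1.0],
}


def metrics_with(**overrides) -> QuantMetrics:
    base = dict(
        snr=100.0, rc=1.0, cv_median=0.0, missing_pct=0.0,
        n_features=1100, replicate_corr=1.0,
    )
    base.update(overrides)
    return QuantMetrics(**base)


class TestScores:
    def test_transcriptomics_extremes_and_midpoint(self):
        assert transcriptomics_score(100.0, 1.0).total == 1.0
        assert transcriptomics_score(50.0, 0.8).total == pytest.approx(0.40)
        assert transcriptomics_score(60.0, -0.2).total == 0.0

    def test_transcriptomics_reports_raw_product(self):
        res = transcriptomics_score(50.0, 0.8)
        assert res.components["raw_product"] == pytest.approx(40.0)

    def test_proteomics_perfect_metrics_score_one(self):
        res = proteomics_score(metrics_with(), HIST)
        assert res.total == pytest.approx(1.0)

    def test_proteomics_single_quarter_component(self):
        res = proteomics_score(metrics_with(n_features=350), HIST)
        assert res.total == pytest.approx(0.25 ** (1 / 6), abs=1e-12)

    def test_proteomics_floor_bound(self):
        res = proteomics_score(metrics_with(snr=0.0), HIST)
        assert res.total <= 0.01 ** (1 / 6) + 1e-12

    def test_proteomics_matches_brute_force_geometric_mean(self):
        res = proteomics_score(
            metrics_with(snr=40.0, rc=0.7, cv_median=0.3, missing_pct=0.1), HIST
        )
        brute = 1.0
        for v in res.components.values():
            brute *= v
        assert res.total == pytest.approx(brute ** (1 / 6), abs=1e-12)

    def test_proteomics_is_permutation_invariant_in_components(self):
        # Two metric sets whose scaled component multisets coincide
        a = proteomics_score(metrics_with(snr=25.0, rc=1.0), HIST)
        b = proteomics_score(metrics_with(snr=100.0, rc=0.25), HIST)
        assert sorted(a.components.values()) == sorted(b.components.values())
        assert a.total == pytest.approx(b.total, abs=1e-12)

    def test_proteomics_constant_history_names_the_metric(self):
        hist = dict(HIST, snr=[50.0, 50.0])
        with pytest.raises(ValueError, match="snr"):
            proteomics_score(metrics_with(), hist)

    def test_metabolomics_extremes_and_floor(self):
        assert metabolomics_score(1.0, 100.0, 1.0).total == 1.0
        assert metabolomics_score(0.25, 100.0, 1.0).total == pytest.approx(
            0.25 ** (1 / 3), abs=1e-12
        )
        res = metabolomics_score(0.0, 100.0, 1.0)
        assert res.total == pytest.approx(0.01 ** (1 / 3), abs=1e-12)
        assert res.warnings

    def test_all_totals_lie_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            snr = float(rng.uniform(-10, 120))
            rc = float(rng.uniform(-1, 1))
            recall = float(rng.uniform(0, 1))
            assert 0.0 <= transcriptomics_score(snr, rc).total <= 1.0
            assert 0.0 <= metabolomics_score(recall, snr, rc).total <= 1.0
        assert 0.0 <= scale01_snr(-5.0) <= 1.0
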