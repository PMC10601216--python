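"""Regenerate the historical-score JSON fixtures shipped with the package.

Simulates 20 batches per omics type at graded quality levels (fixed
seeds) and records each batch's total score — and, for proteomics, the
per-metric values needed for min-max scaling.  Output goes to
src/quartet_qc/data/historical/.  Run from the repository root:

    python scripts/make_historical.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from quartet_qc import (
    HistoricalScores,
    ProfileSimConfig,
    QuartetSimConfig,
    compute_quant_metrics,
    evaluate_genomics,
    metabolomics_score,
    proteomics_score,
    simulate_profile,
    simulate_quartet_variants,
    transcriptomics_score,
)
from quartet_qc.quant import PROTEOMICS_METRICS

OUT = Path(__file__).resolve().parents[1] / "src" / "quartet_qc" / "data" / "historical"
N_BATCHES = 20
VERSION = "sim-2024.1"


def quality_grid(rng: np.random.Generator) -> list[dict]:
    """Twenty batches from excellent to poor, with mild jitter."""
    levels = np.linspace(0.0, 1.0, N_BATCHES)  # 0 = best, 1 = worst
    return [
        {
            "n_features": 600 - int(250 * lv * rng.random()),
            "noise_sd": 0.05 + 0.9 * lv + 0.05 * rng.random(),
            "missing_rate": 0.2 * lv * rng.random(),
            "fp_rate": 0.001 + 0.12 * lv,
            "fn_rate": 0.002 + 0.2 * lv,
            "genotype_error_rate": 0.001 + 0.08 * lv,
        }
        for lv in levels
    ]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(20240001)
    grid = quality_grid(rng)

    genomics_scores = []
    for i, g in enumerate(grid):
        cfg = QuartetSimConfig(
            n_variants=1500,
            fp_rate=g["fp_rate"],
            fn_rate=g["fn_rate"],
            genotype_error_rate=g["genotype_error_rate"],
            seed=1000 + i,
        )
        bench, test = simulate_quartet_variants(cfg)
        genomics_scores.append(evaluate_genomics(test, bench).total_score)
    HistoricalScores("genomics", genomics_scores, VERSION).to_json(OUT / "genomics.json")

    metric_sets = []
    for i, g in enumerate(grid):
        cfg = ProfileSimConfig(
            n_features=g["n_features"],
            noise_sd=g["noise_sd"],
            missing_rate=g["missing_rate"],
            seed=2000 + i,
        )
        prof, ref = simulate_profile(cfg)
        metric_sets.append(compute_quant_metrics(prof, ref, with_dam_recall=True))

    HistoricalScores(
        "transcriptomics",
        [transcriptomics_score(m.snr, m.rc).total for m in metric_sets],
        VERSION,
    ).to_json(OUT / "transcriptomics.json")

    hist_metrics = {
        name: [float(getattr(m, name)) for m in metric_sets]
        for name in PROTEOMICS_METRICS
    }
    HistoricalScores(
        "proteomics",
        [proteomics_score(m, hist_metrics).total for m in metric_sets],
        VERSION,
        metrics=hist_metrics,
    ).to_json(OUT / "proteomics.json")

    HistoricalScores(
        "metabolomics",
        [metabolomics_score(m.dam_recall, m.snr, m.rc).total for m in metric_sets],
        VERSION,
    ).to_json(OUT / "metabolomics.json")

    for f in sorted(OUT.glob("*.json")):
        print(f.name, "written")


if __name__ == "__main__":
    main()
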