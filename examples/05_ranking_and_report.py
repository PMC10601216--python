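"""Ranking a batch against historical scores and writing the QC report.

Scores a simulated genomics batch, ranks it among the shipped historical
batches, assigns the great/good/fair/bad category and writes both the
JSON and HTML report forms to a temporary directory.
"""

import tempfile
from pathlib import Path

from quartet_qc import (
    MetricRow,
    QuartetSimConfig,
    build_report,
    categorize,
    default_historical,
    evaluate_genomics,
    percentile_rank,
    simulate_quartet_variants,
)

benchmark, calls = simulate_quartet_variants(
    QuartetSimConfig(n_variants=3_000, fp_rate=0.02, fn_rate=0.03,
                     genotype_error_rate=0.005, seed=9)
)
card = evaluate_genomics(calls, benchmark)
historical = default_historical("genomics")
pct = percentile_rank(card.total_score, historical)
category = categorize(pct)

report = build_report(
    omics="genomics",
    scorecard=card.as_dict(),
    total_score=card.total_score,
    percentile=pct,
    category=category,
    metrics=[MetricRow(name=f"combined_{c}", value=getattr(card, f"combined_{c}"))
             for c in ("precision", "recall", "mcr")],
    warnings=card.warnings,
    seed=9,
)

out = Path(tempfile.mkdtemp(prefix="quartet_qc_"))
report.write(out / "report.json")
report.write(out / "report.html")

print(f"total score {card.total_score:.4f} -> percentile {pct:.1f} "
      f"of {len(historical.scores)} historical batches -> {category.value!r}")
print(f"reports written to {out}")
print()
print("Percentile uses the midrank tie convention; categories cut at the "
      "80th/50th/20th percentiles (top 20% = great, bottom 20% = bad).")
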