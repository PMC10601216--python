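"""Genomics QC: precision/recall vs a benchmark plus Mendelian concordance.

Simulates a quartet call set with injected errors (5% false calls, 10%
dropped variants, 2% genotype errors), scores it against the matched
benchmark and prints the score card.
"""

from quartet_qc import QuartetSimConfig, evaluate_genomics, simulate_quartet_variants

cfg = QuartetSimConfig(
    n_variants=5_000, fp_rate=0.05, fn_rate=0.10, genotype_error_rate=0.02, seed=7
)
benchmark, calls = simulate_quartet_variants(cfg)
card = evaluate_genomics(calls, benchmark)

for vtype in ("SNV", "Indel"):
    print(
        f"{vtype:6s} precision={card.precision[vtype]:.4f} "
        f"recall={card.recall[vtype]:.4f} MCR={card.mcr[vtype]:.4f}"
    )
print(
    f"combined (F0.5) precision={card.combined_precision:.4f} "
    f"recall={card.combined_recall:.4f} MCR={card.combined_mcr:.4f}"
)
print(f"genomics total score = {card.total_score:.4f}")
print()
print(
    "The measured precision/recall recover the injected error rates "
    "(~0.95/~0.90); the MCR below 1 reflects genotype errors and the "
    "pedigree-inconsistent half of the injected false calls."
)
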