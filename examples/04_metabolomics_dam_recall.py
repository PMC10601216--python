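"""Metabolomics QC: recall of reference differential metabolites (DAMs).

Plants 4-fold differential features between each donor pair and D6,
rediscover them by Welch t-test (raw p < 0.05) and combines the recall
with SNR and RC into the metabolomics total score.
"""

from quartet_qc import (
    ProfileSimConfig,
    compute_quant_metrics,
    metabolomics_score,
    simulate_profile,
)

profile, reference = simulate_profile(
    ProfileSimConfig(
        n_features=500, dam_fraction=0.1, dam_log2fc=2.0, noise_sd=0.15, seed=5
    )
)
metrics = compute_quant_metrics(profile, reference, with_dam_recall=True)
result = metabolomics_score(metrics.dam_recall, metrics.snr, metrics.rc)

n_flagged = int(reference.dam_flags.values.sum())
print(f"reference DAM entries     : {n_flagged}")
print(f"DAM recall (p < 0.05)     : {metrics.dam_recall:.4f}")
print(f"SNR = {metrics.snr:.2f} dB, RC = {metrics.rc:.4f}")
print(f"metabolomics total score  : {result.total:.4f}")
print()
print(
    "Recall is the fraction of flagged reference (feature, pair) entries "
    "found significant; a 4-fold planted change against sd 0.15 noise is "
    "nearly always recovered with 3 replicates per donor."
)
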