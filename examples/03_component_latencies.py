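"""Recover planted component latencies for a small two-group cohort.

Simulates 6 controls and 6 ADHD participants (direct epoch generation),
detects N2/P3a/P3b peaks per electrode on each condition average, pools
them into frontocentral/centroparietal tables, and compares the pooled
medians with the latencies the generator planted.
"""

from gamblerp.study import latency_recovery_run

merged = latency_recovery_run(seed=4, n_per_group=6)
cols = ["component", "roi", "group", "condition", "median", "planted_ms", "error_ms"]
print(merged[cols].round(1).to_string(index=False))
print()
print("'median' is the pooled median detected latency (participants x 3")
print("electrodes per ROI); 'planted_ms' is the generator's mean latency for")
print("that cell; 'error_ms' is their difference — a parameter-recovery check")
print("of the whole generator -> preprocess -> peak-detection chain.")
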