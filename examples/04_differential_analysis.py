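"""Feedback-frequency difference waves and the band-separation contrast.

Simulates two cohorts — one with a frontocentral group-by-condition P3a
amplitude interaction planted, one without — forms each participant's
HF-LF difference wave, and tests the group contrast by integrating the
gap between the two mean±SEM envelopes over the N2-P3 window (260±50 ms),
with a permutation test, at a frontal and a posterior site.
"""

from gamblerp.differential import band_separation_test, window_amplitude_profile
from gamblerp.simulate_eeg import default_templates
from gamblerp.study import (
    StudyConfig,
    add_frontal_interaction,
    group_difference_waves,
    simulate_group_erps,
)

plain = StudyConfig()
planted = StudyConfig(
    templates=add_frontal_interaction(default_templates(), component="P3a", group="controls")
)

diffs_a = group_difference_waves(simulate_group_erps("controls", 10, 8, plain, "S"))
diffs_b = group_difference_waves(simulate_group_erps("controls", 10, 9, planted, "S"))

for el in ("Fz", "POz"):
    ws = band_separation_test(diffs_a, diffs_b, 260.0, electrode=el, n_perm=499, seed=0)
    tag = "significant" if ws.significant_nonzero else "not significant"
    print(f"{el}: band separation {ws.statistic:8.2f} uV*ms, p = {ws.p_value:.3f} ({tag})")

print()
prof = window_amplitude_profile(diffs_b, 260.0, seed=0)
print("cohort B window-amplitude profile (HF-LF integral, 260±50 ms):")
for el, ws in prof.items():
    mark = " *" if ws.significant_nonzero else ""
    print(f"  {el:>3}: {ws.statistic:8.2f} uV*ms  95% CI [{ws.ci_low:8.2f}, {ws.ci_high:8.2f}]{mark}")
print()
print("The planted interaction scales P3a only at Fz/FCz/Cz, so the group")
print("contrast separates the confidence bands frontally but not at POz;")
print("starred electrodes have bootstrap CIs excluding zero.")
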