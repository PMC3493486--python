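"""How the structure of distractor oscillations limits communication.

Runs the same decoding pipeline under four oscillation structures:
asynchronous distractors, distractors oscillating incoherently in the
target's frequency band, distractors separated in frequency, and
distractors sharing the target's oscillation at evenly spaced phases.
Higher Fisher information means more precise recovery of the target
orientation; incoherent same-band distractors are the worst case because
their cycle-to-cycle phase drift relative to the gain modulation adds
'overlap' noise that stochastic spiking alone does not produce.
"""

from ctcsim import build_condition, fit_and_evaluate

# label separations pre-calibrated to the 75-80% classification band
SETTINGS = {
    "asynchronous": 1.4,
    "incoherent_same_band": 7.0,
    "frequency_separated": 1.6,
    "phase_separated": 2.0,
}

print(f"{'condition':26s} {'delta (deg)':>11s} {'FI (deg^-2)':>12s} {'correct':>8s}")
for name, delta in SETTINGS.items():
    result, _ = fit_and_evaluate(build_condition(name), delta, 2000, seed=7)
    print(f"{name:26s} {delta:11.1f} {result.fisher_info:12.4f}"
          f" {100 * result.fraction_correct:7.1f}%")
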