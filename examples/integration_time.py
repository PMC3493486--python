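"""Integration time and the minimum window for oscillatory routing.

Fisher information grows linearly with the integration window as long as
the window spans at least about two cycles of the target modulation; below
one cycle the distractor contributions no longer average out and accuracy
collapses.  For long windows the filter response above three times the
modulation frequency is clamped to zero (there is no target power there).
"""

from ctcsim import build_condition, fit_and_evaluate

print(f"{'window (ms)':>12s} {'cycles of 50 Hz':>16s} {'FI (deg^-2)':>12s}")
for T, delta in ((0.01, 4.0), (0.02, 3.0), (0.04, 2.2), (0.1, 1.4), (0.2, 1.0)):
    cond = build_condition("asynchronous", integration_time=T)
    cap = 150.0 if T >= 0.2 else None
    result, _ = fit_and_evaluate(cond, delta, 1000, seed=83, freq_cap=cap)
    print(f"{1000 * T:12.0f} {T * 50:16.1f} {result.fisher_info:12.4f}")
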