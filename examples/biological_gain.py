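"""Optimized filter versus a biologically plausible gain waveform.

In the incoherent-distractor condition the optimized filter de-emphasizes
the shared 50 Hz band and reads the target's low- and high-frequency
modulation components instead.  A receiving network whose gain simply
follows the target's own modulation waveform (oscillating around zero)
cannot do this; comparing the two on identical batches shows the cost.
"""

import numpy as np

from ctcsim import (
    biological_gain_baseline,
    build_condition,
    decode,
    evaluate_estimates,
    fit_decoder,
    generate_batch,
    hann_window,
)

condition = build_condition("incoherent_same_band")
train = hann_window(generate_batch(condition, 7.0, 2000, seed=52))
test = hann_window(generate_batch(condition, 7.0, 2000, seed=53))

model, _, _ = fit_decoder(train, test)
fi_optimized = evaluate_estimates(decode(model, test), test.labels, 7.0).fisher_info
baseline, _ = biological_gain_baseline(train, test)

h = np.abs(model.h.coefficients)
band = h[4:7].mean()      # 40-60 Hz (the shared oscillation band)
flanks = np.r_[h[2:4], h[7:10]].mean()

print(f"optimized filter FI:        {fi_optimized:.4f} deg^-2")
print(f"waveform-matched gain FI:   {baseline.fisher_info:.4f} deg^-2")
print(f"FI deficit of the waveform gain: "
      f"{100 * (1 - baseline.fisher_info / fi_optimized):.1f}%")
print(f"|H| in the shared band / flanks: {band / flanks:.2f}"
      " (the optimized filter suppresses the band both signals occupy)")
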