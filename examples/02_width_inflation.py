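"""Measure how speckle noise distorts apparent peak widths.

Renders single Gaussian pulses, adds coherent speckle noise over a range
of signal-to-noise ratios, smooths, measures FWHM with filter-broadening
correction, and prints the mean fractional width change per condition.
"""

import numpy as np

from octflux import characterize_width_inflation, width_inflation_plateau

table = characterize_width_inflation(n_rep=100, rng=np.random.default_rng(0))
pivot = table.pivot(index="snr", columns="base_fwhm", values="frac_change")
print("mean fractional FWHM change (%) by SNR (rows) and base width (columns):")
print((100 * pivot).round(1))

plateau = width_inflation_plateau(table)
print(f"\nplateau magnitude of the distortion: {100 * plateau:.1f}%")
# The magnitude grows as the SNR falls and saturates near one fifth of the
# true width, roughly the same for 5-20 ms pulses: noise corrupts narrow
# and wide passages alike, which is why widths (hence RBC speeds) from
# noisy traces need this correction.
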