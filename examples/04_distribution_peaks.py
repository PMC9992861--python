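"""Find the modes of a bimodal distance distribution.

Transient salt bridges show up as bimodal atom-pair distance
distributions: a bound mode near contact distance and a dissociated
mode further out. This example samples a 0.6·N(3.8 Å, 0.3²) +
0.4·N(6.9 Å, 0.5²) mixture (20 000 frames), estimates the kernel
density, and reports the detected peaks and the state summary. The
dominant "most probable distance" is the bound mode near 3.8 Å, far
from the distribution mean.
"""

from motorscape import density_1d, find_peaks_1d, state_summary
from motorscape.synthetic import make_bimodal_series

modes = [(3.8, 0.3, 0.6), (6.9, 0.5, 0.4)]  # (position Å, sd, weight)
series, truth = make_bimodal_series(modes, 20_000, seed=8)

curve = density_1d(series)
report = find_peaks_1d(curve, prominence_fraction=0.05)
print(f"bandwidth (Silverman): {report.bandwidth:.3f} Å")
for i, peak in enumerate(report, start=1):
    print(f"peak {i}: {peak.position:.2f} Å  "
          f"(density {peak.density:.3f}, prominence {peak.prominence:.3f})")

most_probable, mean, sd = state_summary(series)
print(f"most probable distance: {most_probable:.2f} Å  "
      f"(mean {mean:.2f} Å, sd {sd:.2f} Å)")
print("planted modes: 3.80 and 6.90 Å")
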