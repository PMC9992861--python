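"""Collective variables over a synthetic two-domain motor ensemble.

Builds a toy motor with a planted 16 Å inter-domain cleft and a 22°
helix/strand crossing angle, adds 0.2 Å coordinate jitter, and measures
both collective variables plus the inter-domain buried contact area.
The printed means should sit at the planted values (the angle within
the axis-fit tolerance), demonstrating that the CVs recover known
geometry from noisy coordinates.
"""

import numpy as np

from motorscape import cleft_width, contact_area, crossing_angle
from motorscape.synthetic import ToyMotorSpec, make_toy_motor

spec = ToyMotorSpec(
    n_frames=50,
    cleft_distance=16.0,   # Å, planted Cα–Cα anchor distance
    crossing_angle=22.0,   # deg, planted helix/strand crossing angle
    loop_jitter_sd=0.2,    # Å per-coordinate Gaussian noise
    seed=7,
)
ensemble, truth = make_toy_motor(spec)

cleft = cleft_width(ensemble, *truth["cleft_anchors"])
angle = crossing_angle(ensemble, *truth["angle_motifs"])
contact = contact_area(
    ensemble,
    truth["motifs"]["domain_A"],
    truth["motifs"]["domain_B"],
    n_points=240,
)

print(f"frames: {ensemble.n_frames}, atoms: {ensemble.n_atoms}")
print(f"cleft width   : {cleft.values.mean():6.2f} ± {cleft.values.std():.2f} Å"
      f"   (planted 16.00)")
print(f"crossing angle: {angle.values.mean():6.2f} ± {angle.values.std():.2f} °"
      f"   (planted 22.00)")
print(f"contact area  : {contact.values.mean():6.2f} Å²"
      f"  (domains barely touch at this separation)")
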