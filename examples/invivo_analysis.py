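"""Tumor growth under checkpoint blockade and the Tex-ratio correlation.

Caliper length/width series become volumes via V = (pi/6) L W^2; endpoint
volumes are compared across arms with Tukey's HSD, and the per-mouse
Module1-Tex / Module2-Tex frequency ratio is correlated with endpoint
volume (significant only when p < 0.05 AND R^2 > 0.25).
"""

import cd4tex as ct
from cd4tex.invivo import endpoint_volumes, ratio_volume_correlation, tukey_compare

tables = ct.simulate_invivo(n_mice_per_arm=8, seed=3)
vols = endpoint_volumes(tables.measurements)
print("mean endpoint volume (mm^3) per arm:")
print(vols.groupby("arm")["volume_mm3"].mean().round(1))

print("\nTukey HSD on endpoint volumes:")
print(tukey_compare(vols).round(4))

res = ratio_volume_correlation(tables.tex_ratios, vols)
print(f"\nTex-ratio vs volume: r = {res.r:.3f}, R^2 = {res.r_squared:.3f}, "
      f"p = {res.p:.2e}, significant = {res.significant}")
# Treated arms shrink tumors and tilt the CD4 compartment toward Module-1
# exhaustion, producing the negative ratio-volume correlation.
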