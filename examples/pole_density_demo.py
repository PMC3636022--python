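"""Bulk or membrane? The rho(s) crescent-density statistic on 2D projections.

A 2D microscope image cannot directly distinguish foci spread through the
cytoplasmic bulk of a cell pole from foci tethered to its membrane: both
project into the same semi-elliptic footprint.  The radial density rho(s)
between nested scaled semi-ellipses separates them.
"""

from polecrowd.pole_density import classify_localization, rho_profile
from polecrowd.synthetic import gen_position_clouds

for kind in ("bulk", "membrane", "control2d"):
    points, truth = gen_position_clouds(kind, n=10_000, rng=0)
    profile = rho_profile(points.to_numpy())
    label, slope, p = classify_localization(profile)
    inner = profile.density[:5].mean()
    edge = profile.density[-1]
    print(f"{kind:10s}: edge/centre density = {edge / inner:5.2f}  "
          f"trend slope = {slope:+.2e} (p = {p:.3f})  ->  {label}")

print("\nA 3D bulk distribution projects to a density that decays smoothly "
      "toward the pole outline (negative trend); a membrane-bound one "
      "piles up abruptly at s = 1 (positive trend); the genuinely 2D "
      "control stays flat (indeterminate).")
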