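"""Generate a synthetic plateau domain with a known peatland truth.

The generator builds a 40x40 cell 10-arc-minute domain: smoothed random
terrain around a 3500 m plateau base, monthly climate with a shared
wet-warm-SE to arid-cold-NW gradient, a permafrost active-layer field,
and a peat mask produced by classifying the derived environment with
known envelope thresholds.
"""

import numpy as np

from peatenvelope import SynthConfig, make_truth

truth = make_truth(SynthConfig(seed=3))
env = truth.env

print(f"domain: {truth.grid.n_lat} x {truth.grid.n_lon} cells at "
      f"{truth.grid.resolution:.0f}' resolution")
print(f"elevation: {env.elevation.min():.0f}-{env.elevation.max():.0f} m, "
      f"slope up to {env.slope.max():.2f} deg")
print(f"MAT: {env.MAT.min():.1f} to {env.MAT.max():.1f} degC, "
      f"MAP: {env.MAP.min():.0f} to {env.MAP.max():.0f} mm/yr")
print(f"moisture index MI: {env.MI.min():.2f} to {env.MI.max():.2f}")
print(f"cells without permafrost (no ALT): {int(env.ALT.isna().sum())}")
print(f"peat cells under the true (narrow) envelope: "
      f"{int(truth.envelope_presence.sum())} of {len(env)}")
print()
print("Presence marks cells inside MI >= 1.7, MAT 0-2 degC, slope <= 2 deg"
      " - the wet, cold, flat fringe of the synthetic plateau.")
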