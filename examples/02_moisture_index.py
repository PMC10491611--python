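"""Moisture index MI = P/PET with equilibrium evapotranspiration.

PET here is the radiation-driven equilibrium rate (s/(s+gamma)) * Rn /
lambda accumulated over a 365-day year from monthly climate; MI > 1
means the climate delivers more water than the atmosphere can take back.
"""

import numpy as np

from peatenvelope import SynthConfig, make_truth, moisture_index
from peatenvelope.radiation import daily_insolation

# insolation building block: top-of-atmosphere radiation and daylength
ra, dl = daily_insolation(33.5, 172)  # near the June solstice
print(f"33.5N, day 172: Ra = {ra:.1f} MJ m-2 d-1, daylength = {dl:.1f} h")

truth = make_truth(SynthConfig(seed=3))
mi = truth.mi
print(f"annual PET across the domain: "
      f"{np.nanmin(truth.env.MAP / truth.env.MI):.0f}-"
      f"{np.nanmax(truth.env.MAP / truth.env.MI):.0f} mm/yr")
print(f"MI across the domain: {np.nanmin(mi.mi):.2f}-{np.nanmax(mi.mi):.2f}")

# the ratio itself is elementary once PET is known
print(f"MI for MAP=400 mm over PET=200 mm: {moisture_index(400, 200):.1f}")
print()
print("Wet south-eastern cells exceed MI 2 (water surplus); the arid "
      "north-west sits near 0.05 - far too dry for peat.")
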