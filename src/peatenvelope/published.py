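"""Published reference values for the Tibetan Plateau peatland study.

Grid counts and evaluation metrics reported for the real-data analysis
(CRU CL 2.0 climate, PEATMAP coverage, literature site database).  They
ship with the package the same way the threshold presets do: as reference
inputs for consistency checks, not as quantities this package recomputes
— the underlying data products are multi-gigabyte downloads.
"""

#: 10' grid cells covering the whole plateau land area
TP_GRID_CELLS = 10_658
#: cells with at least 12.2% peat coverage in the observed peat map
PEAT_GRID_CELLS = 1_305
#: distinct cells occupied by the 309 literature study sites
SITE_GRID_CELLS = 65
#: cells of the Zoige peatland complex reported in the frequency analysis
ZOIGE_GRID_CELLS = 52
#: reported percentage of plateau cells that are peatlands
PEAT_PREVALENCE_PERCENT = 12.7

#: reported model performance (sensitivity, accuracy, kappa, n cells)
REPORTED_METRICS = {
    "zoige": {"sensitivity": 0.69, "accuracy": 0.85, "kappa": 0.65,
              "n_cells": 65},
    "entire_tp": {"sensitivity": 0.48, "accuracy": 0.80, "kappa": 0.28,
                  "n_cells": 10_658},
}

#: the Zoige peatland complex evaluation rectangle (lon_min, lon_max,
#: lat_min, lat_max in degrees)
ZOIGE_BOX = (102.0, 103.0, 32.0, 35.0)

#: reported moisture-index range of the Zoige complex and literature sites
ZOIGE_MI_RANGE = (1.7, 2.4)
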