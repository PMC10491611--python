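"""Project envelope shifts under warming scenarios.

GCM change signals are applied to the baseline climatology with the
anomaly method, the envelope is re-classified, and per-cell transitions
(stable/lost/gained) are summarised.  A +4.3 degC warming - the upper
end of the reported end-of-century MAT change - pushes every baseline
cell past the 2 degC ceiling of the narrow envelope.
"""

from peatenvelope import (SynthConfig, build_environment, classify_to_mask,
                          make_future_scenario, make_truth,
                          moisture_index_field, project_change)

truth = make_truth(SynthConfig(seed=3))
baseline = classify_to_mask(truth.env, truth.true_thresholds, truth.grid)

for delta_t in (0.0, 1.0, 2.5, 4.3):
    scen = make_future_scenario(truth.config, truth.clim, delta_t=delta_t,
                                label=f"+{delta_t}C")
    mi_f, _ = moisture_index_field(scen.clim, truth.elevation)
    env_f = build_environment(scen.clim, mi_f, truth.slope, truth.alt,
                              truth.elevation)
    future = classify_to_mask(env_f, truth.true_thresholds, truth.grid)
    s = project_change(baseline, future).summary
    rf = s["retained_fraction"]
    print(f"dT=+{delta_t:3.1f}C: stable={s['stable_present']:3d} "
          f"lost={s['lost']:3d} gained={s['gained']:3d} "
          f"retained={rf:.0%}")

print("\nModest warming trades cells along the envelope edge; strong "
      "warming empties the narrow envelope entirely (retained 0%), the "
      "qualitative signature of a high-emission scenario.")
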