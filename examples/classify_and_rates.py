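"""Classify cells as transfected / proliferating and compute the rate.

Per-nucleus Flag (transfection marker) means are measured on the band-passed
Flag channel; the transfection threshold is selected automatically from
their bimodal distribution.  EdU positivity uses a fixed minimum mean
intensity.  The proliferation rate is double-positive / transfected.
"""

from eduscan import (
    SimulationConfig,
    classify_cells,
    measure_channels,
    segment_nuclei,
    simulate_field,
    summarize_condition,
)

cfg = SimulationConfig(seed=7, n_cells=500)  # 40% transfected, EdU 20%/50%
channels, truth = simulate_field(cfg)
labels = segment_nuclei(channels["dapi"])
records = measure_channels(labels, channels["flag"], channels["edu"],
                           dapi_image=channels["dapi"])
classified = classify_cells(records)
summary = summarize_condition(classified, "example", is_control=False)

print(f"cells analyzed:            {summary.n_total}")
print(f"transfected:               {summary.n_transfected} "
      f"({100 * summary.n_transfected / summary.n_total:.1f}%; simulated 40%)")
print(f"transfected proliferating: {summary.n_transfected_proliferating}")
print(f"proliferation rate:        {summary.proliferation_rate:.3f} "
      f"(simulated EdU fraction among transfected: "
      f"{cfg.edu_fraction_transfected})")
# The estimated rate tracks the generative EdU probability of the
# transfected class, demonstrating single-cell recovery of the assay readout.
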