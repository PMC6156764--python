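"""Generate a synthetic three-channel field and detect its nuclei.

The generator plants ~300 round nuclei (10% as fused pairs) with known
positions; the detector runs DoG band-pass -> k-means threshold -> hybrid
watershed -> mean-intensity filter on the DAPI channel.  The printed
recovery compares detected against planted nucleus counts.
"""

from eduscan import SimulationConfig, segment_nuclei, simulate_field

cfg = SimulationConfig(seed=42)
channels, truth = simulate_field(cfg)
labels = segment_nuclei(channels["dapi"])

print(f"planted nuclei:   {truth.n_cells}")
print(f"detected nuclei:  {labels.max()}")
print(f"recovery:         {100 * labels.max() / truth.n_cells:.1f}%")
# ~100% means the detector found essentially every nucleus, including most
# deliberately fused pairs that the watershed had to split.
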