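"""The small defined quantifications: ddCt, co-IP, luciferase, spreading,
alanine-cassette mutants and the construct registry."""

import pandas as pd

from eduscan import (
    ResidueInterval,
    alanine_cassette_mutants,
    coip_normalize,
    ddct_fold_change,
    fragment_registry,
    interval_length,
    luciferase_normalize,
    spreading_classify,
)
from eduscan.assays import ProteinSequence

# Relative qPCR fold change, 2^(-ddCt) with ddCt = dCt(control) - dCt(cond)
ct = pd.DataFrame(
    [("control", "CTGF", 24.8), ("control", "CTGF", 25.2),
     ("control", "RPL37A", 20.0),
     ("treated", "CTGF", 26.5), ("treated", "RPL37A", 20.0)],
    columns=["sample", "gene", "ct"],
)
fc = ddct_fold_change(ct, "CTGF", "treated", control_condition="control")
print(f"CTGF fold change: {fc:.3f}")
# Note the subtraction order (control minus condition): a condition with a
# HIGHER Ct (less transcript) gives a fold change above 1 under this
# convention; see eduscan.assays for details.

# Co-IP densitometry: tead / (flag / igg), normalized to the positive control
rel = coip_normalize(
    [{"condition": "pos", "tead_signal": 8.0, "flag_signal": 4.0, "igg_signal": 2.0},
     {"condition": "mutant", "tead_signal": 2.0, "flag_signal": 4.0, "igg_signal": 2.0}],
    "pos",
)
print(f"relative TEAD binding, mutant: {rel['mutant']:.2f}  (1.0 = control-like)")

# Dual-luciferase reporter normalization
print(f"normalized luciferase activity: {luciferase_normalize(5400, 1800):.1f}")

# Spreading classification at the 120 um^2 cutoff
below, above = spreading_classify([80, 95, 110, 150, 180, 240])
print(f"spreading: {below:.0%} of cells at or below 120 um^2, {above:.0%} above")

# Construct registry and an alanine-cassette scan over the a9 helix
a9 = fragment_registry()["α9"]
print(f"a9 construct: residues {a9.start}-{a9.end} ({interval_length(a9)} aa)")
seq = ProteinSequence("demo", "MK" + "LVDHLFQKW" * 54)  # synthetic 488-aa protein
muts = alanine_cassette_mutants(seq, ResidueInterval(376, 424), cassette_len=7)
print(f"{len(muts)} cassette mutants; first substitutes residues 376-382:")
print("  wild type:", seq.sequence[372:386])
print("  mutant A1:", muts[0].sequence[372:386])
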