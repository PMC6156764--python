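"""Small defined quantifications around the proliferation experiments.

Covers: relative RT-qPCR fold changes (ddCt), co-immunoprecipitation
densitometry normalization, dual-luciferase normalization, spreading-area
classification, alanine-cassette mutant design and the registry of GBP-1
deletion constructs used throughout.

Sign convention for ddCt — implemented exactly as used with these data:

    dCt(condition)  = mean Ct(target) - mean Ct(reference)     per condition
    ddCt            = dCt(control) - dCt(condition)
    fold change     = 2 ** (-ddCt)

Note this subtracts in the opposite order from the more common
Livak convention (condition minus control); with this ordering a target
*down-regulated* in the condition (higher dCt) yields a fold change above 1
relative to how the common convention would report it.  The formula is kept
as-is deliberately; callers needing the other convention can negate ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ResidueInterval:
    """1-based inclusive residue interval, e.g. the a9 helix 376-424."""

    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")


def interval_length(region: ResidueInterval) -> int:
    """Number of residues in the inclusive interval."""
    return region.end - region.start + 1


# GBP-1 deletion constructs (residue numbering of NM_002053.2)
_FRAGMENTS = {
    "Glo": (1, 290),       # globular domain
    "Hel": (291, 592),     # helical domain
    "α7–11": (311, 478),
    "α7–9": (311, 424),
    "α9–11": (376, 478),
    "α12–13": (484, 582),
    "α9": (376, 424),
    "α7–13": (311, 582),
}

# ASCII lookup aliases for the greek-letter names
_ALIASES = {
    "a7-11": "α7–11", "a7-9": "α7–9", "a9-11": "α9–11",
    "a12-13": "α12–13", "a9": "α9", "a7-13": "α7–13",
    "glo": "Glo", "hel": "Hel",
    "α7-11": "α7–11", "α7-9": "α7–9", "α9-11": "α9–11",
    "α12-13": "α12–13", "α7-13": "α7–13",
}


def fragment_registry() -> dict[str, ResidueInterval]:
    """The eight named GBP-1 constructs as residue intervals."""
    return {
        name: ResidueInterval(s, e, name) for name, (s, e) in _FRAGMENTS.items()
    }


def lookup_fragment(name: str) -> ResidueInterval:
    """Find a construct by name; ASCII aliases like ``a9`` are accepted."""
    reg = fragment_registry()
    if name in reg:
        return reg[name]
    key = _ALIASES.get(name) or _ALIASES.get(name.lower())
    if key in reg:
        return reg[key]
    raise KeyError(f"unknown fragment {name!r}; known: {sorted(reg)}")


def ddct_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    condition: str,
    reference_gene: str = "RPL37A",
    control_condition: str = "control",
) -> float:
    """Relative expression fold change, 2**(-ddCt).

    ``table`` has columns ``sample`` (condition), ``gene`` and ``ct``; Ct
    replicates are aggregated by arithmetic mean per (sample, gene).
    """
    df = table.copy()
    required = {"sample", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.all(np.isfinite(df["ct"])):
        raise ValueError("Ct values must be finite")
    means = df.groupby(["sample", "gene"])["ct"].mean()

    def dct(cond: str) -> float:
        try:
            tgt = means[(cond, target_gene)]
        except KeyError:
            raise ValueError(f"no Ct for target {target_gene!r} in {cond!r}") from None
        try:
            ref = means[(cond, reference_gene)]
        except KeyError:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for {cond!r}"
            ) from None
        return float(tgt - ref)

    ddct = dct(control_condition) - dct(condition)
    return float(2.0 ** (-ddct))


def coip_normalize(records, positive_control_condition: str) -> dict[str, float]:
    """Relative TEAD binding from band densitometry.

    Each record has ``tead_signal``, ``flag_signal``, ``igg_signal`` and a
    ``condition`` label.  Raw binding = tead / (flag / igg); the returned
    value is raw binding normalized to the positive control.  Records are
    mappings or objects with those attributes.
    """

    def get(r, k):
        return r[k] if isinstance(r, dict) else getattr(r, k)

    raw: dict[str, float] = {}
    for r in records:
        tead = float(get(r, "tead_signal"))
        flag = float(get(r, "flag_signal"))
        igg = float(get(r, "igg_signal"))
        if flag <= 0 or igg <= 0:
            raise ValueError(
                f"non-positive flag/igg signal for condition {get(r, 'condition')!r}"
            )
        raw[get(r, "condition")] = tead / (flag / igg)
    if positive_control_condition not in raw:
        raise ValueError(
            f"positive control {positive_control_condition!r} not among records"
        )
    ref = raw[positive_control_condition]
    return {cond: v / ref for cond, v in raw.items()}


def luciferase_normalize(firefly: float, renilla: float) -> float:
    """Firefly reporter activity normalized to the Renilla internal control."""
    if renilla <= 0:
        raise ValueError(f"Renilla activity must be > 0, got {renilla}")
    return firefly / renilla


def spreading_classify(areas, cutoff: float = 120.0) -> tuple[float, float]:
    """Fractions of cells with surface area at-or-below / above ``cutoff``
    (um^2).  Ties at the cutoff count as "below"."""
    a = np.asarray(list(areas), dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty area list")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    below = float(np.mean(a <= cutoff))
    return below, 1.0 - below


@dataclass(frozen=True)
class ProteinSequence:
    """Named one-letter amino-acid sequence (standard 20-letter alphabet)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"non-standard residues in {self.name!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def alanine_cassette_mutants(
    seq: ProteinSequence, region: ResidueInterval, cassette_len: int = 7
) -> list[ProteinSequence]:
    """Tile ``region`` with consecutive all-alanine cassettes.

    Mutant i (1-based) replaces residues
    ``[region.start + (i-1)*L, region.start + i*L - 1]`` with alanines and
    leaves all other residues unchanged.  The region length must divide
    evenly into cassettes (the canonical a9 scan is 49 residues in 7
    cassettes of 7).
    """
    if cassette_len < 1:
        raise ValueError("cassette_len must be >= 1")
    if region.end > len(seq):
        raise ValueError(
            f"region {region.start}-{region.end} exceeds sequence length {len(seq)}"
        )
    n = interval_length(region)
    if n % cassette_len != 0:
        raise ValueError(
            f"region length {n} is not divisible by cassette length {cassette_len}"
        )
    mutants = []
    s = seq.sequence
    for i in range(n // cassette_len):
        a = region.start - 1 + i * cassette_len  # 0-based slice start
        b = a + cassette_len
        mutated = s[:a] + "A" * cassette_len + s[b:]
        mutants.append(ProteinSequence(f"{seq.name}_A{i + 1}", mutated))
    return mutants


# ---------------------------------------------------------------- file I/O


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """CSV with columns sample, gene, ct (one row per replicate)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_densitometry(path: str | Path) -> list[dict]:
    """CSV with columns condition, tead_signal, flag_signal, igg_signal."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return df.to_dict("records")


def read_areas(path: str | Path) -> np.ndarray:
    """One area per line, or a CSV with an ``area`` column."""
    p = Path(path)
    text = p.read_text()
    if "," in text.splitlines()[0] or text.lower().startswith("area"):
        df = pd.read_csv(p)
        col = [c for c in df.columns if c.strip().lower().startswith("area")][0]
        return df[col].to_numpy(dtype=float)
    return np.array([float(x) for x in text.split()], dtype=float)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    return [
        ProteinSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, seqs) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def registry_to_csv(path: str | Path) -> None:
    """Export the construct registry as CSV (name, start, end, length)."""
    rows = [
        {"name": n, "start": iv.start, "end": iv.end, "length": interval_length(iv)}
        for n, iv in fragment_registry().items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
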