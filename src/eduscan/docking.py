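"""Post-docking contact analysis of rigid-body model coordinates.

Given docking-model coordinate sets (PDB files, one ligand pose per model)
and a receptor, this module measures the minimum atomic distance from each
model to a reference residue stretch of the receptor (by default residues
376-382, the N-terminal motif of the GBP-1 a9 helix) and counts the models
whose minimum distance falls strictly below a cutoff (default 10 Angstrom).
All atoms participate in the distances by default; a Calpha-only mode is
available.  Running a docking engine is out of scope — only model
coordinates are analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from eduscan.assays import ResidueInterval


@dataclass
class AtomSet:
    """Atom coordinates with residue bookkeeping (distances in Angstrom)."""

    residue_index: np.ndarray  # int, per atom
    residue_name: np.ndarray  # str, per atom
    atom_name: np.ndarray  # str, per atom
    coords: np.ndarray  # (n, 3) float
    chain: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.coords) and np.any(self.residue_index <= 0):
            raise ValueError("residue indices must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    def restrict(self, interval: ResidueInterval) -> "AtomSet":
        """Atoms whose residue index lies in the inclusive interval."""
        keep = (self.residue_index >= interval.start) & (
            self.residue_index <= interval.end
        )
        if not keep.any():
            raise ValueError(
                f"no atoms in residue interval {interval.start}-{interval.end}"
            )
        return AtomSet(
            self.residue_index[keep],
            self.residue_name[keep],
            self.atom_name[keep],
            self.coords[keep],
            self.chain,
        )

    def ca_only(self) -> "AtomSet":
        keep = self.atom_name == "CA"
        if not keep.any():
            raise ValueError("no Calpha atoms present")
        return AtomSet(
            self.residue_index[keep],
            self.residue_name[keep],
            self.atom_name[keep],
            self.coords[keep],
            self.chain,
        )


@dataclass
class ContactParams:
    """Contact definition: strict distance cutoff to a reference interval."""

    cutoff: float = 10.0
    reference_interval: ResidueInterval = field(
        default_factory=lambda: ResidueInterval(376, 382, "VDHLFQK")
    )

    def validate(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")


def read_pdb_atoms(
    path: str | Path, chain: str | None = None, include_hetatm: bool = False
) -> AtomSet:
    """Parse ATOM records from a PDB file into an :class:`AtomSet`.

    Missing occupancy/B-factor columns are tolerated; HETATM records are
    excluded unless requested; altloc variants other than '' or 'A' are
    dropped.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tolerate sparse header/column info
        structure = PDBParser(QUIET=True, PERMISSIVE=True).get_structure(
            Path(path).stem, str(path)
        )
    res_idx, res_name, at_name, coords = [], [], [], []
    chains_seen = set()
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for residue in ch:
                hetflag = residue.id[0].strip()
                if hetflag and not include_hetatm:
                    continue
                for atom in residue:
                    if atom.get_altloc() not in (" ", "", "A"):
                        continue
                    res_idx.append(residue.id[1])
                    res_name.append(residue.get_resname())
                    at_name.append(atom.get_name())
                    coords.append(atom.coord)
                    chains_seen.add(ch.id)
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return AtomSet(
        np.array(res_idx),
        np.array(res_name, dtype=object),
        np.array(at_name, dtype=object),
        np.array(coords, dtype=np.float64),
        chain="".join(sorted(chains_seen)),
    )


def min_distance(a: AtomSet, b: AtomSet) -> float:
    """Minimum Euclidean distance (Angstrom) over all atom pairs."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both atom sets must be non-empty")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    tree = cKDTree(large.coords)
    d, _ = tree.query(small.coords, k=1)
    return float(np.min(d))


def model_distances(
    models, receptor_reference: AtomSet, ca_only: bool = False
) -> pd.DataFrame:
    """Per-model minimum distance to the reference atoms."""
    rows = []
    for i, m in enumerate(models, start=1):
        mm = m.ca_only() if ca_only else m
        rows.append({"model": i, "min_distance": min_distance(mm, receptor_reference)})
    return pd.DataFrame(rows)


def count_contact_models(
    models, receptor_reference: AtomSet, params: ContactParams | None = None,
    ca_only: bool = False,
) -> int:
    """Number of models whose minimum distance to the reference region is
    strictly below the cutoff."""
    params = params or ContactParams()
    params.validate()
    if not models:
        raise ValueError("no models supplied")
    d = model_distances(models, receptor_reference, ca_only=ca_only)
    return int((d["min_distance"] < params.cutoff).sum())
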