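"""Structurally-corrected solubility profiles and aggregation hotspots.

A low intrinsic profile value only drives self-association if the residue
is accessible on the protein surface.  The structural correction therefore
re-weights the sequence-based profile by per-residue relative solvent
exposure and smooths it over spatial neighbours:

    C_i = r_i * < S_j >_{j : |CA_j - CA_i| <= cutoff}

where r_i in [0, 1] is the solvent-accessible surface area of residue i
normalized by its maximal accessibility in an extended reference
tripeptide, and the neighbour average is distance-weighted with
w_ij = 1 - d_ij / cutoff (the residue itself enters with weight 1).
Buried residues (r_i = 0) get C_i = 0; solvent-exposed clusters of
low-S_i residues stand out as minima of C — candidate aggregation
hotspots.  In the cutoff -> 0 limit with all r_i = 1, C reduces to the
intrinsic profile.

Hotspot ranking sorts exposed residues ascending by C_i, optionally
restricted to positions that differ from a reference variant and/or to
hydrophobic residue types — mirroring how self-association sites found by
structural proteomics are narrowed down to mutable candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .profiles import HYDROPHOBIC_SET, SolubilityProfile

#: Maximal accessible surface area per residue (A^2) in an extended
#: Gly-X-Gly reference tripeptide (theoretical values, Tien et al. 2013).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class StructureModel:
    """Heavy-atom structure with per-residue bookkeeping.

    Wraps a biotite AtomArray (first model, highest-occupancy altlocs,
    hydrogens removed) and exposes per-residue arrays: chain id, residue
    id (author numbering, insertion codes appended), one-letter type, and
    CA coordinates (NaN where the CA atom is missing).
    """

    atoms: struc.AtomArray
    chain_ids: np.ndarray = field(init=False)
    res_ids: np.ndarray = field(init=False)
    sequence: str = field(init=False)
    ca_coords: np.ndarray = field(init=False)

    def __post_init__(self):
        atoms = self.atoms
        if atoms.array_length() == 0:
            raise ValueError("empty structure model")
        if not np.all(np.isfinite(atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")
        starts = struc.get_residue_starts(atoms)
        self.chain_ids = atoms.chain_id[starts]
        ins = (
            atoms.ins_code[starts]
            if "ins_code" in atoms.get_annotation_categories()
            else np.array([""] * len(starts))
        )
        self.res_ids = np.array(
            [f"{r}{i}" for r, i in zip(atoms.res_id[starts], ins)]
        )
        letters = []
        for name in atoms.res_name[starts]:
            if name not in _THREE_TO_ONE:
                raise ValueError(f"non-standard residue {name!r} in model")
            letters.append(_THREE_TO_ONE[name])
        self.sequence = "".join(letters)
        ca = np.full((len(starts), 3), np.nan)
        seg_bounds = np.append(starts, atoms.array_length())
        for k in range(len(starts)):
            seg = slice(seg_bounds[k], seg_bounds[k + 1])
            is_ca = atoms.atom_name[seg] == "CA"
            if is_ca.any():
                ca[k] = atoms.coord[seg][is_ca][0]
            else:
                ca[k] = atoms.coord[seg].mean(axis=0)
        self.ca_coords = ca

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def residue_labels(self) -> list[str]:
        """Chain-qualified labels like 'A:W30'."""
        return [
            f"{c}:{aa}{rid}"
            for c, aa, rid in zip(self.chain_ids, self.sequence, self.res_ids)
        ]


def load_structure(path: str | Path) -> StructureModel:
    """Load a PDB file (first model; altlocs resolved to highest occupancy;
    hydrogens and non-amino-acid entities dropped)."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    atoms = atoms[atoms.element != "H"]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no amino-acid atoms found")
    return StructureModel(atoms=atoms)


def write_structure(model: StructureModel, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


def relative_exposure(
    model: StructureModel, probe: float = 1.4, point_number: int = 500
) -> np.ndarray:
    """Per-residue relative solvent exposure r_i in [0, 1].

    Shrake-Rupley sphere sampling of the solvent-accessible surface,
    summed per residue and normalized by the residue type's maximal
    accessibility; clamped to [0, 1].  Residues with missing heavy atoms
    still get an estimate from the atoms present (the value is then a
    lower bound).
    """
    atom_sasa = struc.sasa(
        model.atoms, probe_radius=probe, point_number=point_number
    )
    atom_sasa = np.nan_to_num(atom_sasa, nan=0.0)
    starts = struc.get_residue_starts(model.atoms)
    bounds = np.append(starts, model.atoms.array_length())
    r = np.empty(model.n_residues)
    for k in range(model.n_residues):
        total = atom_sasa[bounds[k] : bounds[k + 1]].sum()
        r[k] = min(total / MAX_ASA[model.sequence[k]], 1.0)
    return r


@dataclass(frozen=True)
class StructuralProfile:
    """Per-residue intrinsic values, relative exposure, and corrected values."""

    labels: list
    intrinsic: np.ndarray = field(repr=False)
    exposure: np.ndarray = field(repr=False)
    corrected: np.ndarray = field(repr=False)
    sequence: str = ""

    def __post_init__(self):
        n = len(self.labels)
        if not (len(self.intrinsic) == len(self.exposure) == len(self.corrected) == n):
            raise ValueError("profile component lengths must match")
        if np.any((self.exposure < 0) | (self.exposure > 1)):
            raise ValueError("relative exposure must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        """Per-residue table (label, intrinsic, exposure, corrected) — the
        (label, corrected) pairs are suitable for structure-viewer colouring."""
        with open(path, "w") as fh:
            fh.write("residue\tintrinsic\texposure\tcorrected\n")
            for lab, s, r, c in zip(
                self.labels, self.intrinsic, self.exposure, self.corrected
            ):
                fh.write(f"{lab}\t{s:.6f}\t{r:.4f}\t{c:.6f}\n")


def corrected_profile(
    profile: SolubilityProfile,
    model: StructureModel,
    cutoff: float = 8.0,
    exposure: np.ndarray | None = None,
    probe: float = 1.4,
) -> StructuralProfile:
    """Exposure-weighted, spatially smoothed solubility profile.

    `profile` and `model` must describe the same residues in the same
    order.  `exposure` may be precomputed (e.g. to reuse across cutoffs);
    otherwise it is derived from the model.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(profile) != model.n_residues:
        raise ValueError(
            f"profile length {len(profile)} != model residues {model.n_residues}"
        )
    if profile.sequence != model.sequence:
        raise ValueError("profile sequence does not match model sequence")
    r = relative_exposure(model, probe=probe) if exposure is None else np.asarray(exposure, float)
    s = profile.values
    ca = model.ca_coords
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    w = np.clip(1.0 - d / cutoff, 0.0, None)
    w[d >= cutoff] = 0.0
    np.fill_diagonal(w, 1.0)
    smoothed = (w @ s) / w.sum(axis=1)
    return StructuralProfile(
        labels=model.residue_labels(),
        intrinsic=s.copy(),
        exposure=r,
        corrected=r * smoothed,
        sequence=model.sequence,
    )


@dataclass(frozen=True)
class HotspotReport:
    """Residues ranked ascending by corrected score (lowest = strongest
    aggregation candidate), with the filters that produced the list."""

    entries: list  # (label, corrected, exposure, differs_flag)
    min_exposure: float
    hydrophobic_only: bool
    n_filtered_out: int

    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]


def rank_hotspots(
    sp: StructuralProfile,
    differing: set | None = None,
    min_exposure: float = 0.2,
    hydrophobic_only: bool = False,
    hydrophobic: frozenset = HYDROPHOBIC_SET,
) -> HotspotReport:
    """Rank candidate aggregation hotspots on a structural profile.

    Restricts to residues in `differing` (when given, labels as produced
    by :meth:`StructureModel.residue_labels`), with exposure >=
    `min_exposure`, optionally to hydrophobic types; sorts ascending by
    corrected value.  An empty result after filtering is reported, not
    fatal.
    """
    entries = []
    dropped = 0
    for k, label in enumerate(sp.labels):
        differs = differing is None or label in differing
        if not differs:
            dropped += 1
            continue
        if sp.exposure[k] < min_exposure:
            dropped += 1
            continue
        if hydrophobic_only and sp.sequence and sp.sequence[k] not in hydrophobic:
            dropped += 1
            continue
        entries.append(
            (label, float(sp.corrected[k]), float(sp.exposure[k]),
             differing is not None)
        )
    entries.sort(key=lambda e: e[1])
    return HotspotReport(
        entries=entries,
        min_exposure=min_exposure,
        hydrophobic_only=hydrophobic_only,
        n_filtered_out=dropped,
    )
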