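"""Distance-shell annotation of residues around a bound ligand and metal.

Residues of a model structure are classed by the minimum distance of any
of their (heavy) atoms to any atom of a ligand group: shells A/B/C at
5/6/7 Angstrom by default, the innermost applicable shell winning.  A
single-atom hetero group is treated as a (divalent) metal ion and probed
for first-sphere coordination by O/N/S donors; basic side chains near the
ligand's phosphate oxygens are reported as salt bridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .formats import Residue, Structure
from .motifs import MotifHit

BASIC_SIDE_CHAIN_N = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}


@dataclass(frozen=True)
class ContactShellConfig:
    """Distance shells (ascending radii, one label each)."""

    radii: tuple[float, ...] = (5.0, 6.0, 7.0)
    labels: tuple[str, ...] = ("A", "B", "C")
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.labels):
            raise ValueError("one label per radius required")
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly ascending")


@dataclass
class ResidueContact:
    chain: str
    number: int
    name: str
    min_distance: float
    shell: str | None  # innermost applicable label, or None beyond the last radius


@dataclass
class MetalSite:
    ion_name: str
    cutoff: float
    coordinating: list[tuple[str, int, str, str, float]] = field(default_factory=list)
    # (chain, resnum, resname, donor atom name, distance)

    def residue_numbers(self) -> set[int]:
        return {num for _, num, _, _, _ in self.coordinating}


@dataclass
class SaltBridge:
    chain: str
    number: int
    name: str
    basic_atom: str
    phosphate_atom: str
    distance: float


def _coords(residues: list[Residue], heavy_only: bool) -> np.ndarray:
    pts = [
        (a.x, a.y, a.z)
        for r in residues
        for a in r.atoms
        if not (heavy_only and a.is_hydrogen)
    ]
    return np.array(pts).reshape(-1, 3)


def min_distances(
    structure: Structure,
    ligand_selection: list[Residue],
    heavy_atoms_only: bool = True,
) -> dict[tuple[str, int], float]:
    """Per protein residue, the minimum atom-atom distance to the ligand.

    Keys are (chain, residue number).  Hydrogens are excluded when
    ``heavy_atoms_only`` is set.
    """
    lig = _coords(ligand_selection, heavy_atoms_only)
    if lig.size == 0:
        raise ValueError("empty ligand selection")
    out: dict[tuple[str, int], float] = {}
    for res in structure.protein_residues:
        pts = _coords([res], heavy_atoms_only)
        if pts.size == 0:
            continue
        out[(res.chain, res.number)] = float(cdist(pts, lig).min())
    return out


def classify_shells(
    distances: dict[tuple[str, int], float],
    structure: Structure,
    config: ContactShellConfig = ContactShellConfig(),
) -> list[ResidueContact]:
    """Assign each residue the innermost shell whose radius covers its
    minimum ligand distance (inclusive boundaries: d <= radius)."""
    names = {(r.chain, r.number): r.name for r in structure.protein_residues}
    contacts = []
    for key, d in distances.items():
        shell = None
        for radius, label in zip(config.radii, config.labels):
            if d <= radius:
                shell = label
                break
        contacts.append(ResidueContact(key[0], key[1], names.get(key, "UNK"), d, shell))
    return contacts


def _single_atom_ion(structure: Structure, ion_name: str | None) -> Residue:
    ions = [
        r for r in structure.hetero_residues
        if len(r.atoms) == 1 and (ion_name is None or r.name == ion_name)
    ]
    if not ions:
        raise ValueError(f"no single-atom ion{f' {ion_name!r}' if ion_name else ''} found")
    if len(ions) > 1:
        raise ValueError("more than one candidate ion; pass ion_name")
    return ions[0]


def detect_coordination(
    structure: Structure,
    ion_name: str | None = None,
    cutoff: float = 3.0,
) -> MetalSite:
    """Residues donating an O/N/S atom within ``cutoff`` of the metal ion.

    The ion is any single-atom hetero group (its chemical identity does
    not enter the geometry); ``ion_name`` disambiguates when several are
    present.
    """
    ion = _single_atom_ion(structure, ion_name)
    ion_xyz = np.array([[ion.atoms[0].x, ion.atoms[0].y, ion.atoms[0].z]])
    site = MetalSite(ion_name=ion.name, cutoff=cutoff)
    for res in structure.protein_residues:
        for atom in res.atoms:
            if atom.element.upper() not in ("O", "N", "S"):
                continue
            d = float(cdist([[atom.x, atom.y, atom.z]], ion_xyz)[0, 0])
            if d <= cutoff:
                site.coordinating.append(
                    (res.chain, res.number, res.name, atom.name, d)
                )
    site.coordinating.sort(key=lambda t: t[4])
    return site


def detect_salt_bridges(
    structure: Structure,
    ligand_selection: list[Residue],
    cutoff: float = 4.0,
) -> list[SaltBridge]:
    """Basic side-chain nitrogens within ``cutoff`` of ligand phosphate
    oxygens.

    Phosphate oxygens are selected by atom-name convention (an O name
    carrying a P, e.g. O1P/OP1); no bonded context is required.
    """
    phos = [
        a for r in ligand_selection for a in r.atoms
        if a.element.upper() == "O" and a.name.upper().startswith("O")
        and "P" in a.name.upper()
    ]
    bridges: list[SaltBridge] = []
    if not phos:
        return bridges
    for res in structure.protein_residues:
        basic_atoms = BASIC_SIDE_CHAIN_N.get(res.name)
        if not basic_atoms:
            continue
        for atom in res.atoms:
            if atom.name not in basic_atoms:
                continue
            for po in phos:
                d = float(np.hypot(
                    np.hypot(atom.x - po.x, atom.y - po.y), atom.z - po.z
                ))
                if d <= cutoff:
                    bridges.append(SaltBridge(
                        res.chain, res.number, res.name, atom.name, po.name, d
                    ))
    bridges.sort(key=lambda b: (b.number, b.distance))
    return bridges


def shell_report(
    contacts: list[ResidueContact],
    motif_hits: list[MotifHit],
    seq_id: str,
    chain: str | None = None,
) -> pd.DataFrame:
    """Binding-site table: motif residues with their shell subscripts.

    Motif positions of ``seq_id`` are resolved against structure residue
    numbering (assumed to share the sequence numbering, as in a model
    built for that sequence).  Unmapped residues are an error naming
    them.
    """
    by_number: dict[int, ResidueContact] = {}
    for c in contacts:
        if chain is None or c.chain == chain:
            by_number[c.number] = c
    rows = []
    unmapped = []
    for hit in motif_hits:
        if seq_id not in hit.per_seq:
            continue
        start, frag = hit.per_seq[seq_id]
        for offset, ch in enumerate(frag):
            pos = start + offset
            contact = by_number.get(pos)
            if contact is None:
                unmapped.append(f"{hit.pattern_name}:{ch}{pos}")
                continue
            rows.append({
                "motif": hit.pattern_name,
                "residue": f"{ch}{pos}",
                "position": pos,
                "resname": contact.name,
                "min_distance": round(contact.min_distance, 3),
                "shell": contact.shell if contact.shell is not None else "none",
            })
    if unmapped:
        raise ValueError(
            "motif residues not present in structure numbering: "
            + ", ".join(unmapped)
        )
    return pd.DataFrame(
        rows,
        columns=["motif", "residue", "position", "resname", "min_distance", "shell"],
    )


def contacts_table(contacts: list[ResidueContact]) -> pd.DataFrame:
    rows = [{
        "chain": c.chain, "resnum": c.number, "resname": c.name,
        "min_dist": round(c.min_distance, 3),
        "shell": c.shell if c.shell is not None else "none",
    } for c in sorted(contacts, key=lambda c: (c.chain, c.number))]
    return pd.DataFrame(rows, columns=["chain", "resnum", "resname", "min_dist", "shell"])
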