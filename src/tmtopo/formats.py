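"""Readers/writers for the standard formats the pipeline touches.

Conventions shared by the whole package:

* residue positions are 1-based inclusive everywhere; the only 0-based
  half-open coordinates appear in the optional BED export of the CLI;
* sequences are upper-case strings over the 20 amino-acid letters plus
  ``X`` for unknown residues;
* alignments keep row order and must degap back to their source sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
from Bio import AlignIO, SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# sequences


@dataclass
class Sequence:
    """A protein sequence with 1-based residue positions."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in AA_ALPHABET:
                raise FormatError(
                    f"illegal residue {ch!r} at position {i} of record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Residues are upper-cased and ``*`` stop/terminator characters stripped.
    An empty file or an illegal residue character is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        residues = str(rec.seq).upper().replace("*", "")
        out.append(Sequence(id=rec.id, residues=residues, description=desc))
    return out


def write_fasta(sequences: list[Sequence], path, width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for seq in sequences:
            header = f">{seq.id} {seq.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """A gapped multiple alignment; rows are (sequence id, gapped string)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        n = len(self.rows[0][1])
        for sid, gapped in self.rows:
            if len(gapped) != n:
                raise FormatError(
                    f"alignment row {sid!r} has length {len(gapped)}, expected {n}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        for sid, gapped in self.rows:
            if sid == seq_id:
                return gapped
        raise KeyError(f"no alignment row {seq_id!r}")

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def position_of_column(self, seq_id: str) -> list[int]:
        """Per column (0-indexed list), the 1-based residue position of this
        row at that column, or 0 where the row has a gap."""
        out = []
        pos = 0
        for ch in self.row(seq_id):
            if ch == GAP:
                out.append(0)
            else:
                pos += 1
                out.append(pos)
        return out

    def column_of_position(self, seq_id: str, position: int) -> int:
        """1-based alignment column holding 1-based residue ``position``."""
        pos = 0
        for col, ch in enumerate(self.row(seq_id), start=1):
            if ch != GAP:
                pos += 1
                if pos == position:
                    return col
        raise IndexError(
            f"position {position} beyond degapped length of {seq_id!r}"
        )

    def gap_fraction(self, column: int) -> float:
        """Gap fraction of a 1-based column."""
        col = [gapped[column - 1] for _, gapped in self.rows]
        return col.count(GAP) / len(col)

    def column(self, column: int) -> list[str]:
        return [gapped[column - 1] for _, gapped in self.rows]


def read_alignment(path, dialect: str = "fasta") -> Alignment:
    """Read an alignment in aligned-FASTA or Clustal dialect."""
    if dialect not in ("fasta", "clustal"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if dialect == "fasta":
        # parse row by row so a ragged file names the offending record
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise FormatError(f"no alignment rows in {path}")
        rows = [(rec.id, str(rec.seq).upper()) for rec in records]
        return Alignment(rows=rows)
    aln = AlignIO.read(str(path), "clustal")
    return Alignment(rows=[(rec.id, str(rec.seq).upper()) for rec in aln])


def write_alignment(alignment: Alignment, path, dialect: str = "fasta") -> None:
    if dialect == "fasta":
        with open(path, "w") as fh:
            for sid, gapped in alignment.rows:
                fh.write(f">{sid}\n")
                for i in range(0, len(gapped), 60):
                    fh.write(gapped[i:i + 60] + "\n")
        return
    if dialect == "clustal":
        with open(path, "w") as fh:
            fh.write("CLUSTAL W multiple sequence alignment\n\n")
            width = 60
            n = alignment.n_columns
            for start in range(0, n, width):
                for sid, gapped in alignment.rows:
                    fh.write(f"{sid:<20} {gapped[start:start + width]}\n")
                fh.write("\n")
        return
    raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# structures


@dataclass
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not self.element:
            raise FormatError(f"atom {self.name!r} has empty element field")
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise FormatError(f"atom {self.name!r} has non-finite coordinate")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom]
    hetero: bool = False


@dataclass
class Structure:
    """Protein residues plus hetero (ligand/ion) groups from one model."""

    residues: list[Residue] = field(default_factory=list)

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.hetero]

    @property
    def hetero_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.hetero]

    def ligand_group(self, name: str) -> list[Residue]:
        """All hetero residues with the given residue name (e.g. 'DPM')."""
        return [r for r in self.residues if r.hetero and r.name == name]


def read_structure(path) -> Structure:
    """Read a PDB file (ATOM + HETATM) into a :class:`Structure`.

    Protein and hetero groups are separated by the PDB record type;
    hydrogens are retained (flagged through :attr:`Atom.is_hydrogen`).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    residues: list[Residue] = []
    for model in st:
        for chain in model:
            for res in chain:
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        x=a.pos.x,
                        y=a.pos.y,
                        z=a.pos.z,
                    )
                    for a in res
                ]
                residues.append(
                    Residue(
                        chain=chain.name,
                        number=res.seqid.num,
                        name=res.name,
                        atoms=atoms,
                        hetero=(res.het_flag == "H"),
                    )
                )
        break  # first model only
    struct = Structure(residues=residues)
    if not struct.protein_residues:
        raise FormatError(f"no ATOM records in {path}")
    return struct


def write_structure(structure: Structure, path) -> None:
    """Write a :class:`Structure` as PDB (coordinates kept to 3 decimals)."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, " ")
        gres.het_flag = "H" if res.hetero else "A"
        for atom in res.atoms:
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element)
            ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
            gres.add_atom(ga)
        chains[res.chain].add_residue(gres)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# annotation tracks


@dataclass
class AnnotationTrack:
    """Labelled 1-based inclusive intervals on named sequences."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sid, start, end, label in self.intervals:
            if start > end:
                raise FormatError(
                    f"interval {label!r} on {sid!r}: start {start} > end {end}"
                )
            if start < 1:
                raise FormatError(f"interval {label!r} on {sid!r}: start < 1")

    def validate_against(self, sequences: list[Sequence]) -> None:
        lengths = {s.id: len(s) for s in sequences}
        for sid, start, end, label in self.intervals:
            if sid in lengths and end > lengths[sid]:
                raise FormatError(
                    f"interval {label!r} on {sid!r} ends at {end}, "
                    f"past sequence length {lengths[sid]}"
                )

    def for_sequence(self, seq_id: str) -> list[tuple[int, int, str]]:
        return [(s, e, lab) for sid, s, e, lab in self.intervals if sid == seq_id]


def read_annotation_tsv(path) -> AnnotationTrack:
    """Read a TSV track with columns seq_id, start, end, label."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "seq_id":
                continue
            if len(parts) < 4:
                raise FormatError(f"annotation row has {len(parts)} columns: {line!r}")
            intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return AnnotationTrack(intervals=intervals)


def write_annotation_tsv(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tlabel\n")
        for sid, start, end, label in track.intervals:
            fh.write(f"{sid}\t{start}\t{end}\t{label}\n")
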