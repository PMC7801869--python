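"""Ground-truth-labelled synthetic inputs for every pipeline stage.

The generator emulates the architecture of a polytopic ER membrane
protein family: hydrophobic ~20-residue TM blocks sprinkled with polar
residues, polar loops, short strictly conserved motifs embedded in named
lumenal loops, and a toy CA-level helix-bundle structure with a ligand
and a metal ion planted at known distances from named residues.  Families
are evolved from a root by per-site substitution and loop-only indels,
and the alignment is reconstructed from the simulation history, so the
truth (TM intervals, motif sites, sidedness) is exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .consensus import CYTO, LUMEN, TopologyModel, _label_loops
from .formats import Alignment, Atom, Residue, Sequence, Structure

# Residue sampling distributions.  TM residues are I/L/V/F/A/M-rich with a
# small tail of borderline residues; loops are enriched in polar/charged
# residues plus the helix breakers P and G.  The gap between the two
# distributions' expected Kyte-Doolittle values (~ +2.9 vs ~ -2.2) leaves
# a clear margin around the default window-caller cutoff of 1.0, so that
# noise-free recovery is a property of the construction.
TM_DIST = {
    "I": 0.18, "L": 0.22, "V": 0.16, "F": 0.12, "A": 0.14, "M": 0.06,
    "G": 0.024, "S": 0.024, "T": 0.024, "W": 0.024, "Y": 0.024,
}
LOOP_DIST = {
    "D": 0.09, "E": 0.09, "K": 0.09, "R": 0.09, "N": 0.09, "Q": 0.09,
    "S": 0.09, "T": 0.09, "P": 0.09, "G": 0.09,
    "A": 0.01, "C": 0.01, "F": 0.01, "H": 0.01, "I": 0.01,
    "L": 0.01, "M": 0.01, "V": 0.01, "W": 0.01, "Y": 0.01,
}
POLAR_SPRINKLE = "DENQKRST"


def _sample(dist: dict[str, float], rng: np.random.Generator, n: int = 1) -> list[str]:
    letters = list(dist)
    p = np.array([dist[ch] for ch in letters])
    p = p / p.sum()
    return list(rng.choice(letters, size=n, p=p))


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class SegmentSpec:
    kind: str  # "tm" | "loop"
    length: tuple[int, int]  # inclusive sampling range


@dataclass(frozen=True)
class TopologySpec:
    """Alternating loop/TM architecture with a known N-terminus side."""

    segments: tuple[SegmentSpec, ...]
    n_term_side: str = CYTO

    def __post_init__(self) -> None:
        if self.n_term_side not in (CYTO, LUMEN):
            raise ValueError("n_term_side must be cytoplasmic or lumenal")
        if not self.segments:
            raise ValueError("spec needs segments")
        if self.segments[0].kind != "loop" or self.segments[-1].kind != "loop":
            raise ValueError("spec must start and end with a loop (terminal tails)")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.kind == b.kind:
                raise ValueError("segment kinds must alternate")
        for seg in self.segments:
            if seg.kind == "tm" and not (15 <= seg.length[0] <= seg.length[1] <= 30):
                raise ValueError("TM lengths must lie within [15, 30]")

    @property
    def n_tm(self) -> int:
        return sum(1 for s in self.segments if s.kind == "tm")

    def loop_names(self) -> list[str]:
        """Names of loop segments in order (NTERM, EL1/CL1..., CTERM)."""
        loops = _label_loops(self.n_tm, self.n_term_side)
        return [lp.name for lp in loops]


def spec_for_n_tm(
    n_tm: int,
    tm_len: tuple[int, int] = (18, 26),
    internal_loop: tuple[int, int] = (12, 25),
    terminal_loop: tuple[int, int] = (15, 30),
    n_term_side: str = CYTO,
) -> TopologySpec:
    """A standard alternating spec: terminal loop, n_tm TMs, terminal loop."""
    if n_tm < 1:
        raise ValueError("need at least one TM")
    segs: list[SegmentSpec] = [SegmentSpec("loop", terminal_loop)]
    for i in range(n_tm):
        segs.append(SegmentSpec("tm", tm_len))
        segs.append(SegmentSpec(
            "loop", internal_loop if i < n_tm - 1 else terminal_loop
        ))
    return TopologySpec(segments=tuple(segs), n_term_side=n_term_side)


@dataclass(frozen=True)
class MotifPlanting:
    """Plant ``text`` verbatim at ``offset`` (0-based) inside a named loop."""

    text: str
    loop_name: str  # e.g. "EL1"
    offset: int = 2


@dataclass(frozen=True)
class FamilySimConfig:
    n_sequences: int = 6
    substitution_prob: float = 0.05
    sprinkle_prob: float = 0.1  # polar residues sprinkled into TMs
    indel_rate: float = 0.2  # per loop per derived sequence
    motifs: tuple[MotifPlanting, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.substitution_prob, self.sprinkle_prob, self.indel_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# ground truth bookkeeping


@dataclass
class Site:
    """One root-sequence site with its architectural labels."""

    segment_index: int
    kind: str  # "tm" | "loop"
    residue: str
    is_motif: bool = False


@dataclass
class GroundTruth:
    """Exact per-sequence truth carried alongside generated data."""

    tm_intervals: list[tuple[int, int]]
    loops: list[tuple[str, int, int, str]]  # (name, start, end, side)
    motif_positions: dict[str, list[int]]  # motif text -> 1-based positions
    n_term_side: str

    @property
    def n_tm(self) -> int:
        return len(self.tm_intervals)


def _truth_from_sites(sites: list[Site], spec: TopologySpec,
                      plantings: tuple[MotifPlanting, ...]) -> GroundTruth:
    loops_meta = _label_loops(spec.n_tm, spec.n_term_side)
    tm_intervals: list[tuple[int, int]] = []
    loop_spans: dict[int, tuple[int, int]] = {}
    cur_seg, seg_start = None, None
    for pos, site in enumerate(sites, start=1):
        if site.segment_index != cur_seg:
            if cur_seg is not None:
                _close(sites, cur_seg, seg_start, pos - 1, tm_intervals, loop_spans)
            cur_seg, seg_start = site.segment_index, pos
    if cur_seg is not None:
        _close(sites, cur_seg, seg_start, len(sites), tm_intervals, loop_spans)

    loops = []
    loop_order = sorted(i for i in loop_spans)
    for loop_counter, seg_idx in enumerate(loop_order):
        meta = loops_meta[loop_counter]
        s, e = loop_spans[seg_idx]
        loops.append((meta.name, s, e, meta.side))

    # a planting occupies a contiguous motif-flagged block matching its own
    # text inside its host loop; locate it there
    motif_positions: dict[str, list[int]] = {}
    name_to_span = {name: (s, e) for name, s, e, _ in loops}
    for planting in plantings:
        motif_positions.setdefault(planting.text, [])
        span = name_to_span.get(planting.loop_name)
        if span is None:
            continue
        text = planting.text
        for pos in range(span[0], span[1] - len(text) + 2):
            if all(sites[pos - 1 + k].residue == text[k] and sites[pos - 1 + k].is_motif
                   for k in range(len(text))):
                motif_positions[text] = list(range(pos, pos + len(text)))
                break
    return GroundTruth(
        tm_intervals=tm_intervals,
        loops=loops,
        motif_positions=motif_positions,
        n_term_side=spec.n_term_side,
    )


def _close(sites, seg_idx, start, end, tm_intervals, loop_spans):
    if sites[start - 1].kind == "tm":
        tm_intervals.append((start, end))
    else:
        loop_spans[seg_idx] = (start, end)


# ---------------------------------------------------------------------------
# sampling and evolution


def sample_sequence(
    spec: TopologySpec,
    config: FamilySimConfig,
    rng: np.random.Generator,
    seq_id: str = "root",
) -> tuple[Sequence, GroundTruth, list[Site]]:
    """Draw a root sequence from the spec; returns sequence, truth, sites.

    TM residues come from the hydrophobic distribution with polar residues
    sprinkled in at ``sprinkle_prob``; loops from the polar-enriched
    distribution; motif texts are written verbatim at their planted
    offsets (those sites are exempt from later mutation).
    """
    sites: list[Site] = []
    loop_names = spec.loop_names()
    loop_counter = -1
    plant_by_loop = {}
    for planting in config.motifs:
        if planting.loop_name not in loop_names:
            raise ValueError(f"no loop named {planting.loop_name!r} in spec")
        plant_by_loop.setdefault(planting.loop_name, []).append(planting)

    for seg_idx, seg in enumerate(spec.segments):
        length = int(rng.integers(seg.length[0], seg.length[1] + 1))
        if seg.kind == "tm":
            residues = _sample(TM_DIST, rng, length)
            for i in range(length):
                if rng.random() < config.sprinkle_prob:
                    residues[i] = POLAR_SPRINKLE[rng.integers(len(POLAR_SPRINKLE))]
            sites.extend(Site(seg_idx, "tm", ch) for ch in residues)
        else:
            loop_counter += 1
            name = loop_names[loop_counter]
            residues = _sample(LOOP_DIST, rng, length)
            motif_flags = [False] * length
            for planting in plant_by_loop.get(name, []):
                if planting.offset + len(planting.text) > length:
                    raise ValueError(
                        f"motif {planting.text!r} (offset {planting.offset}) "
                        f"does not fit in loop {name!r} of length {length}"
                    )
                for k, ch in enumerate(planting.text):
                    residues[planting.offset + k] = ch
                    motif_flags[planting.offset + k] = True
            sites.extend(
                Site(seg_idx, "loop", ch, flag)
                for ch, flag in zip(residues, motif_flags)
            )
    seq = Sequence(id=seq_id, residues="".join(s.residue for s in sites))
    truth = _truth_from_sites(sites, spec, config.motifs)
    return seq, truth, sites


@dataclass
class SyntheticFamily:
    spec: TopologySpec
    config: FamilySimConfig
    sequences: list[Sequence]
    alignment: Alignment
    truths: dict[str, GroundTruth]

    @property
    def root_truth(self) -> GroundTruth:
        return self.truths[self.sequences[0].id]


def evolve_family(
    spec: TopologySpec,
    config: FamilySimConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticFamily:
    """Evolve a family from a freshly sampled root.

    Member 1 is the unmutated root; each further member applies per-site
    substitution (motif sites exempt; replacements drawn from the site's
    state-conditional distribution so hydropathy contrast is stationary)
    and loop-only indels of 1-3 residues.  The alignment is reconstructed
    from the indel history — no aligner is involved — so degapping any row
    reproduces its sequence exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root_seq, _, root_sites = sample_sequence(spec, config, rng, seq_id="seq00")
    n_root = len(root_sites)

    # per sequence: surviving root sites (possibly substituted) and insertions
    members: list[tuple[str, dict[int, str | None], dict[int, list[str]]]] = []
    members.append(("seq00", {i: root_sites[i].residue for i in range(n_root)}, {}))

    loop_ranges: dict[int, tuple[int, int]] = {}
    for i, site in enumerate(root_sites):
        if site.kind == "loop":
            a, b = loop_ranges.get(site.segment_index, (i, i))
            loop_ranges[site.segment_index] = (min(a, i), max(b, i))

    for m in range(1, config.n_sequences):
        residues: dict[int, str | None] = {}
        for i, site in enumerate(root_sites):
            ch = site.residue
            if not site.is_motif and rng.random() < config.substitution_prob:
                dist = TM_DIST if site.kind == "tm" else LOOP_DIST
                ch = _sample(dist, rng)[0]
            residues[i] = ch
        insertions: dict[int, list[str]] = {}
        for seg_idx, (a, b) in loop_ranges.items():
            if rng.random() >= config.indel_rate:
                continue
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion of non-motif loop sites
                candidates = [
                    i for i in range(a, b - size + 2)
                    if all(not root_sites[j].is_motif and residues[j] is not None
                           for j in range(i, i + size))
                ]
                # keep at least 4 residues in the loop so TMs stay separated
                alive = sum(1 for j in range(a, b + 1) if residues[j] is not None)
                if candidates and alive - size >= 4:
                    at = candidates[rng.integers(len(candidates))]
                    for j in range(at, at + size):
                        residues[j] = None
            else:  # insertion after a loop site outside any motif block
                anchors = [
                    i for i in range(a, b)
                    if not (root_sites[i].is_motif and root_sites[i + 1].is_motif)
                ]
                if anchors:
                    at = anchors[rng.integers(len(anchors))]
                    insertions[at] = _sample(LOOP_DIST, rng, size)
        members.append((f"seq{m:02d}", residues, insertions))

    # ---- assemble alignment columns from the event history
    columns: list[tuple[int, int, int]] = []  # (root index, member, k); member=-1 root col
    for i in range(n_root):
        columns.append((i, -1, 0))
        for mi, (_, _, ins) in enumerate(members):
            for k in range(len(ins.get(i, []))):
                columns.append((i, mi, k))

    rows = []
    for mi, (sid, residues, ins) in enumerate(members):
        chars = []
        for (ri, owner, k) in columns:
            if owner == -1:
                ch = residues[ri]
                chars.append(ch if ch is not None else "-")
            elif owner == mi:
                chars.append(ins[ri][k])
            else:
                chars.append("-")
        rows.append((sid, "".join(chars)))
    alignment = Alignment(rows=rows)

    sequences, truths = [], {}
    for mi, (sid, residues, ins) in enumerate(members):
        member_sites: list[Site] = []
        for i in range(n_root):
            ch = residues[i]
            if ch is not None:
                member_sites.append(replace(root_sites[i], residue=ch))
            for ch_ins in ins.get(i, []):
                member_sites.append(
                    Site(root_sites[i].segment_index, "loop", ch_ins)
                )
        seq = Sequence(id=sid, residues="".join(s.residue for s in member_sites))
        sequences.append(seq)
        truths[sid] = _truth_from_sites(member_sites, spec, config.motifs)
    return SyntheticFamily(spec, config, sequences, alignment, truths)


# ---------------------------------------------------------------------------
# toy structures


SIDE_CHAIN_ATOM = {
    "D": ("OD1", "O"), "E": ("OE1", "O"), "N": ("OD1", "O"), "Q": ("OE1", "O"),
    "S": ("OG", "O"), "T": ("OG1", "O"),
    "K": ("NZ", "N"), "R": ("NH1", "N"), "H": ("NE2", "N"),
}

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


@dataclass(frozen=True)
class PlantedAtom:
    """Plant one hetero atom at ``offset`` Angstrom from a target residue.

    ``ref`` selects the reference point: the residue's CA or its
    side-chain donor atom ("side").  The atom is placed along the inward
    direction (towards the bundle axis), emulating a pocket-bound ligand.
    """

    name: str
    element: str
    target_residue: int
    offset: float
    ref: str = "CA"

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be > 0")


@dataclass(frozen=True)
class ToyStructureConfig:
    rise: float = 1.5  # Angstrom per residue along the helix axis
    turn_deg: float = 100.0  # degrees per residue
    helix_radius: float = 2.3
    bundle_radius: float | None = None  # computed from TM count when None
    ligand_name: str = "DPM"
    ligand_atoms: tuple[PlantedAtom, ...] = ()
    ion: PlantedAtom | None = None
    ion_name: str = "ZN"


def build_toy_structure(
    sequence: Sequence,
    truth: GroundTruth,
    config: ToyStructureConfig = ToyStructureConfig(),
) -> Structure:
    """CA-level helix bundle for a generated sequence.

    TM segments become ideal helices (1.5 Angstrom rise, 100 degrees per
    residue) placed on a circle with alternating direction; loops are
    straight-line connectors.  Residues with a polar side chain get one
    pseudo side-chain donor atom 2.4 Angstrom radially outward from the
    helix axis.  Ligand atoms and the ion are planted at their configured
    offsets; planted atoms closer than 1 Angstrom to each other are an
    error.
    """
    n_tm = truth.n_tm
    if n_tm < 1:
        raise ValueError("toy structure needs at least one TM")
    R = config.bundle_radius
    if R is None:
        R = max(8.0, 10.0 / (2.0 * math.sin(math.pi / max(n_tm, 2))))

    coords = np.zeros((len(sequence), 3))
    axis_xy = np.zeros((len(sequence), 2))  # helix axis (for side-chain dirs)
    placed = np.zeros(len(sequence), dtype=bool)

    for h, (s, e) in enumerate(truth.tm_intervals):
        phi = 2 * math.pi * h / n_tm
        cx, cy = R * math.cos(phi), R * math.sin(phi)
        length = e - s + 1
        direction = 1 if h % 2 == 0 else -1
        z0 = 0.0 if direction == 1 else (length - 1) * config.rise
        for j in range(length):
            ang = math.radians(config.turn_deg) * j + phi
            x = cx + config.helix_radius * math.cos(ang)
            y = cy + config.helix_radius * math.sin(ang)
            z = z0 + direction * j * config.rise
            idx = s - 1 + j
            coords[idx] = (x, y, z)
            axis_xy[idx] = (cx, cy)
            placed[idx] = True

    # loops: straight lines between flanking placed residues
    intervals = sorted(truth.tm_intervals)
    gaps = []
    if intervals[0][0] > 1:
        gaps.append((1, intervals[0][0] - 1, None, intervals[0][0]))
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 > e1 + 1:
            gaps.append((e1 + 1, s2 - 1, e1, s2))
    if intervals[-1][1] < len(sequence):
        gaps.append((intervals[-1][1] + 1, len(sequence), intervals[-1][1], None))
    for (a, b, left, right) in gaps:
        k = b - a + 1
        if left is not None and right is not None:
            p0, p1 = coords[left - 1], coords[right - 1]
            for j in range(k):
                t = (j + 1) / (k + 1)
                coords[a - 1 + j] = p0 + t * (p1 - p0)
                axis_xy[a - 1 + j] = axis_xy[left - 1]
        else:
            anchor = right if left is None else left
            p0 = coords[anchor - 1]
            out = p0[:2]
            norm = np.linalg.norm(out)
            u_xy = out / norm if norm > 1e-6 else np.array([1.0, 0.0])
            zdir = -1.0 if left is None else 1.0
            zsign = math.copysign(1.0, p0[2]) if abs(p0[2]) > 1e-9 else 1.0
            step = np.array([u_xy[0] * 2.0, u_xy[1] * 2.0, zsign * zdir * 2.5])
            step = step / np.linalg.norm(step) * 3.5
            for j in range(k):
                offset = (j + 1) if left is not None else (k - j)
                coords[a - 1 + j] = p0 + offset * step
                axis_xy[a - 1 + j] = axis_xy[anchor - 1]
        placed[a - 1:b] = True

    residues: list[Residue] = []
    side_atom_pos: dict[int, np.ndarray] = {}
    for i, ch in enumerate(sequence.residues):
        pos = coords[i]
        atoms = [Atom("CA", "C", float(pos[0]), float(pos[1]), float(pos[2]))]
        if ch in SIDE_CHAIN_ATOM:
            aname, elem = SIDE_CHAIN_ATOM[ch]
            out = pos[:2] - axis_xy[i]
            norm = np.linalg.norm(out)
            u = out / norm if norm > 1e-6 else np.array([1.0, 0.0])
            spos = pos + np.array([u[0] * 2.4, u[1] * 2.4, 0.0])
            atoms.append(Atom(aname, elem, *map(float, spos)))
            side_atom_pos[i + 1] = spos
        residues.append(Residue("A", i + 1, THREE_LETTER[ch], atoms, hetero=False))

    def plant(spec: PlantedAtom) -> Atom:
        if not (1 <= spec.target_residue <= len(sequence)):
            raise ValueError(f"target residue {spec.target_residue} does not exist")
        if spec.ref == "side":
            if spec.target_residue not in side_atom_pos:
                raise ValueError(
                    f"residue {spec.target_residue} has no side-chain donor atom"
                )
            ref = side_atom_pos[spec.target_residue]
        else:
            ref = coords[spec.target_residue - 1]
        inward = -ref[:2]
        norm = np.linalg.norm(inward)
        u = (inward / norm) if norm > 1e-6 else np.array([0.0, 0.0])
        direction = np.array([u[0], u[1], 0.0])
        if norm <= 1e-6:
            direction = np.array([0.0, 0.0, 1.0])
        p = ref + direction * spec.offset
        return Atom(spec.name, spec.element, *map(float, p))

    planted: list[Atom] = []
    if config.ligand_atoms:
        lig_atoms = [plant(spec) for spec in config.ligand_atoms]
        planted.extend(lig_atoms)
        residues.append(Residue("X", 900, config.ligand_name, lig_atoms, hetero=True))
    if config.ion is not None:
        ion_atom = plant(config.ion)
        planted.extend([ion_atom])
        residues.append(Residue("X", 901, config.ion_name, [ion_atom], hetero=True))
    for i in range(len(planted)):
        for j in range(i + 1, len(planted)):
            d = math.dist(
                (planted[i].x, planted[i].y, planted[i].z),
                (planted[j].x, planted[j].y, planted[j].z),
            )
            if d < 1.0:
                raise ValueError(
                    f"planted atoms {planted[i].name!r} and {planted[j].name!r} "
                    f"clash ({d:.2f} Angstrom apart)"
                )
    return Structure(residues=residues)


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass
class RecoveryMetrics:
    tm_count_true: int
    tm_count_pred: int
    boundary_mad: float | None  # mean abs deviation, only when counts match
    loop_side_accuracy: float

    @property
    def count_match(self) -> bool:
        return self.tm_count_true == self.tm_count_pred


def boundary_deviation(
    truth: list[tuple[int, int]], predicted: list[tuple[int, int]]
) -> float | None:
    """Mean absolute boundary deviation (residues) for equal-count interval
    lists matched in order; None when the counts differ."""
    if len(truth) != len(predicted):
        return None
    if not truth:
        return 0.0
    devs = []
    for (ts, te), (ps, pe) in zip(sorted(truth), sorted(predicted)):
        devs.append(abs(ts - ps))
        devs.append(abs(te - pe))
    return float(np.mean(devs))


def evaluate_recovery(
    truth: GroundTruth, model: TopologyModel, seq_id: str
) -> RecoveryMetrics:
    """Compare a reconciled topology with a member's ground truth."""
    predicted = model.tm_intervals(seq_id)
    mad = boundary_deviation(truth.tm_intervals, predicted)
    truth_sides = [side for _, _, _, side in truth.loops]
    # internal loops only (drop the two termini tails)
    truth_internal = truth_sides[1:-1]
    model_internal = [lp.side for lp in model.loops][1:-1]
    n = min(len(truth_internal), len(model_internal))
    if n == 0:
        side_acc = 1.0 if model.n_term_side == truth.n_term_side else 0.0
    else:
        side_acc = sum(
            1 for a, b in zip(truth_internal[:n], model_internal[:n]) if a == b
        ) / max(len(truth_internal), len(model_internal))
    return RecoveryMetrics(
        tm_count_true=truth.n_tm,
        tm_count_pred=model.n_tm,
        boundary_mad=mad,
        loop_side_accuracy=side_acc,
    )
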