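"""Conservation scoring, degenerate motif scanning and position mapping.

Motif patterns use a compact notation transcribed from the field's usual
shorthand: plain letters are fixed residues, bracketed groups are
alternatives ([TQ] = T or Q) and ``x`` is a wildcard — so the conserved
loop motif "KE(T/Q)xxT" is written ``KE[TQ]xxT``.  Scans are restricted
to a named region of the topology (a lumenal loop such as ``EL3`` or a
helix such as ``TM9``) so that a motif is only accepted on the membrane
side where it can act.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import TopologyModel
from .formats import GAP, Alignment


@dataclass
class ConservationProfile:
    """Per-column conservation: frequency of the majority non-gap residue."""

    scores: np.ndarray  # NaN where undefined (gap fraction above threshold)
    gap_fraction: np.ndarray
    max_gap_fraction: float

    def score(self, column: int) -> float:
        """1-based column accessor."""
        return float(self.scores[column - 1])


def column_conservation(
    alignment: Alignment, max_gap_fraction: float = 0.5
) -> ConservationProfile:
    """Majority-residue conservation per alignment column.

    The score is the frequency of the most common non-gap residue among
    the non-gap rows, so an invariant column scores 1.0.  Columns with a
    gap fraction above ``max_gap_fraction`` (and all-gap columns) are
    undefined (NaN).
    """
    if len(alignment.rows) < 2:
        raise ValueError("conservation needs at least 2 rows")
    n = alignment.n_columns
    scores = np.full(n, np.nan)
    gap_frac = np.zeros(n)
    for c in range(1, n + 1):
        col = alignment.column(c)
        gaps = col.count(GAP)
        gap_frac[c - 1] = gaps / len(col)
        residues = [ch for ch in col if ch != GAP]
        if not residues or gap_frac[c - 1] > max_gap_fraction:
            continue
        scores[c - 1] = Counter(residues).most_common(1)[0][1] / len(residues)
    return ConservationProfile(scores, gap_frac, max_gap_fraction)


@dataclass
class MotifPattern:
    """A degenerate motif with a region restriction.

    ``elements`` holds one entry per motif position: a frozenset of
    allowed residues, or ``None`` for a wildcard.
    """

    name: str
    elements: list[frozenset | None]
    region: str  # e.g. "EL1", "TM9"

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("pattern must have length >= 2")
        if all(e is None for e in self.elements):
            raise ValueError("pattern needs at least one non-wildcard element")

    def __len__(self) -> int:
        return len(self.elements)

    def matches(self, fragment: str) -> bool:
        if len(fragment) != len(self.elements):
            return False
        return all(e is None or ch in e
                   for ch, e in zip(fragment, self.elements))


def parse_pattern(name: str, spec: str, region: str) -> MotifPattern:
    """Parse pattern text like ``KE[TQ]xxT`` into a :class:`MotifPattern`."""
    elements: list[frozenset | None] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            j = spec.index("]", i)
            elements.append(frozenset(spec[i + 1:j].upper()))
            i = j + 1
        elif ch == "x":
            elements.append(None)
            i += 1
        else:
            elements.append(frozenset(ch.upper()))
            i += 1
    return MotifPattern(name=name, elements=elements, region=region)


@dataclass
class MotifHit:
    """One motif occurrence anchored to alignment columns.

    ``per_seq`` maps sequence id to (1-based start position, matched
    substring) for every row matching the pattern at these columns.
    """

    pattern_name: str
    columns: tuple[int, ...]
    per_seq: dict[str, tuple[int, str]] = field(default_factory=dict)
    mean_conservation: float = 0.0
    region: str = ""


def scan_pattern(
    alignment: Alignment,
    pattern: MotifPattern,
    topology: TopologyModel,
    match_fraction: float = 0.8,
    conservation: ConservationProfile | None = None,
) -> list[MotifHit]:
    """Scan a degenerate pattern inside its restricted topology region.

    A window of consecutive columns is a hit when at least
    ``match_fraction`` of the rows without gaps in the window satisfy the
    pattern (and at least one row matches).  Overlapping windows are
    resolved by keeping the window with the highest mean conservation
    over its columns, ties to the leftmost — one site per motif, the way
    such motifs are reported.
    """
    c1, c2 = topology.loop_columns(pattern.region, alignment.n_columns)
    if conservation is None:
        conservation = column_conservation(alignment)
    L = len(pattern)
    pos_of_col = {sid: alignment.position_of_column(sid) for sid in alignment.ids}
    windows = []
    for start in range(c1, c2 - L + 2):
        cols = range(start, start + L)
        matched: dict[str, tuple[int, str]] = {}
        eligible = 0
        for sid, gapped in alignment.rows:
            frag = "".join(gapped[c - 1] for c in cols)
            if GAP in frag:
                continue
            eligible += 1
            if pattern.matches(frag):
                matched[sid] = (pos_of_col[sid][start - 1], frag)
        if eligible == 0 or not matched:
            continue
        if len(matched) / eligible >= match_fraction:
            cons = np.nanmean([conservation.scores[c - 1] for c in cols])
            windows.append(MotifHit(
                pattern_name=pattern.name,
                columns=tuple(cols),
                per_seq=matched,
                mean_conservation=float(cons) if np.isfinite(cons) else 0.0,
                region=pattern.region,
            ))
    if not windows:
        return []
    best = max(windows, key=lambda h: (h.mean_conservation, -h.columns[0]))
    return [best]


def map_position(
    alignment: Alignment, from_seq: str, position: int, to_seq: str
) -> int | None:
    """Map a residue position between sequences through the alignment.

    Returns the 1-based position of ``to_seq`` in the same alignment
    column, or ``None`` when ``to_seq`` has a gap there.
    """
    col = alignment.column_of_position(from_seq, position)
    target = alignment.position_of_column(to_seq)[col - 1]
    return target if target > 0 else None


def motif_table(
    hits: list[MotifHit], profile: ConservationProfile | None = None
) -> pd.DataFrame:
    """Tabulate motif hits: one row per motif x matched sequence."""
    rows = []
    for hit in hits:
        for sid, (start, frag) in sorted(hit.per_seq.items()):
            rows.append({
                "motif": hit.pattern_name,
                "seq_id": sid,
                "start": start,
                "end": start + len(frag) - 1,
                "matched": frag,
                "region": hit.region,
                "mean_conservation": round(hit.mean_conservation, 4),
            })
    return pd.DataFrame(
        rows,
        columns=["motif", "seq_id", "start", "end", "matched", "region",
                 "mean_conservation"],
    )


def read_motif_definitions(path) -> list[tuple[str, str, str]]:
    """Read motif definitions TSV (name, pattern, region)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, spec, region = line.split("\t")[:3]
            out.append((name, spec, region))
    return out
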