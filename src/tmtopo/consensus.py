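"""Family-level consensus topology inference.

Per-sequence TM predictions from an ensemble of predictors are projected
onto the family alignment, turned into cross-family candidate membrane
regions, and reconciled into one topology that satisfies the biological
constraints: known compartment of a terminus, the parity rule (termini on
opposite membrane sides require an odd number of crossings), and
annotation masks marking segments that are known not to be
membrane-embedded (e.g. a hydrophobic lumenal helix that predictors call
as a false-positive TM).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .formats import Alignment, AnnotationTrack
from .hydropathy import PredictorOutput

CYTO = "cytoplasmic"
LUMEN = "lumenal"


class TopologyError(ValueError):
    """Raised when no topology can satisfy the constraints."""

    def __init__(self, message: str, report: "DiscrepancyReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class ColumnVoteMatrix:
    """Alignment-column support for the TM state.

    ``per_predictor[p, c]`` is the fraction of sequences that are non-gap
    at column ``c`` (0-indexed) whose prediction by predictor ``p`` covers
    that column; ``aggregate`` is the mean over predictors.  Columns with
    more than ``max_gap_fraction`` gaps are flagged uncallable.
    """

    predictor_ids: list[str]
    per_predictor: np.ndarray  # (n_predictors, n_columns)
    aggregate: np.ndarray  # (n_columns,)
    gap_fraction: np.ndarray  # (n_columns,)
    callable_mask: np.ndarray  # (n_columns,) bool
    max_gap_fraction: float

    @property
    def n_columns(self) -> int:
        return self.aggregate.shape[0]


@dataclass
class CandidateRegion:
    """A merged cross-family candidate TM region in alignment columns.

    ``span`` is the maximal supported column run (1-based inclusive);
    ``core`` the sub-run supported by at least the required number of
    predictors (``None`` when empty).  ``span_by_seq``/``core_by_seq``
    carry the projection onto each sequence's residue coordinates.
    """

    index: int
    span: tuple[int, int]
    core: tuple[int, int] | None
    support: float  # mean aggregate support over the span
    span_by_seq: dict[str, tuple[int, int]] = field(default_factory=dict)
    core_by_seq: dict[str, tuple[int, int]] = field(default_factory=dict)
    status: str = "candidate"  # candidate|accepted|masked|subthreshold|missing-in-member

    def __post_init__(self) -> None:
        if self.core is not None:
            if not (self.span[0] <= self.core[0] <= self.core[1] <= self.span[1]):
                raise ValueError("core must lie within span")


@dataclass
class TopologyConstraints:
    """Biological constraints on the reconciled topology."""

    n_term_side: str = "unknown"  # cytoplasmic | lumenal | unknown
    c_term_side: str = "unknown"
    masks: AnnotationTrack | None = None
    first_segment_signal_anchor: bool = True

    def __post_init__(self) -> None:
        for side in (self.n_term_side, self.c_term_side):
            if side not in (CYTO, LUMEN, "unknown"):
                raise ValueError(f"bad side {side!r}")
        if self.n_term_side == "unknown" and self.c_term_side == "unknown":
            raise ValueError("at least one terminus side must be known")


@dataclass
class Loop:
    """The loop after TM ``after_tm`` (0 = the N-terminal tail)."""

    after_tm: int
    side: str
    name: str  # EL1.. for lumenal loops, CL1.. for cytoplasmic, NTERM/CTERM


@dataclass
class TopologyModel:
    """The reconciled family topology with sided, named loops."""

    tms: list[CandidateRegion]
    loops: list[Loop]
    n_term_side: str
    c_term_side: str
    parity_ok: bool

    @property
    def n_tm(self) -> int:
        return len(self.tms)

    def tm_intervals(self, seq_id: str) -> list[tuple[int, int]]:
        return [r.span_by_seq[seq_id] for r in self.tms if seq_id in r.span_by_seq]

    def lumenal_loops(self) -> list[Loop]:
        return [lp for lp in self.loops if lp.side == LUMEN and lp.name.startswith("EL")]

    def loop_columns(self, name: str, n_columns: int) -> tuple[int, int]:
        """Column interval of a named loop (or TM via 'TM<k>')."""
        if name.startswith("TM"):
            k = int(name[2:])
            if not 1 <= k <= self.n_tm:
                raise KeyError(f"no region {name}")
            return self.tms[k - 1].span
        for lp in self.loops:
            if lp.name == name:
                left = 1 if lp.after_tm == 0 else self.tms[lp.after_tm - 1].span[1] + 1
                right = (n_columns if lp.after_tm == self.n_tm
                         else self.tms[lp.after_tm].span[0] - 1)
                if left > right:
                    raise KeyError(f"loop {name} is empty")
                return (left, right)
        raise KeyError(f"no loop named {name!r}")


@dataclass
class Discrepancy:
    region_index: int
    subject: str  # sequence/family id, or '*' for family-wide findings
    klass: str  # signal-anchor-ambiguity|missing-in-sequence|subthreshold|mask-overlap
    evidence: str


@dataclass
class DiscrepancyReport:
    items: list[Discrepancy] = field(default_factory=list)

    def classes(self) -> set[str]:
        return {d.klass for d in self.items}

    def for_region(self, index: int) -> list[Discrepancy]:
        return [d for d in self.items if d.region_index == index]

    def to_json(self) -> str:
        return json.dumps(
            [d.__dict__ for d in self.items], indent=2, sort_keys=True
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("region\tsubject\tclass\tevidence\n")
            for d in self.items:
                fh.write(f"{d.region_index}\t{d.subject}\t{d.klass}\t{d.evidence}\n")


# ---------------------------------------------------------------------------
# projection and candidate calling


def project_segments_to_columns(
    alignment: Alignment,
    outputs: list[PredictorOutput],
    max_gap_fraction: float = 0.5,
) -> ColumnVoteMatrix:
    """Project per-sequence TM segments onto alignment columns.

    A column is covered by a segment iff the row is non-gap there and the
    residue position falls inside the segment; gap cells contribute to
    neither numerator nor denominator of the per-column fraction.
    """
    n_cols = alignment.n_columns
    n_rows = len(alignment.rows)
    pos_of_col = {sid: np.array(alignment.position_of_column(sid))
                  for sid in alignment.ids}
    nongap = np.stack([pos_of_col[sid] > 0 for sid in alignment.ids])  # rows x cols
    nongap_count = nongap.sum(axis=0)

    per_pred = np.zeros((len(outputs), n_cols))
    for p, out in enumerate(outputs):
        covered = np.zeros(n_cols)
        for sid in alignment.ids:
            segs = out.for_sequence(sid)
            if not segs:
                continue
            positions = pos_of_col[sid]
            deglen = int(positions.max())
            row_cov = np.zeros(n_cols, dtype=bool)
            for seg in segs:
                if seg.end > deglen:
                    raise ValueError(
                        f"segment {seg.start}-{seg.end} of {sid!r} "
                        f"(predictor {out.predictor_id!r}) beyond degapped "
                        f"length {deglen}"
                    )
                row_cov |= (positions >= seg.start) & (positions <= seg.end)
            covered += row_cov
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(nongap_count > 0, covered / nongap_count, 0.0)
        per_pred[p] = frac
    gap_frac = 1.0 - nongap_count / n_rows
    return ColumnVoteMatrix(
        predictor_ids=[o.predictor_id for o in outputs],
        per_predictor=per_pred,
        aggregate=per_pred.mean(axis=0) if outputs else np.zeros(n_cols),
        gap_fraction=gap_frac,
        callable_mask=gap_frac <= max_gap_fraction,
        max_gap_fraction=max_gap_fraction,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as 1-based inclusive pairs."""
    idx = np.flatnonzero(mask) + 1
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs, start = [], 0
    for b in breaks:
        runs.append((int(idx[start]), int(idx[b])))
        start = b + 1
    runs.append((int(idx[start]), int(idx[-1])))
    return runs


def call_candidate_regions(
    votes: ColumnVoteMatrix,
    alignment: Alignment | None = None,
    min_support: float = 0.5,
    core_min_predictors: int = 3,
    min_width: int = 8,
    min_gap: int = 3,
) -> list[CandidateRegion]:
    """Call cross-family candidate TM regions from the vote matrix.

    A span is a maximal run of callable columns with aggregate support at
    least ``min_support``; runs separated by fewer than ``min_gap``
    callable columns are merged; spans narrower than ``min_width`` are
    dropped.  The core is the longest sub-run whose columns are supported
    (fraction >= ``min_support``) by at least ``core_min_predictors``
    predictors.  Uncallable (gap-heavy) columns break runs and block
    merging.
    """
    if not (0 < min_support <= 1):
        raise ValueError("min_support must be in (0, 1]")
    supported = votes.callable_mask & (votes.aggregate >= min_support)
    runs = _runs(supported)
    # merge nearby runs unless an uncallable column lies between them
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged:
            prev = merged[-1]
            gap_cols = np.arange(prev[1], run[0] - 1)  # 0-based cols between
            if (run[0] - prev[1] - 1 < min_gap
                    and bool(votes.callable_mask[gap_cols].all())):
                merged[-1] = (prev[0], run[1])
                continue
        merged.append(run)

    pos_of_col = ({sid: alignment.position_of_column(sid) for sid in alignment.ids}
                  if alignment is not None else {})
    n_pred_support = (votes.per_predictor >= min_support).sum(axis=0)

    regions = []
    for span in merged:
        if span[1] - span[0] + 1 < min_width:
            continue
        in_span = np.zeros(votes.n_columns, dtype=bool)
        in_span[span[0] - 1:span[1]] = True
        core_runs = _runs(in_span & (n_pred_support >= core_min_predictors))
        core = max(core_runs, key=lambda r: (r[1] - r[0], -r[0])) if core_runs else None
        region = CandidateRegion(
            index=len(regions) + 1,
            span=span,
            core=core,
            support=float(votes.aggregate[span[0] - 1:span[1]].mean()),
        )
        for sid, positions in pos_of_col.items():
            for interval, target in ((span, region.span_by_seq),
                                     (core, region.core_by_seq)):
                if interval is None:
                    continue
                pos = [positions[c - 1] for c in range(interval[0], interval[1] + 1)
                       if positions[c - 1] > 0]
                if pos:
                    target[sid] = (min(pos), max(pos))
        regions.append(region)
    return regions


# ---------------------------------------------------------------------------
# constraints and reconciliation


def required_parity(n_term_side: str, c_term_side: str) -> str:
    """'odd' iff the termini lie on opposite membrane sides, else 'even'."""
    for side in (n_term_side, c_term_side):
        if side not in (CYTO, LUMEN):
            raise ValueError(f"terminus side {side!r} must be known")
    return "odd" if n_term_side != c_term_side else "even"


def _mask_columns(masks: AnnotationTrack, alignment: Alignment) -> list[tuple[int, int]]:
    """Mask intervals converted to alignment-column intervals."""
    cols = []
    for sid, start, end, _label in masks.intervals:
        c1 = alignment.column_of_position(sid, start)
        c2 = alignment.column_of_position(sid, end)
        cols.append((c1, c2))
    return cols


def _is_masked(region: CandidateRegion, mask_cols: list[tuple[int, int]]) -> bool:
    # a candidate is masked only when its core lies entirely inside a mask;
    # a mere span overlap keeps genuine TMs adjacent to the masked element
    probe = region.core if region.core is not None else region.span
    return any(m1 <= probe[0] and probe[1] <= m2 for m1, m2 in mask_cols)


def _select_subset(
    candidates: list[CandidateRegion],
    eligible: list[int],
    parity: str | None,
    must_include: int | None,
) -> list[int] | None:
    """Max-support subset of ``eligible`` honouring parity and inclusion.

    Deterministic ordering: maximal total support, then fewest regions,
    then lexicographically smallest kept-index tuple.  Exhaustive for
    small candidate sets, greedy weakest-drop otherwise (equivalent for
    non-negative supports).
    """
    support = {i: candidates[i].support for i in eligible}
    if parity is None:
        keep = sorted(eligible)
        if must_include is not None and must_include not in keep:
            return None
        return keep

    want_odd = parity == "odd"
    if len(eligible) <= 16:
        best = None
        for r in range(len(eligible), -1, -1):
            for combo in itertools.combinations(sorted(eligible), r):
                if len(combo) % 2 != (1 if want_odd else 0):
                    continue
                if must_include is not None and must_include not in combo:
                    continue
                key = (sum(support[i] for i in combo), -len(combo),
                       tuple(-i for i in combo))
                if best is None or key > best[0]:
                    best = (key, combo)
        return list(best[1]) if best else None
    keep = sorted(eligible)
    if len(keep) % 2 != (1 if want_odd else 0):
        droppable = [i for i in keep if i != must_include]
        if not droppable:
            return None
        weakest = min(droppable, key=lambda i: (support[i], -i))
        keep.remove(weakest)
    if must_include is not None and must_include not in keep:
        return None
    return keep


def reconcile(
    candidates: list[CandidateRegion],
    constraints: TopologyConstraints,
    alignment: Alignment | None = None,
) -> tuple[TopologyModel, DiscrepancyReport]:
    """Reconcile candidate regions into a constraint-satisfying topology.

    Candidates whose core lies entirely inside a mask are excluded and
    reported as ``mask-overlap``.  Among the rest, the subset with maximal
    total support whose count matches the required parity is accepted
    (exhaustive search; the first candidate is held in when the
    signal-anchor flag is set, unless that makes the constraints
    unsatisfiable).  Loop sides are then assigned by alternation from the
    known terminus.
    """
    report = DiscrepancyReport()
    mask_cols = (_mask_columns(constraints.masks, alignment)
                 if constraints.masks is not None and alignment is not None
                 else [])
    if constraints.masks is not None and alignment is None and constraints.masks.intervals:
        raise ValueError("masks require the alignment to resolve columns")

    eligible = []
    for i, cand in enumerate(candidates):
        if _is_masked(cand, mask_cols):
            cand.status = "masked"
            report.items.append(Discrepancy(
                cand.index, "*", "mask-overlap",
                f"candidate core {cand.core or cand.span} lies inside an "
                f"annotation mask; excluded from the topology",
            ))
        else:
            eligible.append(i)

    parity = None
    if constraints.n_term_side != "unknown" and constraints.c_term_side != "unknown":
        parity = required_parity(constraints.n_term_side, constraints.c_term_side)

    must_include = None
    if constraints.first_segment_signal_anchor and eligible:
        must_include = eligible[0]

    keep = _select_subset(candidates, eligible, parity, must_include)
    if keep is None and must_include is not None:
        # parity may force the signal anchor out; retry without the pin
        keep = _select_subset(candidates, eligible, parity, None)
    if keep is None:
        for i in eligible:
            candidates[i].status = "subthreshold"
        raise TopologyError(
            f"no candidate subset satisfies required parity {parity!r}", report
        )

    for i in eligible:
        if i in keep:
            candidates[i].status = "accepted"
        else:
            candidates[i].status = "subthreshold"
            report.items.append(Discrepancy(
                candidates[i].index, "*", "subthreshold",
                f"dropped (support {candidates[i].support:.3f}) to satisfy "
                f"required parity {parity!r}",
            ))

    if constraints.first_segment_signal_anchor and candidates:
        report.items.append(Discrepancy(
            candidates[0].index, "*", "signal-anchor-ambiguity",
            "most N-terminal hydrophobic region treated as a signal anchor "
            "(an uncleaved TM), not a cleaved signal peptide",
        ))

    accepted = [candidates[i] for i in keep]
    known = (("n", constraints.n_term_side)
             if constraints.n_term_side != "unknown"
             else ("c", constraints.c_term_side))
    model = _build_model(accepted, known, parity)
    return model, report


def _flip(side: str) -> str:
    return LUMEN if side == CYTO else CYTO


def _build_model(
    accepted: list[CandidateRegion],
    known_terminus: tuple[str, str],
    parity: str | None,
) -> TopologyModel:
    n = len(accepted)
    which, side = known_terminus
    if which == "n":
        n_side = side
    else:
        n_side = side if n % 2 == 0 else _flip(side)
    c_side = n_side if n % 2 == 0 else _flip(n_side)
    parity_ok = True
    if parity is not None:
        parity_ok = (n % 2 == 1) == (parity == "odd")
    model = TopologyModel(
        tms=accepted, loops=[], n_term_side=n_side, c_term_side=c_side,
        parity_ok=parity_ok,
    )
    model.loops = _label_loops(n, n_side)
    return model


def _label_loops(n_tm: int, n_term_side: str) -> list[Loop]:
    loops = [Loop(0, n_term_side, "NTERM")]
    el = cl = 0
    side = n_term_side
    for i in range(1, n_tm):
        side = _flip(side)
        if side == LUMEN:
            el += 1
            loops.append(Loop(i, side, f"EL{el}"))
        else:
            cl += 1
            loops.append(Loop(i, side, f"CL{cl}"))
    side = _flip(side) if n_tm >= 1 else side
    loops.append(Loop(n_tm, side, "CTERM"))
    return loops


def assign_loop_sides(model: TopologyModel, known_terminus: tuple[str, str]) -> TopologyModel:
    """Re-derive sided, numbered loops by alternation from a known terminus.

    ``known_terminus`` is ('n'|'c', side).  Requires a parity-consistent
    model.
    """
    if not model.parity_ok:
        raise TopologyError("cannot assign loop sides: parity violated")
    rebuilt = _build_model(model.tms, known_terminus, None)
    model.loops = rebuilt.loops
    model.n_term_side = rebuilt.n_term_side
    model.c_term_side = rebuilt.c_term_side
    return model


# ---------------------------------------------------------------------------
# cross-family / cross-sequence discrepancies


def cross_family_discrepancies(
    alignment: Alignment,
    outputs: list[PredictorOutput],
    regions: list[CandidateRegion],
    support_threshold: float = 0.5,
    first_segment_signal_anchor: bool = False,
    family_of: dict[str, str] | None = None,
) -> DiscrepancyReport:
    """Classify members that fail to support a shared candidate region.

    For each region and each aligned sequence, the member-level support is
    the mean over predictors of the fraction of the member's non-gap span
    columns covered by that predictor.  Zero support is classed
    ``missing-in-sequence``; support below ``support_threshold`` is
    ``subthreshold``.  Region 1 is flagged ``signal-anchor-ambiguity``
    when the flag is set.  ``family_of`` only relabels the reported
    subject (e.g. a paralogue family name instead of the sequence id).
    """
    if len(alignment.rows) < 2:
        raise ValueError("cross-family comparison needs at least 2 rows")
    report = DiscrepancyReport()
    pos_of_col = {sid: alignment.position_of_column(sid) for sid in alignment.ids}
    for region in regions:
        c1, c2 = region.span
        for sid in alignment.ids:
            positions = pos_of_col[sid]
            span_pos = [positions[c - 1] for c in range(c1, c2 + 1)
                        if positions[c - 1] > 0]
            subject = family_of.get(sid, sid) if family_of else sid
            if not span_pos:
                report.items.append(Discrepancy(
                    region.index, subject, "missing-in-sequence",
                    "member has no residues under the region span (gap)",
                ))
                continue
            per_pred = []
            for out in outputs:
                segs = out.for_sequence(sid)
                covered = sum(
                    1 for p in span_pos if any(s.covers(p) for s in segs)
                )
                per_pred.append(covered / len(span_pos))
            support = float(np.mean(per_pred)) if per_pred else 0.0
            if support == 0.0:
                report.items.append(Discrepancy(
                    region.index, subject, "missing-in-sequence",
                    f"no predictor covers residues {min(span_pos)}-{max(span_pos)}",
                ))
            elif support < support_threshold:
                report.items.append(Discrepancy(
                    region.index, subject, "subthreshold",
                    f"member support {support:.3f} below {support_threshold}",
                ))
        if region.index == 1 and first_segment_signal_anchor:
            report.items.append(Discrepancy(
                region.index, "*", "signal-anchor-ambiguity",
                "most N-terminal region may be a signal anchor",
            ))
    return report
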