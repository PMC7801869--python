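"""Transmembrane-segment prediction from hydropathy profiles.

Two internal predictor families are provided so that an ensemble of
methodologically distinct callers can vote on a family alignment, the way
published TM-prediction suites are combined in practice:

* a sliding trapezoid-window hydropathy caller (``hydropathy_profile`` +
  ``call_segments``), run with different window shapes and scales;
* a global dynamic-programming segmenter (``dp_segmentation``) that places
  an optimal set of membrane segments under a loop penalty.

Externally produced predictions (e.g. from DAS-tmfilter, HMMTOP, PHOBIUS,
TMHMM or TOPPRED2, converted to TSV) join the ensemble through
``import_predictions``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import Sequence

# Kyte & Doolittle hydropathy values (dimensionless, 1 decimal).
KYTE_DOOLITTLE_VALUES = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Goldman-Engelman-Steitz transfer free energies (kcal/mol, hydrophobic > 0).
GES_VALUES = {
    "F": 3.7, "M": 3.4, "I": 3.1, "L": 2.8, "V": 2.6,
    "C": 2.0, "W": 1.9, "A": 1.6, "T": 1.2, "G": 1.0,
    "S": 0.6, "P": -0.2, "Y": -0.7, "H": -3.0, "Q": -4.1,
    "N": -4.8, "E": -8.2, "K": -8.8, "D": -9.2, "R": -12.3,
}


@dataclass(frozen=True)
class HydropathyScale:
    """A residue -> hydropathy mapping; unknown residues (X) score 0."""

    name: str
    values: dict

    def __post_init__(self) -> None:
        missing = set(KYTE_DOOLITTLE_VALUES) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if "X" not in self.values:
            object.__setattr__(self, "values", {**self.values, "X": 0.0})

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


KYTE_DOOLITTLE = HydropathyScale("kyte-doolittle", dict(KYTE_DOOLITTLE_VALUES))
GES = HydropathyScale("ges", dict(GES_VALUES))


@dataclass(frozen=True)
class WindowConfig:
    """Trapezoid averaging window.

    ``core_length`` residues get full weight; on each side ``taper_length``
    further residues get linearly decaying weight; all weights are
    normalised to sum to 1.  ``taper_length = 0`` gives a rectangular
    window.
    """

    core_length: int = 11
    taper_length: int = 5

    def __post_init__(self) -> None:
        if self.core_length < 1 or self.core_length % 2 == 0:
            raise ValueError("core_length must be odd and >= 1")
        if self.taper_length < 0:
            raise ValueError("taper_length must be >= 0")

    @property
    def total_length(self) -> int:
        return self.core_length + 2 * self.taper_length

    @property
    def half_width(self) -> int:
        return (self.total_length - 1) // 2

    def weights(self) -> np.ndarray:
        t = self.taper_length
        core = np.ones(self.core_length)
        if t:
            taper = np.arange(t, 0, -1) / (t + 1)  # decays away from the core
            w = np.concatenate([taper[::-1], core, taper])
        else:
            w = core
        return w / w.sum()


@dataclass
class TMSegment:
    """A predicted membrane-spanning segment, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    score: float = 0.0
    confidence: str = "certain"  # certain | putative
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.confidence not in ("certain", "putative"):
            raise ValueError(f"bad confidence {self.confidence!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class PredictorOutput:
    """All segments one predictor produced, keyed by sequence id."""

    predictor_id: str
    segments: dict[str, list[TMSegment]] = field(default_factory=dict)

    def for_sequence(self, seq_id: str) -> list[TMSegment]:
        return self.segments.get(seq_id, [])


@dataclass
class HydropathyProfile:
    """Per-position windowed hydropathy; NaN where no full window fits."""

    seq_id: str
    scores: np.ndarray  # length = sequence length; index = position - 1
    window: WindowConfig
    scale_name: str

    def defined_positions(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.scores)) + 1


def hydropathy_profile(
    seq: Sequence,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    window: WindowConfig = WindowConfig(),
) -> HydropathyProfile:
    """Windowed hydropathy profile of ``seq``.

    The score at a centre position is the normalised trapezoid-weighted
    mean of the scale values across the window; positions whose window
    would run off the sequence are left undefined (NaN) to avoid edge
    bias at the termini.
    """
    n = len(seq)
    if n < window.total_length:
        raise ValueError(
            f"sequence {seq.id!r} (length {n}) shorter than window "
            f"({window.total_length})"
        )
    values = np.array([scale[ch] for ch in seq.residues])
    w = window.weights()
    valid = np.convolve(values, w[::-1], mode="valid")  # symmetric w; reversed for clarity
    scores = np.full(n, np.nan)
    h = window.half_width
    scores[h:n - h] = valid
    return HydropathyProfile(seq.id, scores, window, scale.name)


def _split_run(run: tuple[int, int], scores: np.ndarray, half: int, max_len: int):
    """Recursively split a centre run whose expansion exceeds max_len at its
    lowest-scoring interior centre (the split centre drops out)."""
    s, e = run
    if (e - s + 1) + 2 * half <= max_len or e - s < 2:
        return [(s, e)]
    interior = np.arange(s + 1, e)  # 1-based positions strictly inside
    cut = interior[int(np.argmin(scores[interior - 1]))]
    return (_split_run((s, cut - 1), scores, half, max_len)
            + _split_run((cut + 1, e), scores, half, max_len))


def call_segments(
    profile: HydropathyProfile,
    upper_cutoff: float = 1.6,
    lower_cutoff: float = 1.0,
    min_len: int = 15,
    max_len: int = 30,
    source: str = "window",
) -> list[TMSegment]:
    """Call TM segments from a hydropathy profile.

    A segment is a maximal run of centres scoring above ``lower_cutoff``,
    expanded by half the core window on each side and clipped to the
    sequence.  A run containing a centre above ``upper_cutoff`` is called
    ``certain``, otherwise ``putative``.  Over-long runs are split at their
    weakest interior centre; where expansions of neighbouring runs collide
    the boundary is drawn at the midpoint of the valley between them;
    segments shorter than ``min_len`` after trimming are discarded.
    """
    if lower_cutoff > upper_cutoff:
        raise ValueError("lower_cutoff must be <= upper_cutoff")
    scores = profile.scores
    n = len(scores)
    half = (profile.window.core_length - 1) // 2
    above = np.flatnonzero(~np.isnan(scores) & (scores > lower_cutoff)) + 1
    if above.size == 0:
        return []
    # maximal runs of consecutive centres
    breaks = np.flatnonzero(np.diff(above) > 1)
    runs = []
    start = 0
    for b in breaks:
        runs.append((int(above[start]), int(above[b])))
        start = b + 1
    runs.append((int(above[start]), int(above[-1])))

    final_runs: list[tuple[int, int]] = []
    for run in runs:
        final_runs.extend(_split_run(run, scores, half, max_len))

    segs = []
    for rs, re_ in final_runs:
        seg_start = max(1, rs - half)
        seg_end = min(n, re_ + half)
        run_scores = scores[rs - 1:re_]
        conf = "certain" if np.any(run_scores > upper_cutoff) else "putative"
        segs.append([seg_start, seg_end, float(np.mean(run_scores)), conf, rs, re_])

    # trim colliding expansions at the midpoint of the valley between runs
    for a, b in zip(segs, segs[1:]):
        if a[1] >= b[0]:
            mid = (a[5] + b[4]) // 2  # between the two runs' centres
            a[1] = mid
            b[0] = mid + 1

    out = []
    for seg_start, seg_end, score, conf, _, _ in segs:
        if seg_end - seg_start + 1 >= min_len:
            out.append(
                TMSegment(profile.seq_id, seg_start, seg_end, score, conf, source)
            )
    return out


def dp_segmentation(
    seq: Sequence,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    tm_len_range: tuple[int, int] = (15, 30),
    loop_penalty: float = 10.0,
    source: str = "dp",
) -> list[TMSegment]:
    """Globally optimal membrane segmentation by dynamic programming.

    Maximises ``sum(hydropathy over TM residues) - loop_penalty * n_segments``
    over all segmentations whose segments have lengths in ``tm_len_range``
    and are separated by at least one loop residue.  Ties are broken by
    fewer segments, then by the lexicographically smallest tuple of segment
    starts.  Scoring is done in integer tenths of a scale unit (both
    built-in scales are 1-decimal), so tie handling is exact.
    """
    lo, hi = tm_len_range
    if not (12 <= lo <= hi <= 35):
        raise ValueError("tm_len_range must lie within [12, 35]")
    n = len(seq)
    deci = np.array([round(scale[ch] * 10) for ch in seq.residues], dtype=np.int64)
    prefix = np.concatenate([[0], np.cumsum(deci)])
    pen = round(loop_penalty * 10)

    # state: (score, n_segments, starts tuple); best = max score, min count,
    # min starts
    empty = (0, 0, ())
    best: list[tuple[int, int, tuple]] = [empty] * (n + 1)

    def better(a, b):
        if a[0] != b[0]:
            return a[0] > b[0]
        if a[1] != b[1]:
            return a[1] < b[1]
        return a[2] < b[2]

    for i in range(1, n + 1):
        cand = best[i - 1]  # residue i in loop state
        for length in range(lo, min(hi, i) + 1):
            s = i - length + 1
            prev = best[max(s - 2, 0)]
            score = prev[0] + int(prefix[i] - prefix[s - 1]) - pen
            trial = (score, prev[1] + 1, prev[2] + (s,))
            if better(trial, cand):
                cand = trial
        best[i] = cand

    # walk the table backwards to recover (start, end) pairs
    segs: list[TMSegment] = []
    i = n
    while i > 0:
        state = best[i]
        if state == best[i - 1]:
            i -= 1
            continue
        # a segment ends at i; find its start from the stored tuple
        s = state[2][-1]
        mean = float((prefix[i] - prefix[s - 1]) / (10.0 * (i - s + 1)))
        segs.append(TMSegment(seq.id, s, i, mean, "certain", source))
        i = s - 2
    segs.reverse()
    return segs


def import_predictions(
    path, predictor_id: str, sequences: list[Sequence] | None = None
) -> PredictorOutput:
    """Import external predictor output from TSV.

    Expected columns: ``seq_id``, ``start``, ``end``; optional ``score``
    and ``confidence``.  Rows are sorted; overlapping segments within one
    sequence, or segment ids not present in ``sequences`` (when given),
    are errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"seq_id", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"prediction TSV must have columns {sorted(required)}")
    known = {s.id: len(s) for s in sequences} if sequences is not None else None
    out = PredictorOutput(predictor_id=predictor_id)
    for seq_id, grp in df.groupby("seq_id", sort=False):
        seq_id = str(seq_id)
        if known is not None and seq_id not in known:
            raise ValueError(f"prediction references unknown sequence {seq_id!r}")
        grp = grp.sort_values("start")
        segs = []
        prev_end = 0
        for _, row in grp.iterrows():
            seg = TMSegment(
                seq_id=seq_id,
                start=int(row["start"]),
                end=int(row["end"]),
                score=float(row["score"]) if "score" in grp.columns else 0.0,
                confidence=str(row["confidence"]) if "confidence" in grp.columns
                else "certain",
                source=predictor_id,
            )
            if not (12 <= seg.length <= 35):
                raise ValueError(
                    f"segment {seg.start}-{seg.end} on {seq_id!r} has length "
                    f"{seg.length}, outside [12, 35]"
                )
            if seg.start <= prev_end:
                raise ValueError(
                    f"overlapping segments on {seq_id!r} in predictor "
                    f"{predictor_id!r} near position {seg.start}"
                )
            if known is not None and seg.end > known[seq_id]:
                raise ValueError(
                    f"segment end {seg.end} beyond length of {seq_id!r}"
                )
            prev_end = seg.end
            segs.append(seg)
        out.segments[seq_id] = segs
    return out


def write_predictions(outputs: list[PredictorOutput], path) -> None:
    """Write ensemble predictions to exchange TSV (one segment per row)."""
    with open(path, "w") as fh:
        fh.write("predictor_id\tseq_id\tstart\tend\tscore\tconfidence\n")
        for out in outputs:
            for segs in out.segments.values():
                for s in segs:
                    fh.write(
                        f"{out.predictor_id}\t{s.seq_id}\t{s.start}\t{s.end}"
                        f"\t{s.score:.4f}\t{s.confidence}\n"
                    )


# ---------------------------------------------------------------------------
# the builtin five-predictor ensemble


def builtin_ensemble(sequences: list[Sequence]) -> list[PredictorOutput]:
    """Run the five builtin predictors over all sequences.

    Five callers vote, mirroring the composition of the published
    TM-prediction suites that get combined in practice: three global
    segmenters (methodologically akin, hence partially correlated — the
    role the probabilistic model-based tools play in such suites) and two
    sliding-window callers on different hydropathy scales (the role of the
    classic window tools).  The global trio differs in loop penalty and
    admissible segment lengths; the window pair differs in scale.
    """
    window_specs = [
        ("kd-w11t5", KYTE_DOOLITTLE, WindowConfig(11, 5), 1.6, 1.0),
        ("ges-w11t5", GES, WindowConfig(11, 5), 2.0, 1.0),
    ]
    dp_specs = [
        ("dp-kd", 10.0, (15, 30)),
        ("dp-kd-lenient", 8.0, (12, 32)),
        ("dp-kd-strict", 12.0, (15, 30)),
    ]
    outputs = []
    for pid, scale, window, upper, lower in window_specs:
        out = PredictorOutput(predictor_id=pid)
        for seq in sequences:
            if len(seq) < window.total_length:
                out.segments[seq.id] = []
                continue
            prof = hydropathy_profile(seq, scale, window)
            out.segments[seq.id] = call_segments(
                prof, upper_cutoff=upper, lower_cutoff=lower, source=pid
            )
        outputs.append(out)
    for pid, penalty, len_range in dp_specs:
        out = PredictorOutput(predictor_id=pid)
        for seq in sequences:
            out.segments[seq.id] = dp_segmentation(
                seq, KYTE_DOOLITTLE, tm_len_range=len_range,
                loop_penalty=penalty, source=pid,
            )
        outputs.append(out)
    return outputs
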