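"""Trial domain types, tabular I/O, validation, and evidence binning.

A trial in the somatosensory evidence-accumulation task consists of two
independent trains of brief air puffs (left and right whiskers) delivered
over a cue period, followed by a memory delay, after which the animal
reports the side with more puffs by licking. Times are seconds from cue
onset; delay-period events are indexed as ``cue_duration + offset``.

The tabular schema (CSV or JSON) is one row/object per trial with columns::

    subject_id, session_id, trial_index, condition_label,
    cue_duration_s, delay_duration_s,
    puffs_left_s, puffs_right_s          (semicolon-delimited decimals)
    light_start_s, light_end_s           (empty if light off)
    light_side                           in {L, R, B, none}
    guided                               in {0, 1}
    choice                               in {L, R, none}
    correct_side                         in {L, R}
    decision_latency_s                   (optional; empty allowed)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Trial",
    "TrialSet",
    "EvidenceBins",
    "LightWindow",
    "CONDITION_LABELS",
    "MIN_INTERPUFF_GAP",
    "TrialParseError",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "validate_trial",
    "bin_evidence",
]

#: Minimum inter-puff interval enforced by the stimulus rig (s).
MIN_INTERPUFF_GAP = 0.2

#: Closed vocabulary of light-delivery / trial-type condition labels.
CONDITION_LABELS = frozenset(
    {
        "light-off",
        "full-cue",
        "first-third",
        "middle-third",
        "last-third",
        "delay",
        "delay-200ms",
        "delay-500ms",
        "guided",
    }
)

_SIDES = ("left", "right")
_LIGHT_SIDES = ("left", "right", "bilateral")

# numerical slack when checking gap/containment invariants on parsed floats
_EPS = 1e-9


class TrialParseError(ValueError):
    """A row/column of a trial file could not be parsed."""


class TrialValidationError(ValueError):
    """One or more trials violate the trial invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__(
            "trial validation failed:\n  " + "\n  ".join(violations)
        )


@dataclass(frozen=True)
class LightWindow:
    """Optogenetic light-delivery window, in seconds from cue onset."""

    start: float
    end: float
    side: str  # "left" | "right" | "bilateral"


@dataclass
class Trial:
    """One behavioral trial: stimulus times, timing structure, and outcome."""

    puffs_left: tuple[float, ...]
    puffs_right: tuple[float, ...]
    cue_duration: float
    delay_duration: float
    correct_side: str  # "left" | "right"
    choice: str = "none"  # "left" | "right" | "none"
    light_window: Optional[LightWindow] = None
    guided: bool = False
    decision_latency: Optional[float] = None
    condition_label: str = "light-off"

    def __post_init__(self) -> None:
        self.puffs_left = tuple(float(t) for t in self.puffs_left)
        self.puffs_right = tuple(float(t) for t in self.puffs_right)

    @property
    def n_left(self) -> int:
        """Number of cue-period left puffs."""
        return sum(1 for t in self.puffs_left if t < self.cue_duration)

    @property
    def n_right(self) -> int:
        """Number of cue-period right puffs."""
        return sum(1 for t in self.puffs_right if t < self.cue_duration)

    @property
    def delta(self) -> int:
        """Signed evidence strength #R − #L over the cue period."""
        return self.n_right - self.n_left

    @property
    def total_duration(self) -> float:
        return self.cue_duration + self.delay_duration

    def with_choice(self, choice: str) -> "Trial":
        return replace(self, choice=choice)


@dataclass
class TrialSet:
    """Ordered collection of trials with session/subject metadata."""

    trials: list[Trial]
    subject_id: str = "sim"
    session_id: str = "0"
    condition_label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return TrialSet(
                self.trials[idx], self.subject_id, self.session_id,
                self.condition_label,
            )
        return self.trials[idx]

    def filter(self, predicate) -> "TrialSet":
        return TrialSet(
            [t for t in self.trials if predicate(t)],
            self.subject_id, self.session_id, self.condition_label,
        )

    def decided(self) -> "TrialSet":
        """Trials on which a decision lick was made (choice != none)."""
        return self.filter(lambda t: t.choice != "none")

    def long_cue(self, cue: float = 3.8, atol: float = 1e-6) -> "TrialSet":
        """Trials with the primary (long) cue period."""
        return self.filter(lambda t: abs(t.cue_duration - cue) <= atol)

    def by_condition(self, label: str) -> "TrialSet":
        sub = self.filter(lambda t: t.condition_label == label)
        sub.condition_label = label
        return sub

    def validate(self, min_gap: float = MIN_INTERPUFF_GAP) -> None:
        """Raise :class:`TrialValidationError` if any trial is invalid."""
        violations: list[str] = []
        for i, t in enumerate(self.trials):
            for v in validate_trial(t, min_gap=min_gap):
                violations.append(f"trial {i}: {v}")
        if violations:
            raise TrialValidationError(violations)


@dataclass(frozen=True)
class EvidenceBins:
    """Per-trial #R − #L puff counts in uniform bins of the cue period."""

    counts: np.ndarray  # int, length n_bins
    edges: np.ndarray  # float, length n_bins + 1

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))


def validate_trial(
    trial: Trial, min_gap: float = MIN_INTERPUFF_GAP
) -> list[str]:
    """Check all trial invariants; return a description of each violation.

    An empty list means the trial is well formed. Guided trials are allowed
    delay-period guide puffs (on the single cued side), so their puff-time
    domain is ``[0, cue + delay)``; all other trials must confine puffs to
    the cue period ``[0, cue_duration)``.
    """
    v: list[str] = []
    cue, delay = trial.cue_duration, trial.delay_duration
    if not (cue > 0):
        v.append(f"cue_duration must be positive, got {cue}")
    if delay < 0:
        v.append(f"delay_duration must be non-negative, got {delay}")
    t_max = cue + delay if trial.guided else cue
    domain = "[0, cue+delay)" if trial.guided else "[0, cue_duration)"

    for side, times in (("left", trial.puffs_left), ("right", trial.puffs_right)):
        arr = np.asarray(times, dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() >= t_max):
            v.append(f"{side} puff times outside {domain}: {list(arr)}")
        if arr.size > 1:
            gaps = np.diff(arr)
            if np.any(gaps <= 0):
                v.append(f"{side} puff times not strictly increasing")
            elif np.any(gaps < min_gap - _EPS):
                v.append(
                    f"{side} inter-puff gap below minimum {min_gap} s "
                    f"(smallest gap {gaps.min():.4g} s)"
                )

    if trial.light_window is not None:
        lw = trial.light_window
        if lw.side not in _LIGHT_SIDES:
            v.append(f"light side must be one of {_LIGHT_SIDES}, got {lw.side!r}")
        if not (0 <= lw.start < lw.end <= cue + delay + _EPS):
            v.append(
                f"light window must satisfy 0 <= start < end <= cue+delay; "
                f"got [{lw.start}, {lw.end}] with cue+delay {cue + delay}"
            )

    if trial.correct_side not in _SIDES:
        v.append(f"correct_side must be left/right, got {trial.correct_side!r}")
    if trial.choice not in ("left", "right", "none"):
        v.append(f"choice must be left/right/none, got {trial.choice!r}")
    if trial.condition_label not in CONDITION_LABELS:
        v.append(f"unknown condition label {trial.condition_label!r}")

    n_l, n_r = trial.n_left, trial.n_right
    if trial.guided:
        if (n_l > 0) == (n_r > 0):
            v.append(
                "guided trial must have cue-period puffs on exactly one side "
                f"(got {n_l} left, {n_r} right)"
            )
    else:
        if n_l == n_r:
            v.append(
                f"tie trial (#R = #L = {n_r}): correct side undefined for "
                "non-guided trials"
            )
        elif trial.correct_side not in _SIDES:
            pass
        else:
            majority = "right" if n_r > n_l else "left"
            if trial.correct_side != majority:
                v.append(
                    f"correct_side {trial.correct_side!r} does not match side "
                    f"with more puffs ({majority}: {n_l} left vs {n_r} right)"
                )
    if trial.decision_latency is not None and trial.decision_latency < 0:
        v.append(f"decision_latency must be >= 0, got {trial.decision_latency}")
    return v


def bin_evidence(trial: Trial, n_bins: int = 3) -> EvidenceBins:
    """Bin cue-period evidence into `n_bins` temporally uniform bins.

    Bins are half-open ``[t_i, t_{i+1})``: a puff exactly at an interior edge
    belongs to the later bin. The counts are per-bin #R − #L and always sum
    to the trial total, because every cue-period puff falls in exactly one
    bin. Edges are ``i * cue_duration / n_bins`` in full precision.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    cue = trial.cue_duration
    if not cue > 0:
        raise ValueError("cue_duration must be positive")
    edges = np.linspace(0.0, cue, n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for sign, times in ((1, trial.puffs_right), (-1, trial.puffs_left)):
        for t in times:
            if t >= cue:  # guided delay puffs are not cue evidence
                continue
            # half-open convention; floor is exact for edge-coincident times
            idx = min(int(t * n_bins / cue), n_bins - 1)
            # guard against float round-down at exact interior edges
            if idx + 1 < n_bins and t >= edges[idx + 1]:
                idx += 1
            counts[idx] += sign
    return EvidenceBins(counts=counts, edges=edges)


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = [
    "subject_id", "session_id", "trial_index", "condition_label",
    "cue_duration_s", "delay_duration_s", "puffs_left_s", "puffs_right_s",
    "light_start_s", "light_end_s", "light_side", "guided", "choice",
    "correct_side", "decision_latency_s",
]

_SIDE_TO_CODE = {"left": "L", "right": "R", "bilateral": "B"}
_CODE_TO_SIDE = {v: k for k, v in _SIDE_TO_CODE.items()}
_CHOICE_TO_CODE = {"left": "L", "right": "R", "none": "none"}
_CODE_TO_CHOICE = {v: k for k, v in _CHOICE_TO_CODE.items()}


def _fmt_times(times: Sequence[float]) -> str:
    # repr() gives the shortest decimal that round-trips the float exactly
    return ";".join(repr(float(t)) for t in times)


def _parse_times(s: str, row: int, col: str) -> tuple[float, ...]:
    s = s.strip()
    if not s:
        return ()
    try:
        return tuple(float(x) for x in s.split(";"))
    except ValueError as e:
        raise TrialParseError(f"row {row}, column {col!r}: {e}") from None


def _trial_to_record(trial: Trial, subject: str, session: str, idx: int) -> dict:
    lw = trial.light_window
    return {
        "subject_id": subject,
        "session_id": session,
        "trial_index": idx,
        "condition_label": trial.condition_label,
        "cue_duration_s": repr(float(trial.cue_duration)),
        "delay_duration_s": repr(float(trial.delay_duration)),
        "puffs_left_s": _fmt_times(trial.puffs_left),
        "puffs_right_s": _fmt_times(trial.puffs_right),
        "light_start_s": "" if lw is None else repr(float(lw.start)),
        "light_end_s": "" if lw is None else repr(float(lw.end)),
        "light_side": "none" if lw is None else _SIDE_TO_CODE[lw.side],
        "guided": int(trial.guided),
        "choice": _CHOICE_TO_CODE[trial.choice],
        "correct_side": _CHOICE_TO_CODE[trial.correct_side],
        "decision_latency_s": (
            "" if trial.decision_latency is None
            else repr(float(trial.decision_latency))
        ),
    }


def _record_to_trial(rec: dict, row: int) -> Trial:
    def get(col: str) -> str:
        if col not in rec or rec[col] is None:
            if col == "decision_latency_s":
                return ""
            raise TrialParseError(f"row {row}: missing column {col!r}")
        return str(rec[col])

    def parse_float(col: str, required: bool = True) -> Optional[float]:
        s = get(col).strip()
        if not s:
            if required:
                raise TrialParseError(f"row {row}, column {col!r}: empty value")
            return None
        try:
            return float(s)
        except ValueError as e:
            raise TrialParseError(f"row {row}, column {col!r}: {e}") from None

    light_start = parse_float("light_start_s", required=False)
    light_end = parse_float("light_end_s", required=False)
    side_code = get("light_side").strip()
    if (light_start is None) != (light_end is None):
        raise TrialParseError(
            f"row {row}: light_start_s and light_end_s must both be set or "
            "both empty"
        )
    if light_start is not None:
        if side_code not in _CODE_TO_SIDE:
            raise TrialParseError(
                f"row {row}, column 'light_side': expected L/R/B, got "
                f"{side_code!r}"
            )
        lw = LightWindow(light_start, light_end, _CODE_TO_SIDE[side_code])
    else:
        lw = None

    choice_code = get("choice").strip()
    if choice_code not in _CODE_TO_CHOICE:
        raise TrialParseError(
            f"row {row}, column 'choice': expected L/R/none, got {choice_code!r}"
        )
    correct_code = get("correct_side").strip()
    if correct_code not in ("L", "R"):
        raise TrialParseError(
            f"row {row}, column 'correct_side': expected L/R, got "
            f"{correct_code!r}"
        )
    guided_s = get("guided").strip()
    if guided_s not in ("0", "1"):
        raise TrialParseError(
            f"row {row}, column 'guided': expected 0/1, got {guided_s!r}"
        )

    return Trial(
        puffs_left=_parse_times(get("puffs_left_s"), row, "puffs_left_s"),
        puffs_right=_parse_times(get("puffs_right_s"), row, "puffs_right_s"),
        cue_duration=parse_float("cue_duration_s"),
        delay_duration=parse_float("delay_duration_s"),
        light_window=lw,
        guided=guided_s == "1",
        choice=_CODE_TO_CHOICE[choice_code],
        correct_side=_CODE_TO_CHOICE[correct_code],
        decision_latency=parse_float("decision_latency_s", required=False),
        condition_label=get("condition_label").strip(),
    )


def write_trials(trials: TrialSet, path, format: str = "csv") -> None:
    """Write a validated TrialSet to `path` in the tabular schema.

    Event times are serialized with shortest round-trip decimals, so a
    write/read cycle reproduces them bit-identically.
    """
    trials.validate()
    path = Path(path)
    records = [
        _trial_to_record(t, trials.subject_id, trials.session_id, i)
        for i, t in enumerate(trials.trials)
    ]
    if format == "csv":
        lines = [",".join(_CSV_COLUMNS)]
        for rec in records:
            lines.append(",".join(str(rec[c]) for c in _CSV_COLUMNS))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def read_trials(path, format: Optional[str] = None) -> TrialSet:
    """Read and validate a TrialSet from a CSV or JSON trial file.

    Row order is preserved. Malformed rows raise :class:`TrialParseError`
    naming the row and column; invariant violations raise
    :class:`TrialValidationError` listing every violation found.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        text = path.read_text(encoding="utf-8")
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise TrialParseError(f"{path}: empty file")
        header = [h.strip() for h in lines[0].split(",")]
        records = []
        for i, ln in enumerate(lines[1:]):
            cells = ln.split(",")
            if len(cells) != len(header):
                raise TrialParseError(
                    f"row {i}: expected {len(header)} columns, got {len(cells)}"
                )
            records.append(dict(zip(header, cells)))
    elif format == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise TrialParseError(f"{path}: JSON root must be an array")
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")

    trials = [_record_to_trial(rec, i) for i, rec in enumerate(records)]
    subject = str(records[0]["subject_id"]) if records else "sim"
    session = str(records[0]["session_id"]) if records else "0"
    ts = TrialSet(trials, subject_id=subject, session_id=session)
    ts.validate()
    return ts
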