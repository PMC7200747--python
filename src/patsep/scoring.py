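"""Scoring of the mnemonic similarity (lure discrimination) task.

At retrieval the task shows exact repeats (targets), perceptually similar
objects (lures) and novel objects (foils); the participant answers "old",
"similar" or "new" for each.  Two bias-corrected scores summarise a session:

* LDI (lure discrimination index) = p("similar" | lure) - p("similar" | foil),
  the behavioural index of pattern separation;
* CRS (corrected recognition score) = p("old" | target) - p("old" | foil),
  plain target recognition.

Trials without a behavioural response are dropped from both numerator and
denominator, so every probability is conditioned on *valid* trials only.
The second judgement (quadrant / confidence) is parsed and stored but never
enters either score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Phase",
    "TrialType",
    "Response",
    "TrialRecord",
    "ResponseTable",
    "ScoreResult",
    "tabulate_responses",
    "compute_ldi",
    "compute_crs",
    "score_session",
    "read_trials_csv",
    "write_scores_csv",
]


class Phase(str, enum.Enum):
    ENCODING = "encoding"
    RETRIEVAL = "retrieval"


class TrialType(str, enum.Enum):
    TARGET = "target"
    LURE = "lure"
    FOIL = "foil"
    NONE = "none"  # encoding trials carry no retrieval condition


class Response(str, enum.Enum):
    OLD = "old"
    SIMILAR = "similar"
    NEW = "new"
    INDOOR = "indoor"  # encoding-phase judgements, kept but never scored
    OUTDOOR = "outdoor"
    NONE = "none"


#: second judgements are free-form but restricted to this vocabulary
SECOND_JUDGEMENTS = frozenset(
    {"quadrant1", "quadrant2", "quadrant3", "quadrant4", "sure", "unsure", "none"}
)

_RETRIEVAL_RESPONSES = (Response.OLD, Response.SIMILAR, Response.NEW)


@dataclass(frozen=True)
class TrialRecord:
    """A single task trial (encoding or retrieval)."""

    trial_id: int
    phase: Phase
    trial_type: TrialType
    response: Response
    second_judgement: str = "none"

    def __post_init__(self) -> None:
        if self.second_judgement not in SECOND_JUDGEMENTS:
            raise ValueError(
                f"malformed record: unknown second judgement {self.second_judgement!r}"
            )
        if self.phase is Phase.RETRIEVAL:
            if self.trial_type is TrialType.NONE:
                raise ValueError("malformed record: retrieval trial without a condition")
            if self.response not in (*_RETRIEVAL_RESPONSES, Response.NONE):
                raise ValueError(
                    f"malformed record: retrieval response {self.response.value!r}"
                )


@dataclass
class ResponseTable:
    """Counts of responses per retrieval condition, missing responses excluded.

    ``counts[(trial_type, response)]`` holds valid-response counts;
    ``valid_n[trial_type]`` the number of trials with any response,
    ``missing_n[trial_type]`` the number dropped for having none.
    """

    counts: dict[tuple[TrialType, Response], int] = field(default_factory=dict)
    valid_n: dict[TrialType, int] = field(default_factory=dict)
    missing_n: dict[TrialType, int] = field(default_factory=dict)

    def probability(self, trial_type: TrialType, response: Response) -> float:
        """p(response | trial_type) over valid trials of that type."""
        n = self.valid_n.get(trial_type, 0)
        if n == 0:
            raise ZeroDivisionError(
                f"undefined probability: no valid {trial_type.value} trials"
            )
        return self.counts.get((trial_type, response), 0) / n


@dataclass
class ScoreResult:
    ldi: float
    crs: float
    probabilities: dict[tuple[TrialType, Response], float]
    valid_counts: dict[TrialType, int]
    table: ResponseTable


def _coerce(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value).strip().lower())
    except ValueError:
        raise ValueError(
            f"malformed record: {value!r} is not a valid {enum_cls.__name__}"
        ) from None


def tabulate_responses(trials: Iterable[TrialRecord]) -> ResponseTable:
    """Tabulate retrieval responses per condition.

    Missing responses (``response == none``) are excluded from both the
    counts and the denominators; encoding trials are ignored entirely.
    """
    table = ResponseTable()
    n_retrieval = 0
    for t in trials:
        if t.phase is not Phase.RETRIEVAL:
            continue
        n_retrieval += 1
        tt = t.trial_type
        if t.response is Response.NONE:
            table.missing_n[tt] = table.missing_n.get(tt, 0) + 1
            table.valid_n.setdefault(tt, 0)
            continue
        key = (tt, t.response)
        table.counts[key] = table.counts.get(key, 0) + 1
        table.valid_n[tt] = table.valid_n.get(tt, 0) + 1
        table.missing_n.setdefault(tt, 0)
    if n_retrieval == 0:
        raise ValueError("empty session: no retrieval trials")
    return table


def compute_ldi(table: ResponseTable) -> float:
    """p("similar" | lure) - p("similar" | foil); in [-1, 1]."""
    return table.probability(TrialType.LURE, Response.SIMILAR) - table.probability(
        TrialType.FOIL, Response.SIMILAR
    )


def compute_crs(table: ResponseTable) -> float:
    """p("old" | target) - p("old" | foil); in [-1, 1]."""
    return table.probability(TrialType.TARGET, Response.OLD) - table.probability(
        TrialType.FOIL, Response.OLD
    )


def score_session(trials: Iterable[TrialRecord]) -> ScoreResult:
    """Tabulate a session and compute both scores.

    Raises if the session has no retrieval trials or if any probability
    entering a score has a zero-valid-trial denominator.
    """
    table = tabulate_responses(list(trials))
    probs: dict[tuple[TrialType, Response], float] = {}
    for tt in (TrialType.TARGET, TrialType.LURE, TrialType.FOIL):
        if table.valid_n.get(tt, 0) == 0:
            continue
        for r in _RETRIEVAL_RESPONSES:
            probs[(tt, r)] = table.probability(tt, r)
    return ScoreResult(
        ldi=compute_ldi(table),
        crs=compute_crs(table),
        probabilities=probs,
        valid_counts=dict(table.valid_n),
        table=table,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    """Read one session's trials from CSV.

    Expected columns: trial_id, phase, trial_type, response, second_judgement
    (header required; enum values case-insensitive).
    """
    df = pd.read_csv(path)
    required = {"trial_id", "phase", "trial_type", "response", "second_judgement"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrialRecord(
                trial_id=int(row.trial_id),
                phase=_coerce(row.phase, Phase),
                trial_type=_coerce(row.trial_type, TrialType),
                response=_coerce(row.response, Response),
                second_judgement=str(row.second_judgement).strip().lower(),
            )
        )
    return records


def write_scores_csv(
    scores: Mapping[str, ScoreResult], path: str | Path
) -> pd.DataFrame:
    """Write one row per session: id, scores and valid counts."""
    rows = []
    for pid, s in scores.items():
        rows.append(
            {
                "participant_id": pid,
                "ldi": s.ldi,
                "crs": s.crs,
                "valid_n_target": s.valid_counts.get(TrialType.TARGET, 0),
                "valid_n_lure": s.valid_counts.get(TrialType.LURE, 0),
                "valid_n_foil": s.valid_counts.get(TrialType.FOIL, 0),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
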