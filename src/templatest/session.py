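"""Core data containers: trials × neurons sessions and per-trial metadata.

A :class:`PopulationSession` holds a pre-windowed activity matrix — each row
is one trial's population vector (time-averaged ΔF/F for imaging data, or
spike counts in a fixed window for electrophysiology) — together with the
per-trial stimulus condition, behavioural outcome and optional covariates
such as pupil size. Every metric in the package consumes this container.
The analysis window itself is upstream preprocessing; it is carried only as
an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "TrialRecord",
    "PopulationSession",
    "ConditionTemplate",
    "CORRECT_OUTCOMES",
    "INCORRECT_OUTCOMES",
    "outcome_is_correct",
]

#: Behavioural outcome labels counted as correct / incorrect responses.
CORRECT_OUTCOMES = frozenset({"hit", "correct_rejection", "correct"})
INCORRECT_OUTCOMES = frozenset({"miss", "false_positive", "incorrect"})
KNOWN_OUTCOMES = CORRECT_OUTCOMES | INCORRECT_OUTCOMES


def outcome_is_correct(outcome: str) -> bool:
    """Map an outcome label to the binary correct/incorrect dichotomy.

    Hits and correct rejections are correct responses; misses and false
    positives are incorrect ones.
    """
    if outcome in CORRECT_OUTCOMES:
        return True
    if outcome in INCORRECT_OUTCOMES:
        return False
    raise ValidationError(f"unknown outcome label: {outcome!r}")


@dataclass(frozen=True)
class TrialRecord:
    """Metadata for one trial: identity, stimulus condition, behavioural
    outcome, and optional named covariates (e.g. pupil size, contrast
    difference)."""

    trial_id: str
    condition: str
    outcome: str
    covariates: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConditionTemplate:
    """Trial-averaged population vector λ for one condition."""

    condition: str
    mean_vector: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mean_vector", np.asarray(self.mean_vector, dtype=float)
        )
        if self.mean_vector.ndim != 1:
            raise ValidationError("template mean_vector must be 1-D")
        if self.n_trials < 1:
            raise ValidationError("template must average at least one trial")


@dataclass
class PopulationSession:
    """Trials × neurons activity matrix plus per-trial records.

    Parameters
    ----------
    responses
        Real matrix, shape ``(n_trials, n_neurons)``. ΔF/F values may be
        negative; under ``modality="counts"`` every entry must be a
        nonnegative integer.
    modality
        ``"continuous"`` or ``"counts"``.
    trial_records
        One :class:`TrialRecord` per matrix row, in row order.
    neuron_ids
        Unique identifier per column.
    """

    responses: np.ndarray
    modality: str
    trial_records: Sequence[TrialRecord]
    neuron_ids: Sequence[str]
    area_label: str = ""
    window_annotation: str = ""

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.trial_records = list(self.trial_records)
        self.neuron_ids = [str(n) for n in self.neuron_ids]
        if self.responses.ndim != 2:
            raise ValidationError("responses must be a 2-D trials × neurons matrix")
        if self.modality not in ("continuous", "counts"):
            raise ValidationError(f"unknown modality: {self.modality!r}")
        n_trials, n_neurons = self.responses.shape
        if len(self.trial_records) != n_trials:
            raise ValidationError(
                f"trial_records length {len(self.trial_records)} does not match "
                f"matrix row count {n_trials}"
            )
        if len(self.neuron_ids) != n_neurons:
            raise ValidationError(
                f"neuron_ids length {len(self.neuron_ids)} does not match "
                f"matrix column count {n_neurons}"
            )
        if len(set(self.neuron_ids)) != n_neurons:
            raise ValidationError("neuron_ids must be unique")
        ids = [r.trial_id for r in self.trial_records]
        if len(set(ids)) != len(ids):
            raise ValidationError("trial_ids must be unique")
        if not np.all(np.isfinite(self.responses)):
            raise ValidationError("responses must be finite")
        if self.modality == "counts":
            if np.any(self.responses < 0) or np.any(
                self.responses != np.round(self.responses)
            ):
                raise ValidationError(
                    "counts modality requires nonnegative integer entries"
                )
        for rec in self.trial_records:
            if rec.outcome not in KNOWN_OUTCOMES:
                raise ValidationError(
                    f"trial {rec.trial_id!r} has unknown outcome {rec.outcome!r}"
                )

    # -- basic introspection -------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for rec in self.trial_records:
            seen.setdefault(rec.condition, None)
        return list(seen)

    @property
    def trial_ids(self) -> list[str]:
        return [r.trial_id for r in self.trial_records]

    def record(self, trial_id: str) -> TrialRecord:
        for rec in self.trial_records:
            if rec.trial_id == trial_id:
                return rec
        raise ValidationError(f"unknown trial_id: {trial_id!r}")

    def row(self, trial_id: str) -> np.ndarray:
        return self.responses[self.trial_ids.index(trial_id)]

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([r.condition == condition for r in self.trial_records])

    # -- derived sessions ----------------------------------------------------

    def subset_neurons(self, indices: Sequence[int]) -> "PopulationSession":
        """Session restricted to the given neuron columns (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return PopulationSession(
            responses=self.responses[:, idx],
            modality=self.modality,
            trial_records=self.trial_records,
            neuron_ids=[self.neuron_ids[i] for i in idx],
            area_label=self.area_label,
            window_annotation=self.window_annotation,
        )

    def subset_trials(self, keep: Sequence[bool] | Sequence[int]) -> "PopulationSession":
        """Session restricted to a boolean mask or index list of trials."""
        arr = np.asarray(keep)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = arr.astype(int)
        return PopulationSession(
            responses=self.responses[idx],
            modality=self.modality,
            trial_records=[self.trial_records[i] for i in idx],
            neuron_ids=self.neuron_ids,
            area_label=self.area_label,
            window_annotation=self.window_annotation,
        )

    def with_responses(self, responses: np.ndarray) -> "PopulationSession":
        return replace(self, responses=responses)


def resolve_label(
    mapping: Mapping[str, str] | Callable[[TrialRecord], str],
    record: TrialRecord,
) -> str:
    """Resolve a per-trial condition label from a flexible specification.

    ``mapping`` may be a callable on the record, or a dict keyed by
    ``trial_id`` or by ``condition`` (trial_id takes precedence).
    """
    if callable(mapping):
        return mapping(record)
    if record.trial_id in mapping:
        return mapping[record.trial_id]
    if record.condition in mapping:
        return mapping[record.condition]
    raise ValidationError(
        f"no label for trial {record.trial_id!r} (condition {record.condition!r})"
    )


def two_condition_pairing(session: PopulationSession) -> dict[str, str]:
    """Default wrong-condition map for a two-condition session: the other one."""
    conds = session.conditions
    if len(conds) != 2:
        raise ValidationError(
            f"default pairing needs exactly 2 conditions, session has {len(conds)}"
        )
    return {conds[0]: conds[1], conds[1]: conds[0]}
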