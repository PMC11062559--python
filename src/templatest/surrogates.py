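"""Surrogate null models for single-trial population responses.

Two generators benchmark how much single-trial variability to expect if
trials were faithful random samples of the trial-averaged template:

* **Gaussian** (continuous ΔF/F data): per condition and neuron, draw
  i.i.d. normal values with that neuron's across-trial mean and variance.
  No truncation — ΔF/F is legitimately negative.
* **Poisson reallocation** (spike-count data): for each trial, redistribute
  its total spike count across neurons by one multinomial draw with
  probabilities λ_m/Σλ from the template. Every surrogate conserves the
  trial's total spike count exactly, so the ensemble tests the null of
  independent neurons sampling the average template.

Percentile bands of surrogate Specificity (median and e.g. 5th–95th
percentiles) are what real single-trial ρ distributions are plotted
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple

import numpy as np

from .exceptions import ComputationError, ValidationError
from .metrics import row_correlations
from .session import ConditionTemplate, PopulationSession, TrialRecord, resolve_label

__all__ = [
    "SurrogateEnsemble",
    "gaussian_surrogate",
    "poisson_reallocation_surrogate",
    "poisson_reallocation_ensemble",
    "surrogate_specificity_band",
    "SpecificityBand",
]


@dataclass
class SurrogateEnsemble:
    """Seeded bootstrap draws under one null generator.

    ``draws`` maps a provenance key — the condition label for the gaussian
    generator, the trial_id for poisson_reallocation — to an
    ``(n_surrogates, n_neurons)`` matrix of surrogate population vectors.
    """

    generator: str  # "gaussian" | "poisson_reallocation"
    n_surrogates: int
    seed: int
    draws: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def pooled(self) -> np.ndarray:
        """All surrogate vectors stacked into one matrix."""
        return np.vstack(list(self.draws.values()))


def gaussian_surrogate(
    session: PopulationSession,
    condition: str,
    n_surrogates: int = 200,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Gaussian null ensemble for one condition of a continuous session.

    For each neuron, draws are i.i.d. normal with the neuron's across-trial
    mean and (unbiased) variance within the condition; independent across
    neurons. The default of 200 draws per stimulus set matches the original
    calcium-imaging analysis. A neuron with zero trial-variance yields all
    draws equal to its mean.
    """
    if session.modality != "continuous":
        raise ValidationError(
            "gaussian surrogate requires continuous modality; "
            "use poisson_reallocation for spike counts"
        )
    if n_surrogates < 1:
        raise ValidationError("n_surrogates must be >= 1")
    mask = session.condition_mask(condition)
    n = int(mask.sum())
    if n < 2:
        raise ValidationError(
            f"condition {condition!r} has {n} trial(s); need >= 2 for a variance"
        )
    block = session.responses[mask]
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, size=(n_surrogates, session.n_neurons))
    return SurrogateEnsemble(
        generator="gaussian",
        n_surrogates=n_surrogates,
        seed=seed,
        draws={condition: draws},
        provenance={"condition": condition, "n_source_trials": n,
                    "area_label": session.area_label},
    )


def _reallocate_trial(
    total: int, template: ConditionTemplate, n_surrogates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    lam = np.asarray(template.mean_vector, dtype=float)
    if np.any(lam < 0):
        raise ValidationError("reallocation template must be nonnegative")
    s = lam.sum()
    if total > 0 and s == 0:
        raise ValidationError(
            "template has zero total mass but the trial has spikes"
        )
    if total == 0:
        return np.zeros((n_surrogates, lam.size), dtype=np.int64)
    return rng.multinomial(total, lam / s, size=n_surrogates)


def poisson_reallocation_surrogate(
    session: PopulationSession,
    trial_id: str,
    template: ConditionTemplate,
    n_surrogates: int = 100,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Spike-conserving null ensemble for one trial of a counts session.

    Each surrogate assigns the trial's total spike count to neurons by
    independent per-spike allocation with probabilities λ_m/Σλ (one
    multinomial draw), so the total is conserved exactly. Default ensemble
    size 100.
    """
    if session.modality != "counts":
        raise ValidationError("poisson_reallocation requires counts modality")
    if n_surrogates < 1:
        raise ValidationError("n_surrogates must be >= 1")
    total = int(round(float(session.row(trial_id).sum())))
    rng = np.random.default_rng(seed)
    draws = _reallocate_trial(total, template, n_surrogates, rng)
    return SurrogateEnsemble(
        generator="poisson_reallocation",
        n_surrogates=n_surrogates,
        seed=seed,
        draws={trial_id: draws},
        provenance={"trial_id": trial_id, "template_condition": template.condition,
                    "total_spikes": total, "area_label": session.area_label},
    )


def poisson_reallocation_ensemble(
    session: PopulationSession,
    templates: Mapping[str, ConditionTemplate],
    template_of: Mapping[str, str] | Callable[[TrialRecord], str],
    n_surrogates: int = 100,
    seed: int = 0,
) -> SurrogateEnsemble:
    """Per-trial reallocation ensembles for every trial of a counts session.

    ``template_of`` resolves which template each trial is downsampled from
    (normally its correct condition). Draws are keyed by trial_id; one seed
    stream covers the whole ensemble reproducibly.
    """
    if session.modality != "counts":
        raise ValidationError("poisson_reallocation requires counts modality")
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for i, rec in enumerate(session.trial_records):
        label = resolve_label(template_of, rec)
        if label not in templates:
            raise ValidationError(f"missing template for condition {label!r}")
        total = int(round(float(session.responses[i].sum())))
        draws[rec.trial_id] = _reallocate_trial(
            total, templates[label], n_surrogates, rng
        )
    return SurrogateEnsemble(
        generator="poisson_reallocation",
        n_surrogates=n_surrogates,
        seed=seed,
        draws=draws,
        provenance={"per_trial": True, "area_label": session.area_label},
    )


class SpecificityBand(NamedTuple):
    """Summary of the surrogate ρ distribution."""

    median: float
    lower: float
    upper: float
    per_key_median: dict[str, float]
    n_pooled: int


def surrogate_specificity_band(
    ensemble: SurrogateEnsemble,
    templates: Mapping[str, ConditionTemplate],
    correct_of: Mapping[str, str],
    wrong_of: Mapping[str, str],
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> SpecificityBand:
    """Median and percentile band of surrogate Specificity ρ.

    Computes ρ for every surrogate vector against the same correct/wrong
    templates used for real trials, pools across surrogates and across
    per-trial ensembles, and returns the pooled median plus the requested
    percentile band (linear-interpolation percentiles). Per-key medians are
    also returned so per-trial summaries remain available.
    """
    if not ensemble.draws:
        raise ValidationError("empty ensemble")
    lo_p, hi_p = percentiles
    pooled: list[np.ndarray] = []
    per_key: dict[str, float] = {}
    for key, matrix in ensemble.draws.items():
        correct_label = correct_of[key] if key in correct_of else None
        wrong_label = wrong_of[key] if key in wrong_of else None
        if correct_label is None or wrong_label is None:
            raise ValidationError(f"no correct/wrong mapping for key {key!r}")
        for lbl in (correct_label, wrong_label):
            if lbl not in templates:
                raise ValidationError(f"missing template for condition {lbl!r}")
        c_corr = row_correlations(matrix, templates[correct_label].mean_vector)
        c_wrong = row_correlations(matrix, templates[wrong_label].mean_vector)
        rho = c_corr - c_wrong
        rho = rho[~np.isnan(rho)]
        if rho.size:
            pooled.append(rho)
            per_key[key] = float(np.median(rho))
    if not pooled:
        raise ComputationError("all surrogate correlations undefined")
    allrho = np.concatenate(pooled)
    lo, med, hi = np.percentile(allrho, [lo_p, 50.0, hi_p], method="linear")
    return SpecificityBand(
        median=float(med), lower=float(lo), upper=float(hi),
        per_key_median=per_key, n_pooled=int(allrho.size),
    )
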