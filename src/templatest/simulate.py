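"""Generative model of template-matching behaviour, and fixture sessions.

The simulator generates a two-stimulus discrimination experiment from the
ground up:

1. **Stimuli** — per trial, two binary stimuli S1, S2 drawn i.i.d. from
   Bernoulli(p); the stimulus difference ΔS = S1 − S2 ∈ {−1, 0, 1} drives
   the neurons. ΔS = 0 trials have no correct response and are excluded
   from template matching.
2. **Population** — each of the (default 200) neurons has a baseline rate
   r⁰ ~ N(5, 1), a stimulus gain g ~ N(5, 1) and a signed selectivity
   ξ ∈ [−1, 1], obtained by shift-and-scale of Beta(β, β) draws: β < 1
   gives segregated preferences (mass near ±1), β > 1 homogeneous ones.
3. **Rates and spikes** — r = ReLU(r⁰ + g·ξ·ΔS) + |N(0, σ²)| with
   σ = gain_mean / snr, and spike counts s ~ Poisson(r).
4. **Decision** — the Specificity Index ρ of each trial (against empirical
   templates for ΔS = ±1, as an analyst would compute them) is perturbed,
   ψ′ = ρ + N(0, q²), squashed through a sigmoid p = 1/(1+e^(−ψ′)), and the
   trial is a hit iff p ≥ 0.5.

Landscape sweeps map median ρ over a β × SNR grid and Ω over a β × q grid,
optionally masking cells compatible with a measured value
(|measured − modelled| < 0.05 by default).

The fixture generators emulate the two experimental data styles end-to-end
(continuous ΔF/F with hit/miss/CR/FP outcomes; integer spike counts with
hit/miss outcomes and optional latent trial modes plus a covariate) with
controllable ground-truth separation and decision noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .exceptions import ValidationError
from .metrics import (
    RelevanceResult,
    SpecificityResult,
    behavioural_relevance,
    compute_templates,
    row_correlations,
    specificity_index,
)
from .session import ConditionTemplate, PopulationSession, TrialRecord

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "SimulationResult",
    "LandscapeResult",
    "draw_stimuli",
    "draw_population",
    "simulate_rates",
    "simulate_spikes",
    "simulate_decision",
    "run_simulation",
    "sweep_landscape",
    "make_continuous_fixture",
    "make_count_fixture",
]

# stage indices for per-stage seed streams: adding a stage never perturbs
# the draws of earlier ones
_STAGES = {"stimuli": 0, "population": 1, "rate_noise": 2, "spikes": 3, "decision": 4}

COND_POS = "dS+1"
COND_NEG = "dS-1"


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    ``snr`` controls the background-noise scale through
    ``noise_sd = gain_mean / snr``; the default snr = 5 with gain_mean = 5
    gives the unit-variance background term. ``decision_noise_q`` is the
    standard deviation of the Gaussian perturbation of ρ before the
    sigmoid choice.
    """

    n_neurons: int = 200
    n_trials: int = 400
    p1: float = 0.5
    p2: float = 0.5
    beta: float = 1.0
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    gain_mean: float = 5.0
    gain_sd: float = 1.0
    snr: float = 5.0
    decision_noise_q: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValidationError("n_neurons must be >= 2")
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        for name in ("p1", "p2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.beta <= 0:
            raise ValidationError("beta must be > 0")
        if self.snr <= 0:
            raise ValidationError("snr must be > 0")
        if self.decision_noise_q < 0:
            raise ValidationError("decision_noise_q must be >= 0")
        if self.baseline_sd < 0 or self.gain_sd < 0:
            raise ValidationError("standard deviations must be >= 0")

    @property
    def noise_sd(self) -> float:
        return self.gain_mean / self.snr


@dataclass
class SimulatedPopulation:
    """Ground-truth neuron parameters: selectivity ξ ∈ [−1, 1], baseline
    rate and stimulus gain."""

    xi: np.ndarray
    baseline: np.ndarray
    gain: np.ndarray


def draw_stimuli(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial stimuli (S1, S2, ΔS) with S ~ Bernoulli(p) i.i.d.

    ΔS = S1 − S2; at p1 = p2 = 0.5 the two informative values ±1 each occur
    with probability 0.25 and ΔS = 0 with probability 0.5.
    """
    rng = rng or _stage_rng(config.seed, "stimuli")
    s1 = (rng.random(config.n_trials) < config.p1).astype(np.int64)
    s2 = (rng.random(config.n_trials) < config.p2).astype(np.int64)
    return s1, s2, s1 - s2


def draw_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedPopulation:
    """Draw neuron selectivities, baselines and gains.

    ξ_raw ~ Beta(β, β) shifted and scaled to [−1, 1] (β = 1 is uniform);
    baselines and gains are i.i.d. normal with the configured parameters.
    """
    rng = rng or _stage_rng(config.seed, "population")
    xi = 2.0 * rng.beta(config.beta, config.beta, size=config.n_neurons) - 1.0
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_neurons)
    gain = rng.normal(config.gain_mean, config.gain_sd, config.n_neurons)
    return SimulatedPopulation(xi=xi, baseline=baseline, gain=gain)


def simulate_rates(
    population: SimulatedPopulation,
    delta_s: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Firing rates r_ij = ReLU(r⁰_j + g_j·ξ_j·ΔS_i) + |N(0, noise_sd²)|."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = rng or _stage_rng(seed, "rate_noise")
    delta_s = np.asarray(delta_s)
    drive = population.baseline[None, :] + (
        population.gain * population.xi
    )[None, :] * delta_s[:, None]
    rates = np.maximum(drive, 0.0)
    if noise_sd > 0:
        rates = rates + np.abs(rng.normal(0.0, noise_sd, size=rates.shape))
    return rates


def simulate_spikes(
    rates: np.ndarray,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Spike counts s_ij ~ Poisson(r_ij), independent across cells."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValidationError("rates must be nonnegative")
    rng = rng or _stage_rng(seed, "spikes")
    return rng.poisson(rates)


def simulate_decision(
    rho_base: np.ndarray,
    q: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noisy sigmoid choice on the Specificity Index.

    ψ′ = ρ + N(0, q²); p = 1/(1 + e^(−ψ′)); outcome 1 (hit) iff p ≥ 0.5,
    equivalently ψ′ ≥ 0. The tie at exactly 0.5 counts as a hit.
    """
    if q < 0:
        raise ValidationError("decision noise q must be >= 0")
    rng = rng or _stage_rng(seed, "decision")
    rho_base = np.asarray(rho_base, dtype=float)
    psi = rho_base + (rng.normal(0.0, q, size=rho_base.shape) if q > 0 else 0.0)
    prob = expit(psi)
    outcome = (prob >= 0.5).astype(np.int64)
    return psi, prob, outcome


@dataclass
class SimulationResult:
    """Everything one simulated experiment produced.

    Raw per-trial arrays cover all trials; ``included`` marks ΔS ≠ 0
    trials, which alone enter templates, Specificity, the decision stage
    and Ω. ``session`` is the counts-modality view of the included trials
    with hit/miss outcomes, ready for any analysis in the package.
    """

    config: SimulationConfig
    s1: np.ndarray
    s2: np.ndarray
    delta_s: np.ndarray
    population: SimulatedPopulation
    rates: np.ndarray
    spikes: np.ndarray
    included: np.ndarray  # bool, ΔS != 0
    session: PopulationSession
    templates: dict[str, ConditionTemplate]
    specificity: SpecificityResult
    psi_noisy: np.ndarray
    decision_probability: np.ndarray
    outcome: np.ndarray
    relevance: RelevanceResult

    def median_rho(self) -> float:
        return self.specificity.median_rho()


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Full pipeline: stimuli → population → rates → spikes → empirical
    templates → ρ → noisy decision → Ω.

    Templates for ΔS = +1 and ΔS = −1 are the trial averages of the
    simulated spike counts (what an analyst could compute), not the
    ground-truth rate profiles. Ω compares ρ of hit vs miss trials.
    Bit-reproducible for identical config (one master seed spawns
    independent per-stage streams).
    """
    s1, s2, delta_s = draw_stimuli(config)
    included = delta_s != 0
    if int((delta_s == 1).sum()) < 2 or int((delta_s == -1).sum()) < 2:
        raise ValidationError(
            "need >= 2 trials with dS=+1 and >= 2 with dS=-1 to form templates; "
            "increase n_trials"
        )
    population = draw_population(config)
    rates = simulate_rates(population, delta_s, config.noise_sd, seed=config.seed)
    spikes = simulate_spikes(rates, seed=config.seed)

    idx = np.flatnonzero(included)
    records = [
        TrialRecord(
            trial_id=f"t{i:05d}",
            condition=COND_POS if delta_s[i] > 0 else COND_NEG,
            outcome="hit",  # placeholder until the decision stage below
        )
        for i in idx
    ]
    # build a provisional session for templates/specificity; outcomes are
    # attached afterwards because they depend on rho
    session = PopulationSession(
        responses=spikes[idx],
        modality="counts",
        trial_records=records,
        neuron_ids=[f"n{j:04d}" for j in range(config.n_neurons)],
        area_label="simulated",
        window_annotation="per-trial spike count",
    )
    templates = compute_templates(session)
    pairing = {COND_POS: COND_NEG, COND_NEG: COND_POS}
    spec = specificity_index(
        session, templates, correct_of=lambda r: r.condition,
        wrong_of=pairing,
    )
    # decision uses rho in the original included-trial order; excluded
    # (zero-variance) trials, if any, get no decision
    psi, prob, outcome = simulate_decision(
        spec.rho, config.decision_noise_q, seed=config.seed
    )
    outcome_by_id = dict(zip(spec.trial_ids, outcome))
    final_records = [
        TrialRecord(
            trial_id=rec.trial_id,
            condition=rec.condition,
            outcome="hit" if outcome_by_id.get(rec.trial_id, 0) else "miss",
        )
        for rec in records
    ]
    session = PopulationSession(
        responses=spikes[idx],
        modality="counts",
        trial_records=final_records,
        neuron_ids=session.neuron_ids,
        area_label="simulated",
        window_annotation="per-trial spike count",
    )
    relevance = behavioural_relevance(
        spec.rho[outcome == 1], spec.rho[outcome == 0],
        groups_compared=("hit", "miss"),
    )
    return SimulationResult(
        config=config,
        s1=s1,
        s2=s2,
        delta_s=delta_s,
        population=population,
        rates=rates,
        spikes=spikes,
        included=included,
        session=session,
        templates=templates,
        specificity=spec,
        psi_noisy=psi,
        decision_probability=prob,
        outcome=outcome,
        relevance=relevance,
    )


# ---------------------------------------------------------------------------
# Parameter landscapes
# ---------------------------------------------------------------------------

@dataclass
class LandscapeResult:
    """Median ρ and Ω over a β × (SNR or q) grid of seeded replicates.

    ``median_rho[i, j]`` (and ``median_omega``) aggregate ``n_replicates``
    simulations at ``beta_grid[i]`` × ``axis_grid[j]``; ``mask`` marks
    cells compatible with a supplied measured value,
    |measured − modelled| < threshold.
    """

    beta_grid: list[float]
    axis_name: str  # "snr" | "q"
    axis_grid: list[float]
    median_rho: np.ndarray
    median_omega: np.ndarray
    n_replicates: int
    seed: int
    mask: np.ndarray | None = None
    measured_value: float | None = None
    threshold: float = 0.05


def _replicate_seed(seed: int, bi: int, ai: int, r: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(bi, ai, r))
    return int(ss.generate_state(1)[0] >> 1)  # keep below 2**31


def sweep_landscape(
    config_template: SimulationConfig,
    beta_grid: Sequence[float],
    snr_grid: Sequence[float] | None = None,
    q_grid: Sequence[float] | None = None,
    n_replicates: int = 50,
    seed: int = 0,
    measured_value: float | None = None,
    threshold: float = 0.05,
) -> LandscapeResult:
    """Sweep β against SNR (Specificity landscape) or against decision
    noise q at fixed SNR (Relevance landscape).

    Exactly one of ``snr_grid`` / ``q_grid`` must be given. Each cell runs
    ``n_replicates`` independent seeded simulations; the cell value is the
    across-replicate median of the per-simulation median ρ, and of Ω
    (NaN-aware, since Ω can be undefined when one outcome group is empty).
    The compatibility mask applies to median ρ for an SNR sweep and to Ω
    for a q sweep. Default threshold 0.05.
    """
    if (snr_grid is None) == (q_grid is None):
        raise ValidationError("provide exactly one of snr_grid or q_grid")
    if not list(beta_grid):
        raise ValidationError("beta_grid must be non-empty")
    axis_name = "snr" if snr_grid is not None else "q"
    axis_grid = list(snr_grid if snr_grid is not None else q_grid)
    if not axis_grid:
        raise ValidationError(f"{axis_name}_grid must be non-empty")
    beta_grid = list(beta_grid)

    med_rho = np.empty((len(beta_grid), len(axis_grid)))
    med_om = np.empty_like(med_rho)
    for bi, beta in enumerate(beta_grid):
        for ai, val in enumerate(axis_grid):
            rhos = np.empty(n_replicates)
            oms = np.full(n_replicates, np.nan)
            for r in range(n_replicates):
                kw = {"beta": beta, "seed": _replicate_seed(seed, bi, ai, r)}
                kw[axis_name if axis_name == "snr" else "decision_noise_q"] = val
                res = run_simulation(replace(config_template, **kw))
                rhos[r] = res.median_rho()
                if res.relevance.status == "ok":
                    oms[r] = res.relevance.omega
            med_rho[bi, ai] = np.median(rhos)
            med_om[bi, ai] = (
                np.nanmedian(oms) if np.any(~np.isnan(oms)) else np.nan
            )
    mask = None
    if measured_value is not None:
        target = med_rho if axis_name == "snr" else med_om
        mask = np.abs(measured_value - target) < threshold
    return LandscapeResult(
        beta_grid=beta_grid,
        axis_name=axis_name,
        axis_grid=axis_grid,
        median_rho=med_rho,
        median_omega=med_om,
        n_replicates=n_replicates,
        seed=seed,
        mask=mask,
        measured_value=measured_value,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Fixture sessions
# ---------------------------------------------------------------------------

def _sigmoid_outcomes(
    rho_truth: np.ndarray, link_slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli correct/incorrect per trial from a sigmoid link on the
    ground-truth match quality; an infinite slope is a deterministic
    threshold at 0 (ties resolved as correct)."""
    if math.isinf(link_slope):
        return rho_truth >= 0.0
    p = expit(link_slope * rho_truth)
    return rng.random(rho_truth.shape) < p


def _assign_outcome_counts(
    conditions: np.ndarray,
    outcome_counts: Mapping[str, Mapping[str, int]],
    rng: np.random.Generator,
) -> list[str]:
    out = [""] * conditions.size
    for cond, counts in outcome_counts.items():
        pos = np.flatnonzero(conditions == cond)
        if sum(counts.values()) != pos.size:
            raise ValidationError(
                f"outcome_counts for condition {cond!r} sum to "
                f"{sum(counts.values())}, but it has {pos.size} trials"
            )
        labels: list[str] = []
        for lbl, c in counts.items():
            labels.extend([lbl] * c)
        rng.shuffle(pos)
        for p, lbl in zip(pos, labels):
            out[p] = lbl
    if "" in out:
        raise ValidationError("outcome_counts must cover every condition")
    return out


def make_continuous_fixture(
    n_neurons: int = 40,
    n_trials_per_condition: int = 40,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    link_slope: float = 3.0,
    seed: int = 0,
    conditions: tuple[str, str] = ("stim", "no_stim"),
    outcome_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> PopulationSession:
    """Synthetic two-photon-style session: continuous ΔF/F responses, two
    conditions, hit/miss/CR/FP outcomes.

    Each neuron gets a baseline mean b ~ N(0, 1) and a signed condition
    preference u ~ N(0, 1); the two ground-truth templates are
    b ± (effect_size/2)·u and trials are template + N(0, noise_sd).
    Outcomes follow a sigmoid link of slope ``link_slope`` on the trial's
    ground-truth Specificity (infinite slope = noiseless threshold):
    correct responses map to hit (first condition) or correct_rejection
    (second), incorrect to miss / false_positive. ``outcome_counts``, if
    given, instead assigns outcome labels in exactly the configured
    numbers.
    """
    if n_neurons < 2 or n_trials_per_condition < 1:
        raise ValidationError("need >= 2 neurons and >= 1 trial per condition")
    if noise_sd < 0 or effect_size < 0:
        raise ValidationError("effect_size and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, 1.0, n_neurons)
    u = rng.normal(0.0, 1.0, n_neurons)
    mu = {
        conditions[0]: b + 0.5 * effect_size * u,
        conditions[1]: b - 0.5 * effect_size * u,
    }
    cond_arr = np.array(
        [conditions[0]] * n_trials_per_condition
        + [conditions[1]] * n_trials_per_condition
    )
    rng.shuffle(cond_arr)
    n_total = cond_arr.size
    responses = np.empty((n_total, n_neurons))
    for i, c in enumerate(cond_arr):
        responses[i] = mu[c] + rng.normal(0.0, noise_sd, n_neurons)

    other = {conditions[0]: conditions[1], conditions[1]: conditions[0]}
    rho_truth = np.empty(n_total)
    for c in conditions:
        mask = cond_arr == c
        rho_truth[mask] = row_correlations(
            responses[mask], mu[c]
        ) - row_correlations(responses[mask], mu[other[c]])
    rho_truth = np.nan_to_num(rho_truth, nan=0.0)

    if outcome_counts is not None:
        outcomes = _assign_outcome_counts(cond_arr, outcome_counts, rng)
    else:
        correct = _sigmoid_outcomes(rho_truth, link_slope, rng)
        outcomes = [
            ("hit" if ok else "miss")
            if c == conditions[0]
            else ("correct_rejection" if ok else "false_positive")
            for c, ok in zip(cond_arr, correct)
        ]
    records = [
        TrialRecord(trial_id=f"t{i:04d}", condition=c, outcome=o)
        for i, (c, o) in enumerate(zip(cond_arr, outcomes))
    ]
    return PopulationSession(
        responses=responses,
        modality="continuous",
        trial_records=records,
        neuron_ids=[f"n{j:03d}" for j in range(n_neurons)],
        area_label="synthetic-continuous",
        window_annotation="synthetic pre-averaged window",
    )


def make_count_fixture(
    n_neurons: int = 40,
    n_trials_per_condition: int = 40,
    rate_base: float = 5.0,
    rate_effect: float = 2.0,
    link_slope: float = 3.0,
    seed: int = 0,
    conditions: tuple[str, str] = ("left", "right"),
    latent_modes: bool = False,
    mode_effect: float = 2.0,
    mode_mix: float = 1.0,
    covariate_name: str | None = None,
    outcome_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> PopulationSession:
    """Synthetic electrophysiology-style session: Poisson spike counts,
    two conditions, hit/miss outcomes, optional latent trial modes and a
    covariate column.

    Neurons have baselines b ~ N(rate_base, 1) and selectivities
    ξ ~ U[−1, 1]; the condition rate profiles are ReLU(b ± rate_effect·ξ).
    With ``latent_modes`` each trial belongs to one of two hidden response
    modes — the structure trial clustering and grouped metrics are meant
    to uncover. A mode does two things: it shifts all rates by
    ±mode_effect·m (m ~ N(0, 1) per neuron), which makes the states
    clusterable; and it remixes the selectivity pattern (``mode_mix`` = 0
    keeps one shared ξ, 1 gives each mode an independent ξ), so that
    pooling trials across modes blurs the condition templates and
    within-mode Specificity exceeds the pooled one. The mode index is
    recorded as covariate ``"mode"``; ``covariate_name`` adds a noisy
    covariate tracking it (pure noise without modes). Outcomes are
    hit/miss through the sigmoid link on ground-truth Specificity, as in
    :func:`make_continuous_fixture`.
    """
    if n_neurons < 2 or n_trials_per_condition < 1:
        raise ValidationError("need >= 2 neurons and >= 1 trial per condition")
    if rate_base < 0 or rate_effect < 0:
        raise ValidationError("rate_base and rate_effect must be >= 0")
    if not 0.0 <= mode_mix <= 1.0:
        raise ValidationError("mode_mix must be in [0, 1]")
    rng = np.random.default_rng(seed)
    b = rng.normal(rate_base, 1.0, n_neurons)
    xi = rng.uniform(-1.0, 1.0, n_neurons)
    if latent_modes:
        xi_alt = rng.uniform(-1.0, 1.0, n_neurons)
        xi_by_mode = [xi, (1.0 - mode_mix) * xi + mode_mix * xi_alt]
        m = rng.normal(0.0, 1.0, n_neurons)
    else:
        xi_by_mode = [xi, xi]
        m = np.zeros(n_neurons)
    sign = {conditions[0]: 1.0, conditions[1]: -1.0}

    def _profile(c: str, mode: int) -> np.ndarray:
        shift = mode_effect * m * (1.0 if mode == 1 else -1.0)
        return np.maximum(b + sign[c] * rate_effect * xi_by_mode[mode] + shift, 0.0)

    cond_arr = np.array(
        [conditions[0]] * n_trials_per_condition
        + [conditions[1]] * n_trials_per_condition
    )
    rng.shuffle(cond_arr)
    n_total = cond_arr.size
    modes = rng.integers(0, 2, n_total) if latent_modes else np.zeros(n_total, dtype=int)
    rates = np.empty((n_total, n_neurons))
    for i, c in enumerate(cond_arr):
        rates[i] = _profile(c, int(modes[i]))
    counts = rng.poisson(rates)

    # ground-truth match quality is judged against the trial's own
    # (condition, mode) profile pair, which is what a perfect observer
    # of the latent state would use
    other = {conditions[0]: conditions[1], conditions[1]: conditions[0]}
    rho_truth = np.empty(n_total)
    for c in conditions:
        for mode in (0, 1):
            mask = (cond_arr == c) & (modes == mode)
            if not mask.any():
                continue
            rho_truth[mask] = row_correlations(
                counts[mask].astype(float), _profile(c, mode)
            ) - row_correlations(counts[mask].astype(float), _profile(other[c], mode))
    rho_truth = np.nan_to_num(rho_truth, nan=0.0)

    if outcome_counts is not None:
        outcomes = _assign_outcome_counts(cond_arr, outcome_counts, rng)
    else:
        correct = _sigmoid_outcomes(rho_truth, link_slope, rng)
        outcomes = ["hit" if ok else "miss" for ok in correct]

    records = []
    for i, (c, o) in enumerate(zip(cond_arr, outcomes)):
        cov: dict[str, float] = {}
        if latent_modes:
            cov["mode"] = float(modes[i])
        if covariate_name is not None:
            centre = float(modes[i]) if latent_modes else 0.0
            cov[covariate_name] = centre + float(rng.normal(0.0, 0.3))
        records.append(
            TrialRecord(trial_id=f"t{i:04d}", condition=c, outcome=o, covariates=cov)
        )
    return PopulationSession(
        responses=counts,
        modality="counts",
        trial_records=records,
        neuron_ids=[f"n{j:03d}" for j in range(n_neurons)],
        area_label="synthetic-counts",
        window_annotation="synthetic fixed-window spike counts",
    )
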