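"""Neuron-level and trial-group-level dissections of Specificity.

* jackknife: remove one neuron at a time, recompute each trial's ρ, and
  report the per-(trial, neuron) contribution n·ρ − (n−1)·ρ_without, whose
  right tail flags "super-coder" neurons;
* selection of the top/bottom fraction of neurons by jackknifed
  contribution;
* neuron-subsampling curves of median ρ and Ω;
* unsupervised trial clustering (standardized responses, k-means, k chosen
  by mean silhouette) to expose latent trial states;
* recomputation of all metrics within trial groups (clusters, covariate
  splits such as pupil size, easy/difficult conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .exceptions import ComputationError, ValidationError
from .metrics import (
    RelevanceResult,
    SpecificityResult,
    behavioural_relevance,
    compute_templates,
    specificity_index,
    yule_kendall,
)
from .session import (
    PopulationSession,
    TrialRecord,
    outcome_is_correct,
    resolve_label,
)

__all__ = [
    "JackknifeResult",
    "jackknife_contributions",
    "select_extreme_neurons",
    "subsample_metrics",
    "SubsampleResult",
    "cluster_trials",
    "ClusterResult",
    "metrics_by_group",
    "GroupedMetrics",
    "GroupMetrics",
    "covariate_split",
]


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    """Leave-one-neuron-out contributions to per-trial Specificity.

    ``contributions[i, j] = n·ρ_i − (n−1)·ρ_i^(¬j)`` where n is the neuron
    count and ρ_i^(¬j) is trial i's Specificity with neuron j removed from
    both the trial vector and the templates. Cells where either ρ is
    undefined are NaN. γ (Yule–Kendall skewness) summarizes how symmetric
    each contribution distribution is around its centre; the pooled γ is
    the headline number, per-neuron γ values are kept alongside.
    """

    trial_ids: list[str]
    neuron_ids: list[str]
    contributions: np.ndarray  # (n_trials_included, n_neurons)
    base_rho: np.ndarray
    neuron_median: np.ndarray
    gamma_per_neuron: np.ndarray
    gamma_pooled: float

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)


def jackknife_contributions(
    session: PopulationSession,
    correct_of: Mapping[str, str] | Callable[[TrialRecord], str],
    wrong_of: Mapping[str, str] | Callable[[TrialRecord], str],
) -> JackknifeResult:
    """Compute leave-one-neuron-out Specificity contributions.

    Templates are recomputed for every deletion (dropping a neuron simply
    drops its component of each per-neuron mean), so the jackknife identity
    holds exactly by construction.
    """
    n = session.n_neurons
    if n < 2:
        raise ValidationError("jackknife needs >= 2 neurons")
    base = specificity_index(session, compute_templates(session), correct_of, wrong_of)
    base_ids = base.trial_ids
    id_pos = {t: k for k, t in enumerate(base_ids)}
    contrib = np.full((len(base_ids), n), np.nan)

    for j in range(n):
        keep = [k for k in range(n) if k != j]
        sub = session.subset_neurons(keep)
        try:
            res_j = specificity_index(
                sub, compute_templates(sub), correct_of, wrong_of
            )
        except ComputationError:
            continue  # every trial undefined without neuron j
        for t, rho_del in zip(res_j.trial_ids, res_j.rho):
            if t in id_pos:
                i = id_pos[t]
                contrib[i, j] = n * base.rho[i] - (n - 1) * rho_del

    with np.errstate(invalid="ignore"):
        neuron_median = np.nanmedian(contrib, axis=0)
    gamma_per_neuron = np.full(n, np.nan)
    for j in range(n):
        col = contrib[:, j]
        col = col[~np.isnan(col)]
        if col.size >= 3:
            gamma_per_neuron[j] = yule_kendall(col)
    pooled = contrib[~np.isnan(contrib)]
    gamma_pooled = yule_kendall(pooled) if pooled.size >= 3 else float("nan")
    return JackknifeResult(
        trial_ids=base_ids,
        neuron_ids=list(session.neuron_ids),
        contributions=contrib,
        base_rho=base.rho.copy(),
        neuron_median=neuron_median,
        gamma_per_neuron=gamma_per_neuron,
        gamma_pooled=gamma_pooled,
    )


def select_extreme_neurons(
    jk: JackknifeResult,
    fraction: float = 0.10,
    which: str = "top",
) -> list[str]:
    """Neurons with the largest (``top``) or smallest (``bottom``) median
    jackknifed contribution.

    Returns ``ceil(fraction · n_neurons)`` neuron ids; ties broken by
    neuron index (stable), NaN medians ranked last in either direction.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValidationError("fraction must be in (0, 0.5]")
    if which not in ("top", "bottom"):
        raise ValidationError("which must be 'top' or 'bottom'")
    n = jk.n_neurons
    k = math.ceil(fraction * n)
    med = jk.neuron_median
    defined = np.flatnonzero(~np.isnan(med))
    if defined.size < k:
        raise ValidationError("not enough neurons with defined contributions")
    key = -med[defined] if which == "top" else med[defined]
    order = defined[np.argsort(key, kind="stable")]
    return [jk.neuron_ids[j] for j in order[:k]]


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

@dataclass
class SubsampleResult:
    """Per-fraction distributions of median ρ and Ω over random neuron
    subsets; no functional extrapolation is fitted."""

    fractions: list[float]
    n_neurons_used: dict[float, int]
    median_rho: dict[float, np.ndarray]  # fraction -> (n_repeats,)
    omega: dict[float, np.ndarray]  # NaN where Ω undefined
    n_repeats: int
    seed: int


def _session_relevance(
    spec: SpecificityResult,
    outcome_lookup: Mapping[str, bool],
    groups_compared: tuple[str, str] = ("correct", "incorrect"),
) -> RelevanceResult:
    x = spec.rho_by(lambda t: outcome_lookup[t])
    y = spec.rho_by(lambda t: not outcome_lookup[t])
    return behavioural_relevance(x, y, groups_compared=groups_compared)


def _outcome_lookup(
    session: PopulationSession,
    outcome_of: Callable[[TrialRecord], bool] | None,
) -> dict[str, bool]:
    fn = outcome_of or (lambda rec: outcome_is_correct(rec.outcome))
    return {rec.trial_id: bool(fn(rec)) for rec in session.trial_records}


def subsample_metrics(
    session: PopulationSession,
    correct_of: Mapping[str, str] | Callable[[TrialRecord], str],
    wrong_of: Mapping[str, str] | Callable[[TrialRecord], str],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    n_repeats: int = 20,
    seed: int = 0,
    outcome_of: Callable[[TrialRecord], bool] | None = None,
) -> SubsampleResult:
    """Median ρ and Ω over random neuron subsets at each population fraction.

    For each fraction, draws ``n_repeats`` subsets without replacement
    (``ceil(fraction · n)`` neurons), recomputes templates, ρ and Ω on the
    subset, and returns the full distributions. At fraction 1.0 every
    repeat reproduces the full-population values.
    """
    n = session.n_neurons
    sizes = {f: math.ceil(f * n) for f in fractions}
    for f, k in sizes.items():
        if k < 2:
            raise ValidationError(
                f"fraction {f} yields {k} neuron(s); need >= 2"
            )
        if k > n:
            raise ValidationError(f"fraction {f} exceeds 1.0")
    lookup = _outcome_lookup(session, outcome_of)
    rng = np.random.default_rng(seed)
    med: dict[float, np.ndarray] = {}
    om: dict[float, np.ndarray] = {}
    for f in fractions:
        k = sizes[f]
        m = np.empty(n_repeats)
        o = np.full(n_repeats, np.nan)
        for r in range(n_repeats):
            idx = rng.choice(n, size=k, replace=False)
            sub = session.subset_neurons(np.sort(idx))
            spec = specificity_index(
                sub, compute_templates(sub), correct_of, wrong_of
            )
            m[r] = spec.median_rho()
            rel = _session_relevance(spec, lookup)
            if rel.status == "ok":
                o[r] = rel.omega
        med[f] = m
        om[f] = o
    return SubsampleResult(
        fractions=list(fractions),
        n_neurons_used=sizes,
        median_rho=med,
        omega=om,
        n_repeats=n_repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Trial clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Trial-state partition chosen by mean silhouette over a k range."""

    labels: dict[str, int]  # trial_id -> cluster label for chosen k
    silhouette_by_k: dict[int, float]
    labels_by_k: dict[int, np.ndarray]
    chosen_k: int
    seed: int


def cluster_trials(
    session: PopulationSession,
    k_range: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
) -> ClusterResult:
    """Cluster trial response vectors and pick k by mean silhouette.

    Responses are standardized per neuron (so high-rate neurons do not
    dominate the Euclidean distance), partitioned by k-means with multiple
    restarts under one seed for each k in ``k_range``, and the k with the
    highest mean silhouette (Euclidean) is chosen. Deterministic under a
    fixed seed.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2:
        raise ValidationError("k_range must contain integers >= 2")
    if session.n_trials < max(k_range) + 1:
        raise ValidationError(
            f"need >= {max(k_range) + 1} trials for k up to {max(k_range)}"
        )
    X = StandardScaler().fit_transform(session.responses)
    if np.allclose(X, X[0]):
        raise ComputationError("all trials identical; clustering is degenerate")
    sil: dict[int, float] = {}
    labs: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        labs[k] = labels
        if len(np.unique(labels)) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
    chosen = max(k_range, key=lambda k: (sil[k], -k))
    return ClusterResult(
        labels={t: int(l) for t, l in zip(session.trial_ids, labs[chosen])},
        silhouette_by_k=sil,
        labels_by_k=labs,
        chosen_k=chosen,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Grouped metrics
# ---------------------------------------------------------------------------

@dataclass
class GroupMetrics:
    label: str
    n_trials: int
    median_rho: float
    relevance: RelevanceResult
    specificity: SpecificityResult


@dataclass
class GroupedMetrics:
    """Specificity/Relevance recomputed within trial groups.

    Groups below ``min_group_size`` are reported in ``skipped`` with a
    reason rather than silently vanishing; the pooled (ungrouped) baseline
    is included for comparison. Covers trial clusters, covariate median
    splits (e.g. pupil size) and easy/difficult condition splits through
    one contract.
    """

    grouping_name: str
    groups: list[GroupMetrics] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)
    pooled: GroupMetrics | None = None


def covariate_split(
    session: PopulationSession, covariate: str, n_bins: int = 2
) -> dict[str, str]:
    """Trial grouping by covariate quantile bin (default median split).

    Returns a trial_id → group-label map with labels like ``"pupil_q1"``.
    """
    vals = []
    for rec in session.trial_records:
        if covariate not in rec.covariates:
            raise ValidationError(
                f"trial {rec.trial_id!r} lacks covariate {covariate!r}"
            )
        vals.append(float(rec.covariates[covariate]))
    vals = np.asarray(vals)
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1), method="linear")
    # right-inclusive top bin
    bins = np.clip(np.searchsorted(edges[1:-1], vals, side="right"), 0, n_bins - 1)
    return {
        rec.trial_id: f"{covariate}_q{b + 1}"
        for rec, b in zip(session.trial_records, bins)
    }


def metrics_by_group(
    session: PopulationSession,
    grouping: Mapping[str, str] | Callable[[TrialRecord], str],
    correct_of: Mapping[str, str] | Callable[[TrialRecord], str],
    wrong_of: Mapping[str, str] | Callable[[TrialRecord], str],
    min_group_size: int = 4,
    grouping_name: str = "grouping",
    outcome_of: Callable[[TrialRecord], bool] | None = None,
) -> GroupedMetrics:
    """Recompute templates, ρ and Ω within each trial group.

    ``grouping`` maps trials to group labels (callable, or dict keyed by
    trial_id/condition). Each group meeting ``min_group_size`` gets its own
    templates and metrics; a pooled baseline over all trials is always
    included.
    """
    lookup = _outcome_lookup(session, outcome_of)
    labels = [resolve_label(grouping, rec) for rec in session.trial_records]
    result = GroupedMetrics(grouping_name=grouping_name)

    pooled_spec = specificity_index(
        session, compute_templates(session), correct_of, wrong_of
    )
    result.pooled = GroupMetrics(
        label="__pooled__",
        n_trials=pooled_spec.n_included,
        median_rho=pooled_spec.median_rho(),
        relevance=_session_relevance(pooled_spec, lookup),
        specificity=pooled_spec,
    )

    seen: dict[str, None] = {}
    for lbl in labels:
        seen.setdefault(lbl, None)
    any_ok = False
    for lbl in seen:
        mask = np.array([l == lbl for l in labels])
        n = int(mask.sum())
        if n < min_group_size:
            result.skipped.append((lbl, f"insufficient trials ({n} < {min_group_size})"))
            continue
        sub = session.subset_trials(mask)
        # a group may lose a condition entirely; templates then cannot be formed
        try:
            spec = specificity_index(
                sub, compute_templates(sub), correct_of, wrong_of
            )
        except (ValidationError, ComputationError) as exc:
            result.skipped.append((lbl, str(exc)))
            continue
        result.groups.append(
            GroupMetrics(
                label=lbl,
                n_trials=spec.n_included,
                median_rho=spec.median_rho(),
                relevance=_session_relevance(spec, lookup),
                specificity=spec,
            )
        )
        any_ok = True
    if not any_ok:
        raise ComputationError("no group meets min_group_size")
    return result
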