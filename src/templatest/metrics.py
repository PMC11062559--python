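"""Headline statistics: Specificity Index ρ and Behavioural Relevance Ω.

The Specificity Index of trial *i* is

    ρ_i = cor(λ_correct, r_i) − cor(λ_wrong, r_i)

where ``cor`` is the Pearson coefficient, λ the trial-averaged population
template of a condition and r_i the trial's population vector. Because each
correlation is bounded in [−1, 1], ρ is bounded in [−2, 2]; no further
normalization is applied since only its sign and tendencies are interpreted.

Behavioural Relevance compares the ρ values of behaviourally correct vs
incorrect trials through the Vargha–Delaney effect size A (the probability
that a random draw from one group exceeds a random draw from the other,
ties counted half, derived from the Mann–Whitney U statistic with mid-rank
tie handling):

    Ω = max(A, 1 − A)  ∈  [0.5, 1]

Ω = 0.5 for totally overlapping groups, 1 for complete stochastic
dominance, and is symmetric in the two groups.

Supporting statistics: the quartile-based Yule–Kendall skewness γ and the
per-neuron Fano factor (across-trial variance / mean; 1 under Poisson
spiking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ComputationError, ValidationError
from .session import ConditionTemplate, PopulationSession, TrialRecord, resolve_label

__all__ = [
    "pearson_correlation",
    "row_correlations",
    "compute_templates",
    "specificity_index",
    "mann_whitney_u",
    "vargha_delaney_A",
    "brute_force_A",
    "behavioural_relevance",
    "yule_kendall",
    "fano_factor",
    "SpecificityResult",
    "RelevanceResult",
    "MannWhitneyResult",
]


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment coefficient; NaN if either vector is constant.

    A zero-variance vector makes the coefficient undefined; NaN is returned
    as an explicit undefined-marker rather than imputing a value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError("need at least 2 points for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def row_correlations(matrix: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each matrix row with vector ``v`` (vectorized).

    Rows (or ``v``) with zero variance yield NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    v = np.asarray(v, dtype=float)
    if matrix.shape[1] != v.size:
        raise ValidationError("row length must match vector length")
    if v.size < 2:
        raise ValidationError("need at least 2 points for a correlation")
    mc = matrix - matrix.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    row_norm = np.sqrt(np.einsum("ij,ij->i", mc, mc))
    v_norm = math.sqrt(float(vc @ vc))
    denom = row_norm * v_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ vc) / denom
    r = np.where(denom == 0.0, np.nan, r)
    return np.clip(r, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def compute_templates(
    session: PopulationSession,
    conditions: Sequence[str] | None = None,
) -> dict[str, ConditionTemplate]:
    """Per-condition trial-averaged population vectors.

    ``mean_vector[j]`` is the arithmetic mean of neuron *j* across the
    condition's trials, in the session's own units.
    """
    if conditions is None:
        conditions = session.conditions
    out: dict[str, ConditionTemplate] = {}
    for cond in conditions:
        mask = session.condition_mask(cond)
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(f"condition {cond!r} has no trials")
        out[cond] = ConditionTemplate(
            condition=cond,
            mean_vector=session.responses[mask].mean(axis=0),
            n_trials=n,
        )
    return out


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

@dataclass
class SpecificityResult:
    """Per-trial template-matching correlations and ρ values.

    ``rho[k] = correlation_to_correct[k] − correlation_to_wrong[k]`` for the
    k-th included trial. Trials where either correlation is undefined are
    listed in ``excluded_trials`` with a reason, never silently dropped.
    """

    trial_ids: list[str]
    correlation_to_correct: np.ndarray
    correlation_to_wrong: np.ndarray
    rho: np.ndarray
    excluded_trials: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return len(self.trial_ids)

    def median_rho(self) -> float:
        return float(np.median(self.rho))

    def rho_by(self, predicate: Callable[[str], bool]) -> np.ndarray:
        """ρ values of the included trials whose trial_id satisfies ``predicate``."""
        keep = [predicate(t) for t in self.trial_ids]
        return self.rho[np.asarray(keep, dtype=bool)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_ids,
                "correlation_to_correct": self.correlation_to_correct,
                "correlation_to_wrong": self.correlation_to_wrong,
                "rho": self.rho,
            }
        )


def specificity_index(
    session: PopulationSession,
    templates: Mapping[str, ConditionTemplate],
    correct_of: Mapping[str, str] | Callable[[TrialRecord], str],
    wrong_of: Mapping[str, str] | Callable[[TrialRecord], str],
    leave_one_out: bool = False,
) -> SpecificityResult:
    """Per-trial Specificity Index against correct and wrong templates.

    Parameters
    ----------
    templates
        Condition → template map; must contain every label that
        ``correct_of``/``wrong_of`` resolve to.
    correct_of, wrong_of
        Per-trial label resolvers: a callable on the trial record, or a dict
        keyed by trial_id or condition.
    leave_one_out
        When the scored trial itself contributed to its correct template,
        recompute that template without it (requires ≥ 2 trials in the
        trial's condition). Self-inclusion inflates correlations for small
        trial counts; the default mirrors the simplest averaging procedure.
    """
    included_ids: list[str] = []
    cc: list[float] = []
    cw: list[float] = []
    excluded: list[tuple[str, str]] = []

    cond_counts = {c: int(session.condition_mask(c).sum()) for c in session.conditions}
    cond_sums = {
        c: session.responses[session.condition_mask(c)].sum(axis=0)
        for c in session.conditions
    }

    for i, rec in enumerate(session.trial_records):
        correct_label = resolve_label(correct_of, rec)
        wrong_label = resolve_label(wrong_of, rec)
        for lbl in (correct_label, wrong_label):
            if lbl not in templates:
                raise ValidationError(f"missing template for condition {lbl!r}")
        r_i = session.responses[i]
        lam_correct = templates[correct_label].mean_vector
        if leave_one_out and rec.condition == correct_label:
            n_c = cond_counts[rec.condition]
            if n_c < 2:
                excluded.append(
                    (rec.trial_id, "leave-one-out needs >= 2 trials in condition")
                )
                continue
            lam_correct = (cond_sums[rec.condition] - r_i) / (n_c - 1)
        lam_wrong = templates[wrong_label].mean_vector

        c1 = pearson_correlation(lam_correct, r_i)
        c2 = pearson_correlation(lam_wrong, r_i)
        if math.isnan(c1) or math.isnan(c2):
            which = []
            if math.isnan(c1):
                which.append("correct")
            if math.isnan(c2):
                which.append("wrong")
            excluded.append(
                (rec.trial_id, f"zero-variance correlation ({'/'.join(which)})")
            )
            continue
        included_ids.append(rec.trial_id)
        cc.append(c1)
        cw.append(c2)

    if not included_ids:
        raise ComputationError("all trials excluded; no Specificity defined")
    cc_arr = np.asarray(cc)
    cw_arr = np.asarray(cw)
    return SpecificityResult(
        trial_ids=included_ids,
        correlation_to_correct=cc_arr,
        correlation_to_wrong=cw_arr,
        rho=cc_arr - cw_arr,
        excluded_trials=excluded,
    )


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------

class MannWhitneyResult(NamedTuple):
    U: float
    U_X: float
    U_Y: float
    R_X: float
    R_Y: float
    n_X: int
    n_Y: int


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Mann–Whitney U with mid-rank tie handling.

    Pools both samples, ranks low-to-high assigning tied values the average
    of their pooled ranks, and forms the rank sums R_X, R_Y. Then
    U_X = R_X − n_X(n_X+1)/2 (the number of (x, y) pairs with x > y, ties
    counted half), symmetrically U_Y, and U = min(U_X, U_Y). The identity
    U_X + U_Y = n_X·n_Y always holds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]), method="average")
    r_x = float(ranks[:n_x].sum())
    r_y = float(ranks[n_x:].sum())
    u_x = r_x - n_x * (n_x + 1) / 2.0
    u_y = r_y - n_y * (n_y + 1) / 2.0
    return MannWhitneyResult(min(u_x, u_y), u_x, u_y, r_x, r_y, n_x, n_y)


def vargha_delaney_A(x: Sequence[float], y: Sequence[float]) -> float:
    """Vargha–Delaney effect size A(x, y) ∈ [0, 1] via the rank route.

    Equals the probability that a random draw from ``x`` exceeds one from
    ``y``, ties counted half: A = U_X / (n_X·n_Y). Agrees exactly with
    :func:`brute_force_A` on every input.
    """
    mw = mann_whitney_u(x, y)
    return mw.U_X / (mw.n_X * mw.n_Y)


def brute_force_A(x: Sequence[float], y: Sequence[float]) -> float:
    """Pairwise-enumeration oracle for the A effect size.

    Explicit double loop over all (x, y) pairs with half credit for exact
    ties; the normative definition against which the rank-based route is
    checked.
    """
    x = list(np.asarray(x, dtype=float))
    y = list(np.asarray(y, dtype=float))
    if not x or not y:
        raise ValidationError("both samples must be non-empty")
    wins = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                wins += 1.0
            elif xi == yj:
                wins += 0.5
    return wins / (len(x) * len(y))


@dataclass
class RelevanceResult:
    """Behavioural Relevance Ω of correct- vs incorrect-outcome ρ samples.

    ``status`` is ``"ok"`` when both groups meet the minimum size (2) and
    Ω = max(A, 1−A) is defined; otherwise ``"undefined"`` with the group
    sizes recorded and no fabricated number.
    """

    status: str
    omega: float | None
    A: float | None
    U: float | None
    rank_sums: tuple[float, float] | None
    group_sizes: tuple[int, int]
    groups_compared: tuple[str, str] = ("correct", "incorrect")
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "omega": self.omega,
            "A": self.A,
            "U": self.U,
            "rank_sums": list(self.rank_sums) if self.rank_sums else None,
            "group_sizes": list(self.group_sizes),
            "groups_compared": list(self.groups_compared),
            "reason": self.reason,
        }


def behavioural_relevance(
    spec_correct: Sequence[float],
    spec_incorrect: Sequence[float],
    groups_compared: tuple[str, str] = ("correct", "incorrect"),
) -> RelevanceResult:
    """Ω = max(A, 1−A) comparing ρ of correct vs incorrect outcome trials.

    Symmetric in its two arguments; bounded in [0.5, 1]. Groups with fewer
    than 2 members give a degenerate rank test, so the result is flagged
    undefined instead of reporting a number.
    """
    x = np.asarray(spec_correct, dtype=float)
    y = np.asarray(spec_incorrect, dtype=float)
    if x.size < 2 or y.size < 2:
        return RelevanceResult(
            status="undefined",
            omega=None,
            A=None,
            U=None,
            rank_sums=None,
            group_sizes=(int(x.size), int(y.size)),
            groups_compared=groups_compared,
            reason="each group needs >= 2 trials",
        )
    mw = mann_whitney_u(x, y)
    a = mw.U_X / (mw.n_X * mw.n_Y)
    # max(A, 1-A) evaluated on the half-integer U scale so that
    # Omega(X, Y) == Omega(Y, X) holds bit-exactly
    return RelevanceResult(
        status="ok",
        omega=max(mw.U_X, mw.U_Y) / (mw.n_X * mw.n_Y),
        A=a,
        U=mw.U,
        rank_sums=(mw.R_X, mw.R_Y),
        group_sizes=(mw.n_X, mw.n_Y),
        groups_compared=groups_compared,
    )


# ---------------------------------------------------------------------------
# Distribution-shape statistics
# ---------------------------------------------------------------------------

def yule_kendall(sample: Sequence[float]) -> float:
    """Quartile skewness γ = (Q¾ + Q¼ − 2·Q½)/(Q¾ − Q¼), in [−1, 1].

    Quantiles use linear interpolation between order statistics, the same
    convention as every percentile in this package, so values reproduce
    bit-for-bit. NaN (flagged-undefined) when the interquartile range is
    zero.
    """
    s = np.asarray(sample, dtype=float)
    s = s[~np.isnan(s)]
    if s.size < 3:
        raise ValidationError("Yule-Kendall needs at least 3 values")
    q1, q2, q3 = np.quantile(s, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    if iqr == 0.0:
        return float("nan")
    return float(np.clip((q3 + q1 - 2.0 * q2) / iqr, -1.0, 1.0))


def fano_factor(session: PopulationSession, condition: str) -> np.ndarray:
    """Per-neuron Fano factor across the condition's trials.

    Unbiased (n−1) sample variance divided by the mean; 1 under Poisson
    spiking. Neurons with zero mean get NaN.
    """
    mask = session.condition_mask(condition)
    n = int(mask.sum())
    if n < 2:
        raise ValidationError(
            f"Fano factor needs >= 2 trials in condition {condition!r}"
        )
    block = session.responses[mask]
    mean = block.mean(axis=0)
    var = block.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = var / mean
    return np.where(mean == 0.0, np.nan, ff)
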