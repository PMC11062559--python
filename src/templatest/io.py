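"""Session and result serialization.

A session on disk is a triple of plain-text files (diffable, suitable for
fixtures): a responses CSV (``trial_id`` column then one column per
neuron), a trials CSV (``trial_id``, ``condition``, ``outcome`` and
``cov_*`` covariate columns) and a JSON manifest (modality, annotations,
provenance). Results are written as a JSON summary of all scalars plus
tidy per-trial / per-neuron CSV tables; outputs carry no timestamps so
identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SessionIOError, ValidationError
from .metrics import RelevanceResult, SpecificityResult
from .population import GroupedMetrics, JackknifeResult, SubsampleResult, ClusterResult
from .session import PopulationSession, TrialRecord
from .simulate import LandscapeResult, SimulationResult
from .surrogates import SpecificityBand, SurrogateEnsemble

__all__ = [
    "SessionFileSet",
    "write_session",
    "read_session",
    "write_results",
    "config_hash",
]

_COV_PREFIX = "cov_"


@dataclass(frozen=True)
class SessionFileSet:
    """Paths of the three files that make up one stored session."""

    responses_file: Path
    trials_file: Path
    manifest_file: Path

    @classmethod
    def in_dir(cls, directory: str | Path, prefix: str = "session") -> "SessionFileSet":
        d = Path(directory)
        return cls(
            responses_file=d / f"{prefix}_responses.csv",
            trials_file=d / f"{prefix}_trials.csv",
            manifest_file=d / f"{prefix}_manifest.json",
        )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_session(
    session: PopulationSession,
    directory: str | Path,
    prefix: str = "session",
    provenance: dict | None = None,
) -> SessionFileSet:
    """Write a session as its responses/trials/manifest file triple."""
    fs = SessionFileSet.in_dir(directory, prefix)
    Path(directory).mkdir(parents=True, exist_ok=True)
    resp = pd.DataFrame(session.responses, columns=session.neuron_ids)
    resp.insert(0, "trial_id", session.trial_ids)
    resp.to_csv(fs.responses_file, index=False)

    cov_names: list[str] = []
    for rec in session.trial_records:
        for k in rec.covariates:
            if k not in cov_names:
                cov_names.append(k)
    rows = []
    for rec in session.trial_records:
        row = {"trial_id": rec.trial_id, "condition": rec.condition,
               "outcome": rec.outcome}
        for k in cov_names:
            row[_COV_PREFIX + k] = rec.covariates.get(k, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(fs.trials_file, index=False)

    manifest = {
        "modality": session.modality,
        "area_label": session.area_label,
        "window_annotation": session.window_annotation,
        "n_trials": session.n_trials,
        "n_neurons": session.n_neurons,
        "provenance": provenance or {},
    }
    fs.manifest_file.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return fs


def read_session(file_set: SessionFileSet | str | Path, prefix: str = "session") -> PopulationSession:
    """Load and validate a stored session.

    Raises a named :class:`ValidationError` for each distinct defect:
    row-count mismatch, trial_id mismatch between the two tables, unknown
    outcome label, or non-integer cells under counts modality.
    """
    if not isinstance(file_set, SessionFileSet):
        file_set = SessionFileSet.in_dir(file_set, prefix)
    for p in (file_set.responses_file, file_set.trials_file, file_set.manifest_file):
        if not Path(p).exists():
            raise SessionIOError(f"missing session file: {p}")
    try:
        manifest = json.loads(Path(file_set.manifest_file).read_text())
        resp = pd.read_csv(file_set.responses_file)
        trials = pd.read_csv(file_set.trials_file)
    except (OSError, json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise SessionIOError(f"cannot parse session files: {exc}") from exc

    if "trial_id" not in resp.columns:
        raise ValidationError("responses file lacks a trial_id column")
    if len(resp) != len(trials):
        raise ValidationError(
            f"row-count mismatch: {len(resp)} response rows vs "
            f"{len(trials)} trial records"
        )
    resp_ids = resp["trial_id"].astype(str).tolist()
    trial_ids = trials["trial_id"].astype(str).tolist()
    if resp_ids != trial_ids:
        missing = set(trial_ids) - set(resp_ids)
        extra = set(resp_ids) - set(trial_ids)
        detail = []
        if missing:
            detail.append(f"absent from responses: {sorted(missing)[:3]}")
        if extra:
            detail.append(f"absent from trials: {sorted(extra)[:3]}")
        raise ValidationError(
            "trial_id mismatch between responses and trials files ("
            + "; ".join(detail or ["ordering differs"]) + ")"
        )
    neuron_ids = [c for c in resp.columns if c != "trial_id"]
    matrix = resp[neuron_ids].to_numpy(dtype=float)
    modality = manifest.get("modality")
    if modality == "counts":
        if np.any(matrix != np.round(matrix)) or np.any(matrix < 0):
            bad = np.argwhere(matrix != np.round(matrix))
            where = (
                f" (e.g. row {bad[0][0]}, neuron {neuron_ids[bad[0][1]]})"
                if bad.size else ""
            )
            raise ValidationError(
                "manifest declares counts modality but the matrix has "
                f"non-integer or negative cells{where}"
            )
    records = []
    cov_cols = [c for c in trials.columns if c.startswith(_COV_PREFIX)]
    for _, row in trials.iterrows():
        cov = {
            c[len(_COV_PREFIX):]: float(row[c])
            for c in cov_cols
            if pd.notna(row[c])
        }
        records.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                condition=str(row["condition"]),
                outcome=str(row["outcome"]),
                covariates=cov,
            )
        )
    return PopulationSession(
        responses=matrix,
        modality=modality,
        trial_records=records,
        neuron_ids=neuron_ids,
        area_label=manifest.get("area_label", ""),
        window_annotation=manifest.get("window_annotation", ""),
    )


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def _dump_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return None if np.isnan(v) else v
    if isinstance(o, np.ndarray):
        return [_jsonify(v) for v in o.tolist()]
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _clean(v):
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def write_results(results, out_dir: str | Path, name: str | None = None,
                  extra_summary: dict | None = None) -> Path:
    """Write any result object as JSON summary + tidy CSV tables.

    Dispatches on the result type; returns the summary JSON path.
    Undefined quantities are recorded with status/reason, never as
    fabricated numbers.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SessionIOError(f"cannot create output directory {out}: {exc}") from exc

    summary: dict = dict(extra_summary or {})

    if isinstance(results, SpecificityResult):
        name = name or "specificity"
        results.to_frame().to_csv(out / f"{name}_trials.csv", index=False)
        summary.update(
            {
                "median_rho": results.median_rho(),
                "n_included": results.n_included,
                "excluded_trials": [list(t) for t in results.excluded_trials],
            }
        )
    elif isinstance(results, RelevanceResult):
        name = name or "relevance"
        summary.update(results.to_dict())
    elif isinstance(results, JackknifeResult):
        name = name or "jackknife"
        pd.DataFrame(
            results.contributions, index=results.trial_ids,
            columns=results.neuron_ids,
        ).rename_axis("trial_id").to_csv(out / f"{name}_contributions.csv")
        pd.DataFrame(
            {
                "neuron_id": results.neuron_ids,
                "median_contribution": results.neuron_median,
                "gamma": results.gamma_per_neuron,
            }
        ).to_csv(out / f"{name}_neurons.csv", index=False)
        summary.update(
            {
                "gamma_pooled": _clean(results.gamma_pooled),
                "n_neurons": results.n_neurons,
                "n_trials": results.n_trials,
            }
        )
    elif isinstance(results, SubsampleResult):
        name = name or "subsample"
        rows = []
        for f in results.fractions:
            for r in range(results.n_repeats):
                rows.append(
                    {
                        "fraction": f,
                        "n_neurons": results.n_neurons_used[f],
                        "repeat": r,
                        "median_rho": results.median_rho[f][r],
                        "omega": _clean(float(results.omega[f][r])),
                    }
                )
        pd.DataFrame(rows).to_csv(out / f"{name}_curve.csv", index=False)
        summary.update(
            {
                "fractions": results.fractions,
                "n_repeats": results.n_repeats,
                "seed": results.seed,
                "median_rho_by_fraction": {
                    str(f): float(np.median(results.median_rho[f]))
                    for f in results.fractions
                },
            }
        )
    elif isinstance(results, ClusterResult):
        name = name or "clusters"
        pd.DataFrame(
            {"trial_id": list(results.labels), "cluster": list(results.labels.values())}
        ).to_csv(out / f"{name}_labels.csv", index=False)
        summary.update(
            {
                "chosen_k": results.chosen_k,
                "silhouette_by_k": {str(k): v for k, v in results.silhouette_by_k.items()},
                "seed": results.seed,
            }
        )
    elif isinstance(results, GroupedMetrics):
        name = name or "groups"
        rows = []
        for g in results.groups:
            rows.append(
                {
                    "group": g.label,
                    "n_trials": g.n_trials,
                    "median_rho": g.median_rho,
                    "omega": _clean(g.relevance.omega),
                    "relevance_status": g.relevance.status,
                }
            )
        pd.DataFrame(rows).to_csv(out / f"{name}_table.csv", index=False)
        summary.update(
            {
                "grouping_name": results.grouping_name,
                "groups": rows,
                "skipped": [list(s) for s in results.skipped],
                "pooled": {
                    "median_rho": results.pooled.median_rho,
                    "omega": _clean(results.pooled.relevance.omega),
                    "n_trials": results.pooled.n_trials,
                }
                if results.pooled
                else None,
            }
        )
    elif isinstance(results, SimulationResult):
        name = name or "simulation"
        results.specificity.to_frame().to_csv(out / f"{name}_trials.csv", index=False)
        summary.update(
            {
                "config": dataclasses.asdict(results.config),
                "median_rho": results.median_rho(),
                "relevance": results.relevance.to_dict(),
                "n_trials_included": int(results.included.sum()),
                "hit_fraction": float(results.outcome.mean()),
            }
        )
    elif isinstance(results, LandscapeResult):
        name = name or "landscape"
        rows = []
        for bi, beta in enumerate(results.beta_grid):
            for ai, v in enumerate(results.axis_grid):
                rows.append(
                    {
                        "beta": beta,
                        results.axis_name: v,
                        "median_rho": results.median_rho[bi, ai],
                        "median_omega": _clean(float(results.median_omega[bi, ai])),
                        "compatible": bool(results.mask[bi, ai])
                        if results.mask is not None
                        else None,
                    }
                )
        pd.DataFrame(rows).to_csv(out / f"{name}_grid.csv", index=False)
        summary.update(
            {
                "beta_grid": results.beta_grid,
                "axis_name": results.axis_name,
                "axis_grid": results.axis_grid,
                "n_replicates": results.n_replicates,
                "seed": results.seed,
                "threshold": results.threshold,
                "measured_value": results.measured_value,
            }
        )
    elif isinstance(results, SpecificityBand):
        name = name or "surrogate_band"
        summary.update(
            {
                "median": results.median,
                "lower": results.lower,
                "upper": results.upper,
                "n_pooled": results.n_pooled,
                "per_key_median": results.per_key_median,
            }
        )
    elif isinstance(results, SurrogateEnsemble):
        name = name or "surrogate"
        frames = []
        for key, matrix in results.draws.items():
            df = pd.DataFrame(matrix)
            df.insert(0, "surrogate_index", np.arange(matrix.shape[0]))
            df.insert(0, "key", key)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"{name}_draws.csv", index=False
        )
        summary.update(
            {
                "generator": results.generator,
                "n_surrogates": results.n_surrogates,
                "seed": results.seed,
                "provenance": results.provenance,
            }
        )
    else:
        raise ValidationError(f"no writer for result type {type(results).__name__}")

    path = out / f"{name}_summary.json"
    _dump_json(path, summary)
    return path
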