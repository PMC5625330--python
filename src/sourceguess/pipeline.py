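"""End-to-end orchestration: coding -> guessing null -> inference.

``run_analysis`` takes one experiment's generation/recall CSVs and
produces the per-participant coded counts, the Monte Carlo guessing
predictions, a Table-1-style summary, observed-vs-predicted tests and
standardized-mean-change effects.  ``run_meta`` pools effect files
across experiments into fixed-effect summaries (forest data) and
optional half-normal-prior Bayes factors.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coding import (
    GenerationEvent,
    RecallEvent,
    apply_extended_recall_filter,
    code_recall_events,
    encoding_sets,
    filter_pair_duplicates,
    load_events,
)
from .guessing import build_frequency_norms, predict_participant
from .stats import (
    dienes_bf,
    fixed_effect_summary,
    mixed_anova,
    paired_t_onetailed,
    smc_effect,
    within_subject_ci,
)

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "run_meta", "participant_seed"]

POOLED = "pooled"


@dataclass(frozen=True)
class RunConfig:
    generation_path: str | Path
    recall_path: str | Path
    outdir: str | Path | None = None
    study_id: str = "study"
    mode: str = "free_report"
    n_reps: int = 500
    seed: int = 0
    anova: bool = True
    ttests: bool = True

    def digest(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisResult:
    counts: pd.DataFrame
    predictions: pd.DataFrame
    summary: pd.DataFrame
    effects: pd.DataFrame
    ttests: pd.DataFrame
    anova: pd.DataFrame | None
    duplication: pd.DataFrame
    manifest: dict
    paths: dict = field(default_factory=dict)


def participant_seed(base_seed: int, index: int) -> int:
    """Stable, collision-free per-participant substream seed."""
    state = np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
    return int(state % (2**31))


def _shape_condition_map(events: Sequence[GenerationEvent]) -> dict[str, str]:
    """Condition label per shape: the concurrent load scheduled for it."""
    out: dict[str, str] = {}
    for e in events:
        if e.shape_id not in out or out[e.shape_id] == "none":
            if e.load_condition != "none":
                out[e.shape_id] = e.load_condition
            else:
                out.setdefault(e.shape_id, "none")
    return out


def run_analysis(cfg: RunConfig) -> AnalysisResult:
    """Execute the full single-experiment pipeline.

    Stages run in order (coding, guessing null, inference); any failure
    aborts with the stage name.  All randomness derives from
    ``cfg.seed`` via per-participant substreams, so reruns with the same
    config are byte-identical.
    """
    t0 = time.time()
    stage = "load"
    try:
        gen_events = load_events(cfg.generation_path, "generation")
        recall_events = load_events(cfg.recall_path, "test")

        stage = "duplicate_filter"
        pairs: dict[str, list[GenerationEvent]] = {}
        for e in gen_events:
            pairs.setdefault(e.pair_id, []).append(e)
        retained: dict[str, list[GenerationEvent]] = {}
        dup_rows = []
        for pair_id, events in sorted(pairs.items()):
            filtered, summary = filter_pair_duplicates(events)
            retained[pair_id] = filtered
            dup_rows.append({
                "pair_id": pair_id,
                "pct_self_repeats": summary.pct_self_repeats,
                "pct_partner_duplicates": summary.pct_partner_duplicates,
                "n_removed_actions": summary.n_removed_actions,
            })
        duplication = pd.DataFrame(dup_rows)

        stage = "frequency_norms"
        norms = build_frequency_norms(gen_events)
        condition_of_shape = _shape_condition_map(gen_events)
        conditions = sorted(set(condition_of_shape.values()))
        pair_of = {e.participant_id: e.pair_id for e in gen_events}

        stage = "coding"
        by_participant: dict[str, list[RecallEvent]] = {}
        for e in recall_events:
            by_participant.setdefault(e.participant_id, []).append(e)

        count_rows, pred_rows, obs_pred = [], [], []
        for idx, (pid, events) in enumerate(sorted(by_participant.items())):
            tasks = {e.task for e in events}
            if len(tasks) != 1:
                raise ValueError(f"participant {pid} has multiple tasks: {tasks}")
            task = tasks.pop()
            if pid not in pair_of:
                raise ValueError(f"participant {pid} absent from generation phase")
            reported, _withheld = apply_extended_recall_filter(events, cfg.mode)
            own, partner = encoding_sets(retained[pair_of[pid]], pid)

            cells = [POOLED] + (conditions if len(conditions) > 1 else [])
            for condition in cells:
                if condition == POOLED:
                    cell_events = reported
                else:
                    cell_events = [
                        e for e in reported
                        if condition_of_shape.get(e.shape_id, "none") == condition
                    ]
                counts, labels = code_recall_events(
                    cell_events, own, partner, task, condition=condition
                )
                shape_counts: dict[str, int] = {}
                for ev, label in labels:
                    if label != "repeat":
                        shape_counts[ev.shape_id] = shape_counts.get(ev.shape_id, 0) + 1
                seed = participant_seed(cfg.seed, idx)
                pred = predict_participant(
                    pid, shape_counts, counts.n_intrusions, own, partner,
                    norms, task, n_reps=cfg.n_reps, seed=seed,
                )
                count_rows.append({
                    "participant_id": pid, "task": task, "condition": condition,
                    "n_correct": counts.n_correct,
                    "n_source_errors": counts.n_source_errors,
                    "n_intrusions": counts.n_intrusions,
                })
                pred_rows.append({
                    "participant_id": pid, "task": task, "condition": condition,
                    "ratio": pred.ratio,
                    "n_degenerate_reps": pred.n_degenerate_reps,
                    "intrusions_observed": pred.n_intrusions_observed,
                    "predicted_source_errors": pred.predicted_source_errors,
                    "seed": pred.seed,
                })
                obs_pred.append({
                    "participant_id": pid, "task": task, "condition": condition,
                    "observed": counts.n_source_errors,
                    "predicted": pred.predicted_source_errors,
                })

        counts_df = pd.DataFrame(count_rows)
        preds_df = pd.DataFrame(pred_rows)
        op_df = pd.DataFrame(obs_pred).dropna(subset=["predicted"])

        stage = "summary"
        melted = counts_df.melt(
            id_vars=["participant_id", "task", "condition"],
            value_vars=["n_correct", "n_source_errors", "n_intrusions"],
            var_name="measure", value_name="count",
        )
        summary = (
            melted.groupby(["task", "condition", "measure"])["count"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"count": "n"})
        )

        stage = "inference"
        ttest_rows, effect_rows = [], []
        for (task, condition), cell in op_df.groupby(["task", "condition"]):
            if len(cell) < 3:
                continue
            obs = cell["observed"].to_numpy(float)
            pred = cell["predicted"].to_numpy(float)
            if cfg.ttests:
                res = paired_t_onetailed(obs, pred)
                ci = within_subject_ci(np.column_stack([obs, pred]))
                ttest_rows.append({
                    "task": task, "condition": condition, "n": res.n,
                    "mean_diff": res.mean_diff, "t": res.t, "df": res.df,
                    "p_one_tailed": res.p_one_tailed, "d_av": res.d_av,
                    "ci95_observed": ci[0], "ci95_predicted": ci[1],
                })
            if float(np.std(obs - pred, ddof=1)) > 0:
                eff = smc_effect(obs, pred, study_id=cfg.study_id)
                effect_rows.append({
                    "study_id": cfg.study_id, "task": task, "condition": condition,
                    "smc": eff.smc, "var_smc": eff.var_smc, "n": eff.n,
                })
        ttests_df = pd.DataFrame(ttest_rows)
        effects_df = pd.DataFrame(effect_rows)

        anova_df = None
        if cfg.anova and op_df["task"].nunique() == 2:
            pooled = op_df[op_df["condition"] == POOLED]
            long = pooled.melt(
                id_vars=["participant_id", "task"],
                value_vars=["observed", "predicted"],
                var_name="data_type", value_name="value",
            )
            anova_df = mixed_anova(
                long, dv="value", subject="participant_id",
                between="task", within="data_type",
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": {k: str(v) for k, v in asdict(cfg).items()},
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "n_participants": int(counts_df["participant_id"].nunique()),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "runtime_s": round(time.time() - t0, 3),
    }

    result = AnalysisResult(
        counts=counts_df, predictions=preds_df, summary=summary,
        effects=effects_df, ttests=ttests_df, anova=anova_df,
        duplication=duplication, manifest=manifest,
    )
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "counts": counts_df, "predictions": preds_df, "summary": summary,
            "effects": effects_df, "ttests": ttests_df, "duplication": duplication,
        }
        if anova_df is not None:
            tables["anova"] = anova_df
        for name, tbl in tables.items():
            path = outdir / f"{name}.csv"
            tbl.to_csv(path, index=False)
            result.paths[name] = path
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        result.paths["manifest"] = manifest_path
        norms_path = outdir / "norms.json"
        norms_path.write_text(json.dumps(
            {s: dict(norms.probs[s]) for s in norms.shapes},
            indent=2, sort_keys=True,
        ))
        result.paths["norms"] = norms_path
    return result


def run_meta(
    effect_paths: Sequence[str | Path],
    priors: Sequence[Mapping] = (),
    outdir: str | Path | None = None,
) -> dict:
    """Pool per-study effects and compute configured Bayes factors.

    ``effect_paths`` are effects.csv files from :func:`run_analysis`;
    studies are grouped by (task, condition).  Each entry of ``priors``
    is a mapping with ``label``, ``data_mean``, ``data_se`` and
    ``prior_sd`` and yields one half-normal-prior Bayes factor.
    """
    if not effect_paths:
        raise ValueError("need at least one effects file")
    frames = [pd.read_csv(p) for p in effect_paths]
    effects = pd.concat(frames, ignore_index=True)
    required = {"study_id", "task", "condition", "smc", "var_smc", "n"}
    if not required.issubset(effects.columns):
        raise ValueError(f"effects files must have columns {sorted(required)}")

    forest_rows = []
    meta_out = {}
    for (task, condition), group in effects.groupby(["task", "condition"]):
        studies = [
            smc_row_to_result(row) for row in group.to_dict("records")
        ]
        meta = fixed_effect_summary(studies)
        key = f"{task}/{condition}"
        meta_out[key] = {
            "summary_effect": meta.summary_effect,
            "se": meta.se_summary,
            "ci95": list(meta.ci95),
            "weights": {
                s.study_id: w for s, w in zip(meta.per_study, meta.norm_weights)
            },
        }
        for s, w in zip(meta.per_study, meta.norm_weights):
            half = 1.96 * np.sqrt(s.var_smc)
            forest_rows.append({
                "task": task, "condition": condition, "study_id": s.study_id,
                "effect": s.smc, "ci_lo": s.smc - half, "ci_hi": s.smc + half,
                "weight": w, "n": s.n, "is_summary": False,
            })
        forest_rows.append({
            "task": task, "condition": condition, "study_id": "summary",
            "effect": meta.summary_effect,
            "ci_lo": meta.ci95[0], "ci_hi": meta.ci95[1],
            "weight": 1.0, "n": int(group["n"].sum()), "is_summary": True,
        })
    forest = pd.DataFrame(forest_rows)

    bf_out = []
    for prior in priors:
        res = dienes_bf(
            float(prior["data_mean"]), float(prior["data_se"]), float(prior["prior_sd"])
        )
        bf_out.append({
            "label": prior.get("label", ""),
            "data_mean": res.data_mean, "data_se": res.data_se,
            "prior_sd": res.prior_sd,
            "bf10": res.bf10, "bf10_numeric": res.bf10_numeric,
        })

    report = {"meta": meta_out, "bayes_factors": bf_out}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        forest.to_csv(outdir / "forest.csv", index=False)
        (outdir / "meta.json").write_text(json.dumps(meta_out, indent=2, sort_keys=True))
        if bf_out:
            (outdir / "bf.json").write_text(json.dumps(bf_out, indent=2))
    report["forest"] = forest
    return report


def smc_row_to_result(row: Mapping):
    from .stats import SMCResult

    return SMCResult(
        study_id=str(row["study_id"]),
        smc=float(row["smc"]),
        var_smc=float(row["var_smc"]),
        n=int(row["n"]),
    )
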