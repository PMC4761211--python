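"""End-to-end pipeline: simulate (or load) -> discover -> score -> evaluate.

Outputs are deterministic: a rerun with the same config and seed writes
byte-identical files (no timestamps; full-precision floats; sorted JSON
keys).  A run log records the package and library versions, the seed, and
the analysis conventions in effect (tie handling, the p-value feeding the
vote, the ties-go-low split rule).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .evaluation import aggregate, evaluate_cohort
from .matrix import ExpressionMatrix
from .scoring import SignatureDef, load_signature, signature_score, stratify
from .selection import ConsensusCriteria, consensus_select, probe_cohort_grid
from .simulate import SimulationConfig, generate_multi_cohort


def simulate_to_dir(config: SimulationConfig, out_dir) -> list[dict]:
    """Generate all cohorts and write expr_<k>.tsv / clinical_<k>.tsv / truth.tsv.

    Returns a manifest-style list of the written cohorts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohorts = generate_multi_cohort(config)
    manifest = []
    for k, cohort in enumerate(cohorts):
        expr_path = out_dir / f"expr_{k}.tsv"
        clin_path = out_dir / f"clinical_{k}.tsv"
        io.write_expression(cohort.expression, expr_path)
        io.write_clinical(cohort.clinical, clin_path)
        manifest.append(
            {
                "cohort_id": cohort.cohort_id,
                "expression": expr_path,
                "clinical": clin_path,
                "endpoint": "OS",
            }
        )
    truth = pd.DataFrame(
        {
            "probe_id": list(cohorts[0].truth),
            "log_hazard_per_sd": list(cohorts[0].truth.values()),
        }
    ).sort_values("probe_id")
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "cohorts": [
                    {
                        "cohort_id": m["cohort_id"],
                        "expression": m["expression"].name,
                        "clinical": m["clinical"].name,
                        "endpoint": m["endpoint"],
                    }
                    for m in manifest
                ]
            },
            fh,
            sort_keys=False,
        )
    return manifest


def discover(cohort_data: list[dict], criteria: ConsensusCriteria, out_dir=None):
    """Probe x cohort grid plus the consensus selection.

    ``cohort_data`` entries carry in-memory ``expression`` (ExpressionMatrix)
    and ``clinical`` (DataFrame).  Probes not shared by every cohort are
    dropped before testing.  Returns (grid, selected).
    """
    shared = None
    for c in cohort_data:
        ids = set(c["expression"].probe_ids)
        shared = ids if shared is None else shared & ids
    frames = []
    for c in cohort_data:
        expr = c["expression"]
        drop = [p for p in expr.probe_ids if p not in shared]
        if drop:
            expr = expr.subset_probes([p for p in expr.probe_ids if p in shared])
        clin = c["clinical"]
        order = [s for s in clin["sample_id"] if s in set(expr.sample_ids)]
        clin = clin.set_index("sample_id").loc[order].reset_index()
        expr = expr.subset_samples(order)
        frames.append(
            probe_cohort_grid(
                expr,
                clin["time"].to_numpy(float),
                clin["event"].to_numpy(),
                cohort_id=c["cohort_id"],
            )
        )
    grid = pd.concat(frames, ignore_index=True)
    selected = consensus_select(grid, criteria)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out_dir / "grid.tsv", sep="\t", index=False, lineterminator="\n")
        pd.DataFrame({"probe_id": selected}).to_csv(
            out_dir / "selected.tsv", sep="\t", index=False, lineterminator="\n"
        )
    return grid, selected


def _load_cohort_data(manifest: list[dict]) -> list[dict]:
    return [
        {
            "cohort_id": m["cohort_id"],
            "expression": io.read_expression(m["expression"]),
            "clinical": io.read_clinical(m["clinical"]),
        }
        for m in manifest
    ]


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the full chain and write a deterministic artifact directory.

    ``config`` names either a ``simulation`` block (SimulationConfig
    fields) or a ``manifest`` path, plus optional ``criteria`` and
    ``signature`` entries.  When no signature file is given, the probes
    selected by the consensus vote define the evaluated signature.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if "simulation" in config:
        sim_kwargs = dict(config["simulation"] or {})
        if seed is not None:
            sim_kwargs["seed"] = seed
        sim_config = SimulationConfig(**sim_kwargs)
        manifest = simulate_to_dir(sim_config, out_dir / "cohorts")
        stage = "simulate"
    elif "manifest" in config:
        manifest = io.read_manifest(config["manifest"])
        sim_config = None
        stage = "load"
    else:
        raise ValueError("config must contain a 'simulation' block or a 'manifest' path")

    crit_kwargs = dict(config.get("criteria") or {})
    crit_kwargs.setdefault("n_cohorts", len(manifest))
    criteria = ConsensusCriteria(**crit_kwargs)

    try:
        cohort_data = _load_cohort_data(manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        grid, selected = discover(cohort_data, criteria, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'discover' failed: {exc}") from exc

    if config.get("signature"):
        signature = load_signature(config["signature"])
    else:
        if not selected:
            raise RuntimeError(
                "pipeline stage 'score' failed: consensus selected no probes and no "
                "signature file was supplied"
            )
        signature = SignatureDef(name="selected", probe_ids=tuple(selected))

    evaluations = []
    for c in cohort_data:
        try:
            sv = signature_score(c["expression"], signature)
            scores = pd.DataFrame(
                {
                    "sample_id": sv.sample_ids,
                    "score": sv.score.to_numpy(),
                    "group_median": stratify(sv, 2),
                    "group_quartile": stratify(sv, 4),
                }
            )
            scores.to_csv(
                out_dir / f"scores_{c['cohort_id']}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
            ev = evaluate_cohort(
                c["expression"], c["clinical"], signature, cohort_id=c["cohort_id"]
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'evaluate' failed in cohort {c['cohort_id']}: {exc}"
            ) from exc
        evaluations.append(ev)
        for label, curve in {**ev.km_curves, **ev.quartile_curves}.items():
            curve.to_frame().to_csv(
                out_dir / f"km_{c['cohort_id']}_{label}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )

    forest = aggregate(evaluations)
    forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False, lineterminator="\n")

    summary = {
        "signature": {"name": signature.name, "probe_ids": list(signature.probe_ids)},
        "criteria": {
            "alpha": criteria.alpha,
            "min_significant": criteria.min_significant,
            "n_cohorts": criteria.n_cohorts,
            "require_all_same_direction": criteria.require_all_same_direction,
        },
        "selected": list(selected),
        "cohorts": {
            ev.cohort_id: {
                "n": ev.n,
                "n_events": ev.n_events,
                "hr_median_split": ev.hr_median_split.single(),
                "logrank_p": ev.logrank_p,
                "hr_continuous": ev.hr_continuous.single(),
                "hr_multivariate": (
                    None
                    if ev.hr_multivariate is None
                    else {
                        "hr": float(ev.hr_multivariate.hr[0]),
                        "ci_low": float(ev.hr_multivariate.ci_low[0]),
                        "ci_high": float(ev.hr_multivariate.ci_high[0]),
                        "p": float(ev.hr_multivariate.p[0]),
                    }
                ),
            }
            for ev in evaluations
        },
        "weighted_mean_hr": {
            row["fit"]: {"hr": row["hr"], "hr_rounded": row["hr_rounded"]}
            for _, row in forest[forest["cohort_id"] == "weighted_mean"].iterrows()
        },
    }
    with open(out_dir / "evaluation.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    effective = {
        "seed": seed if seed is not None else (sim_config.seed if sim_config else None),
        "criteria": crit_kwargs,
        "signature": config.get("signature"),
        "simulation": (
            None
            if sim_config is None
            else {k: getattr(sim_config, k) for k in (
                "cohort_sizes", "n_probes", "prognostic_probe_count",
                "intra_signature_correlation", "baseline_hazard", "censoring_rate",
                "admin_cutoff", "seed",
            )}
        ),
    }
    with open(out_dir / "config_used.yaml", "w") as fh:
        yaml.safe_dump(effective, fh, sort_keys=True)

    log_lines = [
        f"consig {__version__}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
        f"seed {effective['seed']}",
        f"criteria alpha={criteria.alpha} min_significant={criteria.min_significant} "
        f"n_cohorts={criteria.n_cohorts} "
        f"require_all_same_direction={criteria.require_all_same_direction}",
        "ties_method efron",
        "vote_p_value logrank",
        "median_split ties_go_low",
        "quantile_cuts empirical, ties_go_low",
    ]
    (out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
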