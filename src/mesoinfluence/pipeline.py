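"""End-to-end orchestration: simulate -> fit -> network influence -> associations.

A :class:`PipelineConfig` embeds every stage's settings plus one master seed;
each stage derives its own seed through a fixed per-stage code
(``SeedSequence([master_seed, stage_code])``), so adding or toggling a stage
never perturbs another stage's random stream. ``run_pipeline`` executes the
enabled stages in order into a run directory and writes a manifest (config,
seeds, stage timings, output hashes) sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import depna, stats
from .bandit import TaskConfig, compliance_filter
from .inference import ModelSpec, SamplerConfig, compute_waic, fit_hierarchical
from .synthetic import NetSimConfig, PopulationSpec, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

# fixed stage codes: appending new stages must not renumber existing ones
_STAGE_CODES = {"simulate": 1, "fit": 2, "depna": 3, "associate": 4, "report": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed below 2**31 from the master seed and stage code."""
    ss = np.random.SeedSequence([master_seed, _STAGE_CODES[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    out_dir: str = "runs/demo"
    master_seed: int = 0
    n_per_group: int = 20
    stages: tuple[str, ...] = ("simulate", "fit", "depna", "associate", "report")
    net: NetSimConfig = field(default_factory=lambda: NetSimConfig(group_coupling_delta=0.15))
    task: TaskConfig = field(default_factory=TaskConfig)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    fit_models: tuple[int, ...] = (1, 2)
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig.fast())
    covariates: tuple[str, ...] = ("age", "sex", "medicated", "daw")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Any stage failure propagates with the stage name attached; artifacts
    written by earlier stages are left in place. Re-running an identical
    config reproduces identical numeric outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": cfg.master_seed, "stages": {}, "outputs": {}}
    (out / "config.json").write_text(cfg.to_json())

    state: dict = {}
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            _run_stage(stage, cfg, out, state)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": stage_seed(cfg.master_seed, stage) if stage in _STAGE_CODES else None,
            "seconds": round(time.perf_counter() - t0, 3),
        }

    for f in sorted(out.rglob("*.csv")):
        manifest["outputs"][str(f.relative_to(out))] = _hash_file(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _require(state: dict, key: str, stage: str) -> object:
    if key not in state:
        raise FileNotFoundError(f"stage {stage!r} needs missing input {key!r}; enable its producer stage")
    return state[key]


def _run_stage(stage: str, cfg: PipelineConfig, out: Path, state: dict) -> None:
    if stage == "simulate":
        cohort, panel, records, truth = simulate_cohort(
            cfg.net, cfg.task, cfg.population, cfg.n_per_group,
            seed=stage_seed(cfg.master_seed, "simulate"),
        )
        write_cohort(out / "cohort", cohort, panel, records, truth)
        state.update(cohort=cohort, panel=panel, records=records, truth=truth)

    elif stage == "fit":
        records = _require(state, "records", stage)
        include = compliance_filter(records)
        kept = [r for r, ok in zip(records, include) if ok]
        fits = {}
        for m in cfg.fit_models:
            spec = ModelSpec(model_id=m)
            scfg = dataclasses.replace(cfg.sampler, seed=stage_seed(cfg.master_seed, "fit") + m)
            groups = None
            if m == 3:
                cohort = _require(state, "cohort", stage)
                keep_ids = {r.subject_id for r in kept}
                groups = cohort.set_index("subject_id").loc[[r.subject_id for r in kept], "group"].tolist()
            fits[f"model{m}"] = fit_hierarchical(spec, kept, scfg, groups=groups)
        waic = compute_waic(fits)
        waic.table.to_csv(out / "waic.csv")
        waic.pairwise.to_csv(out / "waic_pairwise.csv", index=False)
        pd.DataFrame(
            {k: f.summary() for k, f in fits.items()}
        ).to_json(out / "fit_summary.json", indent=2)
        state.update(fits=fits, waic=waic, included=include)

    elif stage == "depna":
        panel = _require(state, "panel", stage)
        mats = [
            depna.dependency_matrix(depna.correlation_matrix(panel.subject(i), list(panel.node_names)))
            for i in range(len(panel.subject_ids))
        ]
        deg = depna.degrees_table(mats, panel.subject_ids, hub=0)
        deg.to_csv(out / "degrees.csv", index=False)
        state.update(dep_matrices=mats, degrees=deg)

    elif stage == "associate":
        cohort = _require(state, "cohort", stage)
        deg = _require(state, "degrees", stage)
        mats = _require(state, "dep_matrices", stage)
        panel = state["panel"]
        covs = list(cfg.covariates)
        rows = []
        for col in ("influencing", "influenced"):
            keep = depna.exclude_outliers(deg[col].to_numpy())
            res = depna.influence_regression(
                deg[col].to_numpy()[keep], cohort[keep].reset_index(drop=True), "group", covs
            )
            res.analysis_id = f"{col}~group"
            rows.append(res.to_dict())
        conn = stats.connectivity_table(
            [panel.subject(i) for i in range(len(panel.subject_ids))],
            panel.subject_ids, list(panel.node_names), seed="VTA",
        ).drop(columns="state")
        for r in stats.adjusted_group_difference(conn, cohort.set_index("subject_id"), covs):
            rows.append(r.to_dict())
        pd.DataFrame(rows).to_csv(out / "associations.csv", index=False)
        g = depna.edge_graph(
            np.stack([m.values for m in mats]), cohort, "group", covs,
            node_names=list(panel.node_names), hub=0,
        )
        g.graph["tests"].to_csv(out / "edge_tests.csv", index=False)
        edge_table = g.graph.pop("tests")
        import networkx as nx

        nx.write_graphml(g, out / "influence_graph.graphml")
        g.graph["tests"] = edge_table
        state.update(graph=g)

    elif stage == "report":
        lines = ["# Pipeline run summary", ""]
        if "waic" in state:
            lines += ["## Model comparison (WAIC)", state["waic"].table.to_markdown(), ""]
        if "degrees" in state:
            d = state["degrees"]
            lines += [
                "## Hub influence degrees",
                f"mean influencing = {d['influencing'].mean():.4f}, "
                f"mean influenced = {d['influenced'].mean():.4f}",
                "",
            ]
        (out / "report.md").write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown stage {stage!r}")
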