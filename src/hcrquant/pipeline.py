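"""End-to-end orchestration of the mRNA, flow and transcript-error stages.

A single JSON config drives every stage. Each stage accepts either real input
files (plate CSVs + metadata, flow event CSVs, FASTQ reads) or a simulation block
— exactly one of the two — and all randomness flows from explicit seeds, so a
re-run with the same config reproduces the outputs bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .contrasts import ContrastSpec, GroupSummary, contrast_test, summary_from_values
from .flow import (SpilloverMatrix, compensate_events, condition_summary_anova,
                   fit_induced_mixture, log_ratio_normalize, summarize_population)
from .normalize import (ConditionGroup, MeasurementPair, combination_ratios,
                        scale_to_control_max, summarize_timecourse)
from .qpcr import quantify_plate
from .simulate import (ExperimentDesign, FlowSimConfig, ReadSimConfig,
                       simulate_expression_experiment, simulate_flow_events)
from .variants import align_and_classify, tally_variants

__all__ = ["RunConfig", "RunReport", "run_mrna_pipeline", "run_flow_pipeline",
           "run_errors_pipeline", "run_all"]


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`RunConfig.from_json`)."""

    seed: int = 0
    out_dir: Path = Path("hcrquant_out")
    mrna: dict | None = None
    flow: dict | None = None
    errors: dict | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "hcrquant_out")),
            mrna=raw.get("mrna"), flow=raw.get("flow"), errors=raw.get("errors"),
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path = Path(".")) -> None:
        """Fail before any computation: referenced paths must exist, and each
        stage must have exactly one of a simulation block or real inputs."""
        for stage, block in (("mrna", self.mrna), ("flow", self.flow),
                             ("errors", self.errors)):
            if block is None:
                continue
            has_sim = "simulate" in block
            real_keys = {"mrna": "plates", "flow": "events", "errors": "reads"}[stage]
            has_real = real_keys in block
            if has_sim == has_real:
                raise ValueError(
                    f"stage {stage!r}: provide exactly one of a 'simulate' block "
                    f"or real inputs ({real_keys!r})"
                )
            if not has_real:
                continue
            paths = block[real_keys]
            if isinstance(paths, str):
                paths = [paths]
            elif isinstance(paths, list) and paths and isinstance(paths[0], dict):
                paths = [p["path"] for p in paths]
            for extra in ("metadata", "reference", "spillover"):
                if extra in block:
                    paths = list(paths) + [block[extra]]
            for p in paths:
                if not (base / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(f"stage {stage!r}: input {p!r} not found")


@dataclass
class RunReport:
    """Per-stage record counts, exclusions and output paths."""

    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"stages": self.stages, "outputs": {k: str(v) for k, v in self.outputs.items()},
             "wall_clock_s": self.wall_clock_s},
            indent=2, default=hio._json_default))


def _log(handle, **record) -> None:
    handle.write(json.dumps(record, default=hio._json_default) + "\n")


def _design_from_block(block: dict, seed: int) -> ExperimentDesign:
    sim = dict(block)
    effects = {tuple(e[:3]): float(e[3]) for e in sim.pop("effects", [])}
    return ExperimentDesign(
        cell_lines=tuple(sim.get("cell_lines", ("fibroblast",))),
        vectors=tuple(sim.get("vectors", ("control", "lesionA"))),
        time_points_h=tuple(float(t) for t in sim.get("time_points_h", (6.0, 18.0))),
        n_replicates=int(sim.get("n_replicates", 6)),
        gfp_gamma=tuple(sim.get("gfp_gamma", (1.5, 1.0))),
        condition_effect={(c, v, float(t)): e for (c, v, t), e in effects.items()},
        noise_cv=float(sim.get("noise_cv", 0.2)),
        seed=int(sim.get("seed", seed)),
    )


def _groups_from_plates(block: dict, log) -> list[ConditionGroup]:
    """Plate CSVs -> PlateQuant -> replicate (RFP, GFP) pairs.

    Duplicate qPCR reactions of one measurement are averaged at the
    expression-value level, leaving one RFP and one GFP value per replicate.
    """
    meta = pd.read_csv(block["metadata"])
    needed = {"well", "cell_line", "vector", "time_h", "replicate"}
    if not needed.issubset(meta.columns):
        raise ValueError(f"metadata lacks columns {sorted(needed - set(meta.columns))}")
    frames = []
    for plate_path in block["plates"]:
        curves = hio.read_plate_csv(plate_path)
        quant = quantify_plate(curves)
        for well, reason in quant.excluded:
            _log(log, stage="mrna", event="well_excluded", well=well, reason=reason)
        frames.append(quant.table)
    expr = pd.concat(frames, ignore_index=True).merge(meta, on="well", how="inner")
    groups = []
    key_cols = ["cell_line", "vector", "time_h"]
    for key, grp in expr.groupby(key_cols, sort=True):
        pairs = []
        for _rep, sub in grp.groupby("replicate", sort=True):
            means = sub.groupby("amplicon")["expression"].mean()
            if "RFP" not in means or "GFP" not in means:
                _log(log, stage="mrna", event="replicate_incomplete",
                     condition=list(key), replicate=_rep)
                continue
            pairs.append(MeasurementPair(float(means["RFP"]), float(means["GFP"])))
        if pairs:
            groups.append(ConditionGroup(
                cell_line=str(key[0]), vector=str(key[1]), time_h=float(key[2]),
                pairs=pairs))
    return groups


def run_mrna_pipeline(config: RunConfig) -> RunReport:
    """Plates (or simulated expression) -> combination ratios -> scaled time
    courses -> SMCV contrasts, with every intermediate written to out_dir."""
    if config.mrna is None:
        return RunReport(stages={"mrna": {"skipped": True}})
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    block = config.mrna
    control = block.get("control_vector", "control")

    with open(out / "mrna_log.jsonl", "w") as log:
        if "simulate" in block:
            design = _design_from_block(block["simulate"], config.seed)
            groups, truth = simulate_expression_experiment(design)
            hio.write_ground_truth(truth, out / "mrna_ground_truth.json")
            _log(log, stage="mrna", event="simulated", n_groups=len(groups))
        else:
            groups = _groups_from_plates(block, log)
        if not groups:
            raise ValueError("mrna stage produced no condition groups")

        summaries = []
        scaled_by_cell: dict = {}
        for cell in sorted({g.cell_line for g in groups}):
            cell_groups = [g for g in groups if g.cell_line == cell]
            scaled = scale_to_control_max(cell_groups, control_vector=control)
            scaled_by_cell[cell] = scaled
            for tc in scaled.values():
                summaries.append(summarize_timecourse(tc))
        timecourses = pd.concat(summaries, ignore_index=True).sort_values(
            ["cell_line", "vector", "time_h"]).reset_index(drop=True)
        timecourses.to_csv(out / "timecourses.csv", index=False)

        contrast_rows = []
        for cdef in block.get("contrasts", []):
            name = cdef["name"]
            cspec = ContrastSpec(tuple(cdef["coefficients"]))
            gsums = []
            for sel in cdef["groups"]:
                cell = sel["cell_line"]
                tc = scaled_by_cell[cell][sel["vector"]]
                vals = tc.scaled[float(sel["time_h"])]
                n_meas = tc.n_measurements[float(sel["time_h"])]
                s = summary_from_values(vals)
                # combination ratios carry the information of n measurements,
                # not of C(n, 2) correlated pairs
                gsums.append(GroupSummary(mean=s.mean, variance=s.variance, n=n_meas))
            res = contrast_test(gsums, cspec)
            contrast_rows.append({
                "contrast": name, "smcv": res.smcv, "cplus": res.cplus,
                "p": res.p_value, "significant": res.significant,
            })
            _log(log, stage="mrna", event="contrast", name=name, p=res.p_value)
        if contrast_rows:
            pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)
            report.outputs["contrasts"] = out / "contrasts.csv"

    report.stages["mrna"] = {
        "n_groups": len(groups),
        "n_measurements": int(sum(g.n for g in groups)),
        "n_timecourse_rows": int(len(timecourses)),
        "n_contrasts": len(contrast_rows),
    }
    report.outputs["timecourses"] = out / "timecourses.csv"
    report.wall_clock_s = time.monotonic() - t0
    report.to_json(out / "mrna_report.json")
    return report


def run_flow_pipeline(config: RunConfig) -> RunReport:
    """Events -> compensation -> log-ratio -> mixture gating -> condition ANOVA."""
    if config.flow is None:
        return RunReport(stages={"flow": {"skipped": True}})
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    block = config.flow
    report = RunReport()
    control = block.get("control", "control")

    with open(out / "flow_log.jsonl", "w") as log:
        populations = []
        pop_inputs = []  # (condition, population, events DataFrame, spillover)
        if "simulate" in block:
            sim = block["simulate"]
            spill = SpilloverMatrix(np.asarray(sim.get("spillover", np.eye(3).tolist())))
            rng = np.random.default_rng(config.seed)
            for cond, cparams in sim["conditions"].items():
                shift = float(np.log(cparams.get("ratio_of_control", 1.0)))
                for p in range(int(sim.get("n_populations", 3))):
                    fcfg = FlowSimConfig(
                        n_events=int(sim.get("n_events", 5000)),
                        induced_fraction=float(sim.get("induced_fraction", 0.7)),
                        component_params={
                            "non_induced": (-2.0, 0.5),
                            "induced": (1.0 + shift, 0.5),
                        },
                        spillover=spill.matrix,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    events, labels = simulate_flow_events(fcfg)
                    pop_inputs.append((cond, f"pop{p}", events, spill))
        else:
            spill = (hio.read_spillover_csv(block["spillover"])
                     if "spillover" in block else SpilloverMatrix.identity())
            for rec in block["events"]:
                events = hio.read_flow_csv(rec["path"])
                pop_inputs.append((rec["condition"], rec["population"], events, spill))

        for cond, pop, events, spill in pop_inputs:
            comp = compensate_events(events, spill)
            logratios, excl = log_ratio_normalize(comp)
            _log(log, stage="flow", event="log_ratio", condition=cond,
                 population=pop, **excl)
            fit = fit_induced_mixture(logratios, seed=config.seed)
            _log(log, stage="flow", event="mixture", condition=cond, population=pop,
                 weights=fit.weights, means=fit.means, degenerate=fit.degenerate)
            populations.append(summarize_population(cond, pop, logratios,
                                                    fit.induced_labels))

        summary = condition_summary_anova(
            populations, control=control, contrasts=block.get("contrasts"),
            scale=block.get("scale", "geometric"),
        )
        pd.DataFrame([p.__dict__ for p in populations]).to_csv(
            out / "flow_populations.csv", index=False)
        summary.table.to_csv(out / "flow_conditions.csv", index=False)
        if summary.contrast_results:
            pd.DataFrame(summary.contrast_results).to_csv(
                out / "flow_contrasts.csv", index=False)

    report.stages["flow"] = {
        "n_populations": len(populations),
        "anova_f": summary.anova_f, "anova_p": summary.anova_p,
    }
    report.outputs["flow_conditions"] = out / "flow_conditions.csv"
    report.wall_clock_s = time.monotonic() - t0
    report.to_json(out / "flow_report.json")
    return report


def run_errors_pipeline(config: RunConfig) -> RunReport:
    """Reads -> lesion-site classification -> tally -> background filter."""
    if config.errors is None:
        return RunReport(stages={"errors": {"skipped": True}})
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    block = config.errors
    report = RunReport()

    if "simulate" in block:
        sim = block["simulate"]
        from .simulate import simulate_amplicon_reads
        from .variants import example_reference
        ref = example_reference()
        rcfg = ReadSimConfig(
            reference=ref,
            background_error_rate=float(sim.get("background_error_rate", 0.001)),
            lesion_event_profile=sim.get("lesion_event_profile", {}),
            n_reads=int(sim.get("n_reads", 1000)),
            seed=int(sim.get("seed", config.seed)),
        )
        reads = simulate_amplicon_reads(rcfg)
        hio.write_fastq(reads, out / "reads.fastq")
    else:
        ref = hio.read_reference_fasta(block["reference"], int(block["lesion_pos"]))
        reads = hio.read_fastq(block["reads"])

    calls = [align_and_classify(seq, ref, read_id=rid) for rid, seq in reads]
    tally = tally_variants(
        calls,
        background_rate=float(block.get("background_rate", 0.001)),
        fold_threshold=float(block.get("fold_threshold", 10.0)),
    )
    pd.DataFrame(
        [{"read_id": c.read_id, "class": c.class_key, "position": c.position,
          "n_differences": c.n_differences} for c in calls]
    ).to_csv(out / "variant_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"class": k, "count": tally.counts[k], "frequency": tally.frequencies[k],
          "retained": tally.retained[k]} for k in sorted(tally.counts)]
    ).to_csv(out / "variant_tally.csv", index=False)

    report.stages["errors"] = {
        "n_reads": len(reads), "n_classified": tally.n_classified,
        "n_unclassifiable": tally.n_unclassifiable,
    }
    report.outputs["variant_tally"] = out / "variant_tally.csv"
    report.wall_clock_s = time.monotonic() - t0
    report.to_json(out / "errors_report.json")
    return report


def run_all(config: RunConfig) -> RunReport:
    """Run every configured stage; skipped stages are recorded explicitly."""
    combined = RunReport()
    t0 = time.monotonic()
    Path(config.out_dir).mkdir(parents=True, exist_ok=True)
    for runner in (run_mrna_pipeline, run_flow_pipeline, run_errors_pipeline):
        rep = runner(config)
        combined.stages.update(rep.stages)
        combined.outputs.update(rep.outputs)
    combined.wall_clock_s = time.monotonic() - t0
    combined.to_json(Path(config.out_dir) / "run_report.json")
    return combined
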