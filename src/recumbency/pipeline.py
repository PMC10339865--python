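"""End-to-end orchestration: simulate -> blur QC -> velocity -> link -> fit -> evaluate.

Each stage writes its artifact as a plain CSV/PNG/JSON file under the run
directory, and the final manifest records input hashes, per-stage counts
and the evaluation metrics, so that two runs with the same configuration
and seed are byte-identical.  A stage failure aborts the run with the
stage named; artifacts written before the failure are retained for
debugging.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blur, coding, evaluation, io, synthetic, threshold, velocity

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one synthetic end-to-end run."""

    out_dir: str
    seed: int = synthetic.DEFAULT_SEED
    n_pens: int = 2
    duration_s: float = 14400.0          # 4 h of footage per pen
    frame_interval_s: float = 2.0
    sampling_interval_s: float = 1200.0  # one coded image every 20 min
    state_period_s: float = 1800.0       # behavior state alternates every 30 min
    n_active_when_active: int = 1
    window_s: float = 300.0
    blur_cutoff: float = blur.DEFAULT_BLUR_CUTOFF
    blur_sigmas: tuple[float, ...] = (0.0,)
    disagreement_rate: float = 0.02
    fit_method: str = "exhaustive"
    k: int = 10
    report_precision: int = 6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "blur_sigmas" in raw:
            raw["blur_sigmas"] = tuple(raw["blur_sigmas"])
        return cls(**raw)


@dataclass
class RunResult:
    manifest: dict
    report: evaluation.EvalReport
    model: threshold.ThresholdModel
    linked: pd.DataFrame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage in order and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    hashes: dict = {}

    # -- simulate -----------------------------------------------------------
    try:
        pens = [
            synthetic.PenConfig(
                pen_id=f"pen{i + 1:02d}",
                frame_interval_s=config.frame_interval_s,
                sampling_interval_s=config.sampling_interval_s,
            )
            for i in range(config.n_pens)
        ]
        scenarios = [
            synthetic.BehaviorScenario(
                duration_s=config.duration_s,
                state_schedule=synthetic.alternating_schedule(
                    config.duration_s,
                    config.state_period_s,
                    first=synthetic.SOME_ACTIVE if i % 2 == 0 else synthetic.ALL_RECUMBENT,
                ),
                n_active_when_active=config.n_active_when_active,
                seed=int((config.seed + 104729 * i) % 2**31),
            )
            for i in range(config.n_pens)
        ]
        dataset = synthetic.generate_labeled_dataset(
            pens,
            scenarios,
            blur_sigmas=config.blur_sigmas,
            disagreement_rate=config.disagreement_rate,
            seed=config.seed,
        )
        io.write_csv(dataset.frames, out / "trajectories.csv")
        io.write_csv(dataset.ethogram, out / "ethogram.csv")
        io.write_csv(dataset.coder_a, out / "labels_coder_a.csv")
        io.write_csv(dataset.coder_b, out / "labels_coder_b.csv")
        for rec in dataset.images:
            io.write_image_png(rec, out / "images")
        counts["simulate"] = dataset.summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # -- blur QC ------------------------------------------------------------
    try:
        scored = blur.score_records(dataset.images)
        kept, excluded = blur.filter_blurred(scored, cutoff=config.blur_cutoff)
        manifest_rows = pd.DataFrame(
            {
                "filename": [io.image_filename(r.pen_id, r.t_s) for r in scored],
                "pen_id": [r.pen_id for r in scored],
                "t_s": [r.t_s for r in scored],
                "blur_score": [r.blur_score for r in scored],
                "kept": [int(r.blur_score >= config.blur_cutoff) for r in scored],
            }
        )
        io.write_csv(manifest_rows, out / "blur_manifest.csv")
        counts["blur_qc"] = {
            "images_in": len(scored),
            "kept": len(kept),
            "excluded": len(excluded),
        }
    except Exception as exc:
        raise PipelineError("blur_qc", str(exc)) from exc

    # -- coding: agreement and consensus ------------------------------------
    try:
        agreement = coding.intercoder_agreement(dataset.coder_a, dataset.coder_b)
        # Adjudication by discussion is emulated with the ground truth codes.
        consensus = coding.build_consensus(
            dataset.coder_a, dataset.coder_b, resolution=dataset.ethogram
        )
        io.write_csv(consensus, out / "consensus.csv")
        counts["coding"] = {
            "intercoder_agreement_pct": agreement,
            "n_discrepant": int(consensus["was_discrepant"].sum()),
        }
    except Exception as exc:
        raise PipelineError("coding", str(exc)) from exc

    # -- velocity ------------------------------------------------------------
    try:
        pair_v = velocity.stream_velocities(dataset.frames)
        origins = dataset.frames.groupby("pen_id")["t_s"].min().to_dict()
        windows = velocity.window_summarize(pair_v, config.window_s, origin=origins)
        io.write_csv(windows, out / "windows.csv")
        counts["velocity"] = {
            "frame_pairs": len(pair_v),
            "windows": len(windows),
            "empty_windows": int((windows["n_frame_pairs"] == 0).sum()),
        }
    except Exception as exc:
        raise PipelineError("velocity", str(exc)) from exc

    # -- link ----------------------------------------------------------------
    try:
        kept_keys = {(r.pen_id, r.t_s) for r in kept}
        labels_kept = consensus[
            [(p, t) in kept_keys for p, t in zip(consensus["pen_id"], consensus["t_s"])]
        ][["pen_id", "t_s", "code"]]
        blur_scores = manifest_rows[["pen_id", "t_s", "blur_score"]]
        linked, n_unmatched = velocity.link(windows, labels_kept, blur_scores=blur_scores)
        io.write_csv(linked, out / "linked.csv")
        counts["link"] = {
            "labels_in": len(consensus),
            "dropped_by_qc": len(consensus) - len(labels_kept),
            "dropped_unmatched": n_unmatched,
            "linked": len(linked),
        }
    except Exception as exc:
        raise PipelineError("link", str(exc)) from exc

    # -- fit -----------------------------------------------------------------
    try:
        if linked.empty:
            raise ValueError("no linked samples survived QC and linking")
        v = linked["v_mps"].to_numpy(float)
        codes = linked["code"].to_numpy(int)
        if config.fit_method == "exhaustive":
            model = threshold.fit_exhaustive(v, codes)
        elif config.fit_method == "mean_plus_sd":
            model = threshold.fit_mean_plus_sd(v[codes == 0])
        else:
            raise ValueError(f"unknown fit method {config.fit_method!r}")
        io.write_json(model.to_dict(), out / "model.json")
        counts["fit"] = {"threshold_mps": model.threshold_mps, "n": int(len(v))}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    # -- evaluate ------------------------------------------------------------
    try:
        report = evaluation.cross_validate(linked, k=config.k, seed=config.seed)
        report_dict = _round_floats(report.to_dict(), config.report_precision)
        io.write_json(report_dict, out / "report.json")
        counts["evaluate"] = {"k": config.k, "averages": report_dict["averages"]}
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    for name in [
        "trajectories.csv", "ethogram.csv", "labels_coder_a.csv", "labels_coder_b.csv",
        "blur_manifest.csv", "consensus.csv", "windows.csv", "linked.csv",
        "model.json", "report.json",
    ]:
        hashes[name] = _sha256(out / name)

    manifest = _round_floats(
        {
            "config": {**asdict(config), "blur_sigmas": list(config.blur_sigmas)},
            "seed": config.seed,
            "stage_counts": counts,
            "input_hashes": hashes,
            "final_metrics": report_dict["averages"],
        },
        config.report_precision,
    )
    io.write_json(manifest, out / "manifest.json")
    return RunResult(manifest=manifest, report=report, model=model, linked=linked)
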