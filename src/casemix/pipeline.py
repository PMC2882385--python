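"""End-to-end orchestration: simulate → score → split → fit → validate → benchmark → compare.

A :class:`RunConfig` fixes all stage options and one global seed.  The run
writes, into the output directory: the discharge table (when simulated), the
fitted model JSON, the decile calibration CSV, the per-hospital benchmarks
CSV, the OE table CSV, the reclassification-matrix CSV, the group-comparison
CSV, and a ``manifest.json`` recording seed, versions, config hash and
record counts.  Stage timings go to the log only, so manifests from two runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, benchmarking, comorbidity, hospital_comparison, io, risk_model, validation
from .synthetic_data import CovariateMarginals, GeneratorConfig, hospital_metadata, simulate

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("casemix")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs."""

    out_dir: Path
    seed: int = 0
    input_path: Optional[Path] = None  # skip simulation when given
    split_fraction: float = 0.5
    cindex_cutoff: float = 0.8
    oe_bin_edges: tuple = benchmarking.DEFAULT_OE_BIN_EDGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    plots: bool = False

    def validate(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not 0 < self.cindex_cutoff < 1:
            raise ValueError("cindex_cutoff must lie in (0, 1)")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ValueError(f"input_path does not exist: {self.input_path}")
        self.generator.validate()

    @classmethod
    def from_yaml(cls, path, out_dir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_raw = raw.pop("generator", {})
        marg_raw = gen_raw.pop("covariate_marginals", None)
        gen = GeneratorConfig(**gen_raw)
        if marg_raw:
            gen.covariate_marginals = CovariateMarginals(**marg_raw)
        cfg = cls(out_dir=Path(raw.pop("out_dir", out_dir or ".")), generator=gen, **raw)
        if out_dir is not None:
            cfg.out_dir = Path(out_dir)
        if seed is not None:
            cfg.seed = seed
            cfg.generator.seed = seed
        return cfg

    def to_payload(self) -> dict:
        gen = dataclasses.asdict(self.generator)
        coeffs = gen.pop("true_coefficients", None)
        if coeffs is not None and self.generator.true_coefficients is not None:
            gen["true_coefficients"] = {
                "intercept": self.generator.true_coefficients.intercept,
                "log_odds": self.generator.true_coefficients.values.to_dict(),
            }
        return {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "input_path": None if self.input_path is None else str(self.input_path),
            "split_fraction": self.split_fraction,
            "cindex_cutoff": self.cindex_cutoff,
            "oe_bin_edges": list(self.oe_bin_edges),
            "generator": gen,
        }


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
            return False
        log.info("stage %s: done in %.1fs", self.name, dt)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.generator.seed = config.seed
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    metadata = None
    with _Stage("simulate"):
        if config.input_path is not None:
            records, rejects = io.read_discharges(config.input_path)
            counts["rejected_rows"] = len(rejects)
            if len(rejects):
                rejects_path = out / "rejects.csv"
                rejects.to_csv(rejects_path, index=False)
                outputs["rejects"] = rejects_path.name
        else:
            hospitals, records, coeffs = simulate(config.generator)
            metadata = hospital_metadata(hospitals)
            rec_path = out / "records.csv"
            io.write_discharges(
                records,
                rec_path,
                sidecar={
                    "generator": config.to_payload()["generator"],
                    "true_intercept": coeffs.intercept,
                    "true_log_odds": coeffs.values.to_dict(),
                },
            )
            meta_path = out / "hospitals.csv"
            metadata.to_csv(meta_path)
            outputs["records"] = rec_path.name
            outputs["hospital_metadata"] = meta_path.name
        counts["records"] = len(records)
        log.info("%d discharge records from %d hospitals",
                 len(records), records["hospital_id"].nunique())

    with _Stage("charlson"):
        scored = comorbidity.score_code_strings(records["comorbidity_codes"])
        records = pd.concat([records, scored], axis=1)

    with _Stage("split"):
        dev, val = risk_model.split(records, fraction=config.split_fraction, seed=config.seed)
        counts["development"] = len(dev)
        counts["validation"] = len(val)
        log.info("split: %d development / %d validation", len(dev), len(val))

    with _Stage("fit"):
        X_dev = risk_model.encode_frame(dev)
        model = risk_model.fit(X_dev, dev["died"])
        model.seed = config.seed
        model_path = out / "model.json"
        model.to_json(model_path)
        outputs["model"] = model_path.name

    with _Stage("validate"):
        X_val = risk_model.encode_frame(val)
        preds_val = risk_model.predict_risk(model, X_val)
        cidx = validation.c_index(preds_val, val["died"].to_numpy())
        calib = validation.decile_calibration(preds_val, val["died"].to_numpy())
        calib_path = out / "calibration.csv"
        calib.to_csv(calib_path, index=False)
        outputs["calibration"] = calib_path.name
        log.info("validation c-index: %.4f", cidx)
        if config.plots:
            validation.plot_calibration(calib, out / "calibration.png")
            outputs["calibration_plot"] = "calibration.png"

    with _Stage("benchmark"):
        X_all = risk_model.encode_frame(records)
        preds_all = risk_model.predict_risk(model, X_all)
        benchmarks = benchmarking.summarize_hospitals(
            records["hospital_id"], preds_all, records["died"].to_numpy()
        )
        benchmarks, groups = benchmarking.classify_by_cindex(benchmarks, cutoff=config.cindex_cutoff)
        included = benchmarks[benchmarks["group"] != "excluded"]
        oe = benchmarking.oe_table(included, config.oe_bin_edges)
        reclass = benchmarking.quartile_matrix(included)
        counts["hospitals"] = len(benchmarks)
        counts["hospitals_excluded"] = int((benchmarks["group"] == "excluded").sum())
        bench_path = out / "benchmarks.csv"
        benchmarks.to_csv(bench_path)
        oe_path = out / "oe_table.csv"
        oe.to_csv(oe_path, index=False)
        reclass_path = out / "reclassification.csv"
        reclass.to_frame().to_csv(reclass_path)
        groups_path = out / "cindex_groups.csv"
        groups.to_csv(groups_path)
        outputs.update(
            benchmarks=bench_path.name, oe_table=oe_path.name,
            reclassification=reclass_path.name, cindex_groups=groups_path.name,
        )
        log.info(
            "reclassified off-diagonal: %d of %d hospitals (%.0f%%)",
            reclass.off_diagonal_count, reclass.total, reclass.off_diagonal_percent,
        )
        if config.plots:
            benchmarking.plot_expected_observed(benchmarks, out / "expected_observed.png")
            outputs["expected_observed_plot"] = "expected_observed.png"

    with _Stage("compare"):
        profiles = hospital_comparison.hospital_profile_table(records, metadata)
        try:
            comparison = hospital_comparison.compare_groups(included, profiles)
            comp_path = out / "comparison.csv"
            comparison.to_csv(comp_path, index=False)
            outputs["comparison"] = comp_path.name
        except ValueError as exc:
            log.warning("group comparison skipped: %s", exc)

    manifest = {
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "config": config.to_payload(),
        "config_hash": io.config_hash(config.to_payload()),
        "counts": counts,
        "validation_c_index": round(float(cidx), 6),
        "outputs": dict(sorted(outputs.items())),
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
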