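"""End-to-end orchestration: simulate -> cohort -> encode -> train -> contribute.

A single :class:`PipelineConfig` (optionally loaded from YAML) nests the
stage configs; :func:`run_pipeline` executes the stages in order, writes
every intermediate artifact as UTF-8 TSV/JSON(L) under the output directory,
and finishes with a run manifest recording file digests, row counts and the
seeds used, so a rerun with the same config can be verified byte-for-byte
on the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ehr_io
from .cohort import CohortConfig, CohortSample, Visit, build_cohort
from .contribution import ContributionConfig, analyze_contributions, build_fc_table, round_sig
from .encoding import EncodedSample, EncodingConfig, FeatureEncoder
from .models import ModelConfig, RunReport, auroc, repeat_runs, train_model
from .synthetic import PlantedEffect, SimConfig, generate_population

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    contribution: ContributionConfig = field(default_factory=ContributionConfig)
    n_runs: int = 1          # >1 adds a repeated-seed AUROC report
    seed: int | None = None  # when set, overrides every stage seed

    def resolved(self) -> "PipelineConfig":
        """Apply the global seed to the stage configs (sim, cohort, model)."""
        if self.seed is None:
            return self
        return dataclasses.replace(
            self,
            sim=dataclasses.replace(self.sim, seed=self.seed),
            cohort=dataclasses.replace(self.cohort, seed=self.seed + 1),
            model=dataclasses.replace(self.model, seed=self.seed + 2),
        )

    def validate(self) -> None:
        self.sim.validate()
        self.cohort.validate()
        self.model.validate()
        self.contribution.validate()

    # -- YAML ---------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim_raw = dict(raw.get("sim", {}))
        effects = [PlantedEffect(**e) for e in sim_raw.pop("planted_effects", [])]
        sim = SimConfig(**sim_raw, planted_effects=effects)
        cohort_raw = dict(raw.get("cohort", {}))
        if "split_ratio" in cohort_raw:
            cohort_raw["split_ratio"] = tuple(cohort_raw["split_ratio"])
        enc_raw = dict(raw.get("encoding", {}))
        if "domains" in enc_raw:
            enc_raw["domains"] = tuple(enc_raw["domains"])
        return cls(
            sim=sim,
            cohort=CohortConfig(**cohort_raw),
            encoding=EncodingConfig(**enc_raw),
            model=ModelConfig(**raw.get("model", {})),
            contribution=ContributionConfig(**raw.get("contribution", {})),
            n_runs=raw.get("n_runs", 1),
            seed=raw.get("seed"),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["planted_effects"] = [dataclasses.asdict(e) for e in self.sim.planted_effects]
        return d


# ---------------------------------------------------------------------------
# sample (de)serialization


def cohort_to_jsonl(samples: list[CohortSample], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps({
                "patient_id": s.patient_id,
                "index_date": s.index_date.isoformat(),
                "label": s.label,
                "history": [[v.days_before_index, [list(e) for e in v.events]]
                            for v in s.history],
            }) + "\n")


def cohort_from_jsonl(path) -> list[CohortSample]:
    import datetime
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(CohortSample(
                d["patient_id"],
                datetime.date.fromisoformat(d["index_date"]),
                d["label"],
                [Visit(days, tuple((dom, code, flag) for dom, code, flag in events))
                 for days, events in d["history"]],
            ))
    return out


def encoded_to_jsonl(samples: list[EncodedSample], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(json.dumps({
                "patient_id": s.patient_id,
                "index_date": str(s.index_date),
                "label": s.label,
                "visits": [[d, list(t)] for d, t in s.visits],
            }) + "\n")


def encoded_from_jsonl(path) -> list[EncodedSample]:
    out = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            out.append(EncodedSample(
                d["patient_id"], d["index_date"], d["label"],
                [(v[0], list(v[1])) for v in d["visits"]],
            ))
    return out


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig, out_dir, analysis_partitions: str = "all") -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    ``analysis_partitions`` selects the samples entering contribution
    analysis: ``"all"`` (default; maximises per-feature support) or
    ``"test"`` (held-out only).
    """
    config = config.resolved()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pipeline.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    manifest: dict = {"stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def record(stage: str, files: dict[str, Path], counts: dict) -> None:
        manifest["stages"][stage] = {
            "files": {k: {"path": str(p), "sha256": ehr_io.file_digest(p)}
                      for k, p in files.items()},
            "counts": counts,
        }

    # 1. simulate ----------------------------------------------------------
    timelines = generate_population(config.sim)
    events_path, patients_path = out / "events.tsv", out / "patients.tsv"
    ehr_io.write_events(timelines, events_path, patients_path)
    record("simulate", {"events": events_path, "patients": patients_path}, {
        "patients": len(timelines),
        "encounters": sum(len(t.encounters) for t in timelines),
        "events": sum(len(ev) for t in timelines for (_, _, ev) in t.encounters),
        "sres": sum(len(t.sre_dates) for t in timelines),
        "seed": config.sim.seed,
    })

    # 2. cohort ------------------------------------------------------------
    cohort = build_cohort(timelines, config.cohort)
    cohort_files = {}
    for part in ("train", "valid", "test"):
        p = out / f"cohort_{part}.jsonl"
        cohort_to_jsonl(cohort[part], p)
        cohort_files[part] = p
    summary = pd.DataFrame([
        {"partition": part,
         "cases": sum(s.label for s in cohort[part]),
         "controls": sum(1 - s.label for s in cohort[part]),
         "samples": len(cohort[part])}
        for part in ("train", "valid", "test")
    ])
    summary_path = out / "cohort_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, lineterminator="\n")
    cohort_files["summary"] = summary_path
    record("build-cohort", cohort_files, cohort["counts"])

    # 3. encode ------------------------------------------------------------
    encoder = FeatureEncoder(config.encoding).fit(cohort["train"])
    encoded = {part: encoder.encode(cohort[part]) for part in ("train", "valid", "test")}
    enc_files = {}
    for part, samples in encoded.items():
        p = out / f"encoded_{part}.jsonl"
        encoded_to_jsonl(samples, p)
        enc_files[part] = p
    vocab_path = out / "vocabulary.tsv"
    encoder.vocab.save(vocab_path)
    enc_files["vocabulary"] = vocab_path
    record("encode", enc_files, {
        "vocabulary": len(encoder.vocab),
        "oov_dropped": encoder.vocab.oov_count,
        "retained_labs": len(encoder.retained_labs),
    })

    # 4. train -------------------------------------------------------------
    model, log = train_model(config.model, encoded["train"], encoded["valid"])
    y_test = np.array([s.label for s in encoded["test"]], dtype=float)
    test_auroc = auroc(y_test, model.predict(encoded["test"]))
    report: RunReport | None = None
    if config.n_runs > 1:
        report = repeat_runs(config.model, encoded["train"], encoded["valid"],
                             encoded["test"], n_runs=config.n_runs)
    train_report = {
        "architecture": config.model.architecture,
        "valid_auroc": log.best_valid_auroc,
        "test_auroc": test_auroc,
        "epochs_trained": len(log.epochs),
        "best_epoch": log.best_epoch,
        "seed": config.model.seed,
    }
    if report is not None:
        train_report["repeats"] = report.to_dict()
    train_path = out / "train_report.json"
    train_path.write_text(json.dumps(train_report, indent=2))
    record("train", {"report": train_path}, {
        "epochs": len(log.epochs), "valid_auroc": log.best_valid_auroc,
        "test_auroc": test_auroc,
    })

    # 5. contribute --------------------------------------------------------
    if analysis_partitions == "test":
        analysis_samples = encoded["test"]
    else:
        analysis_samples = encoded["train"] + encoded["valid"] + encoded["test"]
    features = set(encoder.vocab.index.values())
    fc_table = build_fc_table(model, analysis_samples, features, config.contribution)
    names = {i: t for t, i in encoder.vocab.index.items()}
    results, exclusions = analyze_contributions(fc_table, config.contribution, names)
    rc_path, excl_path = out / "rc_table.tsv", out / "rc_exclusions.tsv"
    results.to_csv(rc_path, sep="\t", index=False, lineterminator="\n")
    exclusions.to_csv(excl_path, sep="\t", index=False, lineterminator="\n")
    (out / "rc_table.json").write_text(results.to_json(orient="records", indent=2))
    record("contribute", {"rc_table": rc_path, "exclusions": excl_path}, {
        "features_tested": len(results),
        "features_significant": int(results["significant"].sum()) if len(results) else 0,
        "features_excluded": len(exclusions),
    })

    # 6. rendered tables ---------------------------------------------------
    table_files = render_tables(results, train_report, out)
    record("report", table_files, {"tables": len(table_files)})

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _fmt_sig(x: float) -> str:
    v = round_sig(float(x), 3)
    return f"{v:.6g}"


def _fmt_p(x: float) -> str:
    return f"{float(x):.3g}"


def render_tables(results: pd.DataFrame, train_report: dict, out_dir) -> dict:
    """Publication-shaped output tables, derived from the JSON twins.

    Writes a model-performance summary and one relative-contribution table
    per feature domain (lab / medication / diagnosis) listing only the
    significant features, RC and CI bounds rounded to 3 significant figures.
    """
    out = Path(out_dir)
    files: dict[str, Path] = {}

    perf_rows = [{
        "Model": train_report["architecture"].upper(),
        "Valid AUC": f"{train_report['valid_auroc']:.3f}",
        "Test AUC": f"{train_report['test_auroc']:.3f}",
    }]
    if "repeats" in train_report:
        r = train_report["repeats"]
        perf_rows[0].update({
            "Valid AUC": f"{r['valid_mean']:.3f}",
            "Test AUC": f"{r['test_mean']:.3f}",
            "Valid AUC std": f"{r['valid_std']:.3f}",
            "Test AUC std": f"{r['test_std']:.3f}",
        })
    perf_path = out / "table_performance.tsv"
    pd.DataFrame(perf_rows).to_csv(perf_path, sep="\t", index=False, lineterminator="\n")
    files["performance"] = perf_path

    name_col = "feature_name" if "feature_name" in results.columns else "feature"
    domains = {"LAB:": "lab", "MED:": "medication", "DX:": "diagnosis"}
    sig = results[results["significant"]] if len(results) else results
    for prefix, label in domains.items():
        if len(sig):
            rows = sig[sig[name_col].astype(str).str.startswith(prefix)]
        else:
            rows = sig
        table = pd.DataFrame({
            "Feature Name": rows[name_col].astype(str).str.slice(len(prefix)) if len(rows) else [],
            "Relative Contribution": rows["rc"].map(_fmt_sig) if len(rows) else [],
            "CI95up": rows["ci95_high"].map(_fmt_sig) if len(rows) else [],
            "CI95down": rows["ci95_low"].map(_fmt_sig) if len(rows) else [],
            "FDR_Q": rows["q_fdr"].map(_fmt_p) if len(rows) else [],
            "p (Bonferroni adjusted)": rows["p_bonferroni"].map(_fmt_p) if len(rows) else [],
        })
        p = out / f"table_rc_{label}.tsv"
        table.to_csv(p, sep="\t", index=False, lineterminator="\n")
        files[label] = p
    return files
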