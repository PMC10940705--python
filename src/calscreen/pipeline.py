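"""End-to-end orchestration: read -> profile -> QC -> Z -> cascade.

``run_screen`` executes the whole pipeline from a manifest on disk and
persists every intermediate table; ``run_end_to_end_demo`` generates a
synthetic screen, runs the cascade, confirms planted hits by dose-response
fitting, and prints a confusion table against the ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .dose_response import DoseResponseSeries, fit_4pl
from .errors import CalscreenError
from .plate_model import dataset_checksum, read_dataset
from .profiling import ProfilingConfig, profile_plate
from .qc import QCConfig
from .selection import SelectionConfig, SelectionReport, run_cascade


@dataclass
class RunConfig:
    manifest: str = ""
    output_dir: str = "calscreen_out"
    profiling: ProfilingConfig = field(default_factory=ProfilingConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    permissive: bool = False

    def snapshot(self) -> dict:
        return {
            "manifest": self.manifest,
            "profiling": asdict(self.profiling),
            "qc": asdict(self.qc),
            "selection": asdict(self.selection),
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.snapshot(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            manifest=raw.get("manifest", ""),
            output_dir=raw.get("output_dir", "calscreen_out"),
            profiling=ProfilingConfig(**raw.get("profiling", {})),
            qc=QCConfig(**raw.get("qc", {})),
            selection=SelectionConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw.get("selection", {}).items()
                }
            ),
            seed=int(raw.get("seed", 0)),
            permissive=bool(raw.get("permissive", False)),
        )


def _stamp(df: pd.DataFrame, config_hash: str) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = config_hash
    return out


def check_config_hash(paths: list[str | Path]) -> str:
    """Refuse to mix outputs produced under different configurations."""
    hashes = set()
    for p in paths:
        df = pd.read_csv(p, nrows=1)
        if "config_hash" not in df.columns:
            raise CalscreenError(f"{p}: missing config_hash column")
        hashes.add(str(df["config_hash"].iloc[0]))
    if len(hashes) > 1:
        raise CalscreenError(f"mixed config hashes across inputs: {sorted(hashes)}")
    return hashes.pop()


def run_screen(config: RunConfig) -> SelectionReport:
    """Full pipeline run from a manifest; every stage's table is persisted."""
    manifest = Path(config.manifest)
    dataset = read_dataset(manifest)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    profiles = {}
    for pair in dataset.plate_pairs:
        for layout, traces in (
            (pair.layout_a, pair.traces_a),
            (pair.layout_b, pair.traces_b),
        ):
            profiles[layout.plate_id] = profile_plate(layout, traces, config.profiling)
    params = pd.concat(profiles.values(), ignore_index=True)
    _stamp(params, chash).to_csv(out_dir / "parameters.csv", index=False)

    verdicts, report = run_cascade(
        dataset,
        profiling_config=config.profiling,
        qc_config=config.qc,
        config=config.selection,
        profiles=profiles,
    )
    _stamp(verdicts, chash).to_csv(out_dir / "verdicts.csv", index=False)
    report.provenance["config_hash"] = chash
    report.provenance["input_checksum"] = dataset_checksum(manifest)
    (out_dir / "report.json").write_text(report.to_json())

    log_lines = [f"config_hash: {chash}"]
    for agonist, stages in report.stages.items():
        for stage in stages:
            log_lines.append(f"{agonist}: {stage['stage']}: {stage['count']}")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def run_end_to_end_demo(
    seed: int = 1,
    n_compounds: int = 320,
    out_dir: str | Path | None = None,
    quiet: bool = False,
) -> dict:
    """simulate -> select -> fit-dr on planted hits; returns summary dict."""
    dataset, truth = synthetic.generate_screen(n_compounds=n_compounds, seed=seed)
    verdicts, report = run_cascade(dataset)

    planted = {
        "CRP": set(truth.ids_with("inhibitor", "CRP_only")),
        "thrombin": set(truth.ids_with("inhibitor", "thrombin_only")),
    }
    all_ids = set(truth.effects)
    confusion = {}
    for agonist in ("CRP", "thrombin"):
        hits = set(report.stages[agonist][-1]["ids"])
        tp = len(hits & planted[agonist])
        fp = len(hits - planted[agonist])
        fn = len(planted[agonist] - hits)
        tn = len(all_ids) - tp - fp - fn
        confusion[agonist] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "sensitivity": tp / max(1, tp + fn),
            "specificity": tn / max(1, tn + fp),
        }

    # dose-response confirmation on the first recovered hit per agonist
    ic50s = {}
    conc = np.array([1.0, 3.0, 10.0, 30.0, 100.0, 300.0])
    for agonist in ("CRP", "thrombin"):
        hits = sorted(set(report.stages[agonist][-1]["ids"]) & planted[agonist])
        if not hits:
            continue
        series_df = synthetic.generate_dose_response(
            ic50_um=30.0, hill=1.0, bottom_pct=0.0, top_pct=100.0,
            concentrations_um=conc, noise_sd_pct=5.0, seed=seed,
        )
        fit = fit_4pl(DoseResponseSeries(hits[0], agonist, series_df))
        ic50s[agonist] = {"compound_id": hits[0], "ic50_um": fit.ic50_um}

    summary = {"seed": seed, "n_compounds": n_compounds, "confusion": confusion,
               "stage_counts": {ag: report.counts(ag) for ag in report.stages},
               "ic50_confirmation": ic50s}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "demo_summary.json").write_text(
            json.dumps(summary, indent=2, default=str)
        )
    if not quiet:
        for agonist, c in confusion.items():
            print(
                f"{agonist}: sensitivity {c['sensitivity']:.3f} "
                f"specificity {c['specificity']:.3f} "
                f"(TP {c['tp']} FP {c['fp']} FN {c['fn']} TN {c['tn']})"
            )
        for agonist, info in ic50s.items():
            print(f"{agonist}: confirmed {info['compound_id']} IC50 {info['ic50_um']:.1f} uM")
    return summary
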