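"""Per-plate normalization, Z-scoring, and the agonist-specific hit cascade.

Per plate, each curve parameter is expressed as percent of the mean of
that plate's agonist-control (vehicle) wells, set at 100 %.  Compound
wells are then Z-scored per parameter: the number of scale units a well
lies from the center of the plate's compound-well distribution.  By
default the center/scale are the median and 1.4826*MAD, which keep the
reference distribution honest when a plate carries strongly interfering
or active compounds; the classical mean / SD (ddof=1) estimator is
available via ``SelectionConfig(robust_z=False)``.  |Z| > 4 on at least
one of P2-P7 calls a compound active; P1 (baseline) is excluded from the
activity call because baseline shifts flag fluorescence interference, not
a Ca2+ response effect.

The selection cascade per agonist:

1. duplicate-consistent (DI <= threshold);
2. active (|Z| > 4 after averaging the A/B normalized parameters);
3. agonist-specific (active with exactly one agonist);
4. inhibitor direction (direction parameters' Z all negative);
5. artifact rejection (injection failure or fluorescence interference);
6. ADMET rejection (external in-silico flag; unknown compounds are
   retained and logged).

Stage counts are non-increasing and each stage's retained set is a subset
of the previous one.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .plate_model import PlateLayout, ScreenDataset
from .profiling import PARAM_COLUMNS, ProfilingConfig, profile_plate
from .qc import (
    QCConfig,
    control_pre_median_summary,
    detect_injection_failure,
    detect_interference,
    difference_index,
)
from . import profiling as _profiling

ACTIVITY_PARAMS_DEFAULT = ("p2", "p3", "p4", "p5", "p6", "p7")
DIRECTION_PARAMS_DEFAULT = ("p2", "p7")


@dataclass
class SelectionConfig:
    z_threshold: float = 4.0
    active_parameters: tuple[str, ...] = ACTIVITY_PARAMS_DEFAULT
    direction_parameters: tuple[str, ...] = DIRECTION_PARAMS_DEFAULT
    min_active_params: int = 1
    robust_z: bool = True
    min_control_wells: int = 8
    min_compound_wells: int = 16

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ParameterError("z_threshold must be > 0")
        if not set(self.direction_parameters) <= set(self.active_parameters):
            raise ParameterError(
                "direction_parameters must be a subset of active_parameters"
            )


@dataclass
class CompoundVerdict:
    compound_id: str
    per_agonist: dict[str, dict]
    specific_agonist: str  # CRP_only | thrombin_only | both | none
    artifact_rejected: bool
    admet_rejected: object  # True / False / pd.NA (unknown)
    final_hit_for: str  # CRP | thrombin | none


@dataclass
class SelectionReport:
    stages: dict[str, list[dict]]  # agonist -> ordered [{stage, count, ids}]
    provenance: dict = field(default_factory=dict)

    def counts(self, agonist: str) -> list[tuple[str, int]]:
        return [(s["stage"], s["count"]) for s in self.stages[agonist]]

    def retained(self, agonist: str, stage: str) -> list[str]:
        for s in self.stages[agonist]:
            if s["stage"] == stage:
                return list(s["ids"])
        raise KeyError(stage)

    def rejected_at(self, agonist: str, stage: str) -> list[str]:
        stages = self.stages[agonist]
        names = [s["stage"] for s in stages]
        i = names.index(stage)
        previous = set(stages[i - 1]["ids"]) if i > 0 else set()
        return sorted(previous - set(stages[i]["ids"]))

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stages, "provenance": self.provenance},
            indent=2,
            sort_keys=True,
            default=str,
        )


def normalize_to_controls(
    params_by_well: pd.DataFrame,
    layout: PlateLayout,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Express each parameter as percent of the plate's agonist-control mean.

    Parameters whose control mean is exactly 0 (e.g. P5 on plates where no
    decline phase exists) are carried as missing and excluded downstream.
    """
    config = config or SelectionConfig()
    df = params_by_well.copy()
    controls = df[df["role"] == "agonist_control"]
    if len(controls) < config.min_control_wells:
        raise DataError(
            f"plate {layout.plate_id}: {len(controls)} usable agonist-control wells "
            f"(< {config.min_control_wells}); plate rejected"
        )
    for col in PARAM_COLUMNS:
        mean = controls[col].mean()
        if mean == 0.0 or not np.isfinite(mean):
            warnings.warn(
                f"plate {layout.plate_id}: control mean of {col} is 0; "
                f"percent-of-control undefined",
                stacklevel=2,
            )
            df[f"{col}_pct"] = np.nan
        else:
            df[f"{col}_pct"] = df[col] / mean * 100.0
    return df


def zscore_per_plate(
    normalized: pd.DataFrame,
    config: SelectionConfig | None = None,
    group_col: str = "plate",
) -> pd.DataFrame:
    """Z-score percent-of-control parameters per plate over compound wells.

    The reference distribution is the plate's compound wells only; control
    wells receive Z against the same reference.  Zero scale gives Z = 0 for
    the whole parameter with a warning.
    """
    config = config or SelectionConfig()
    df = normalized.copy()
    for col in PARAM_COLUMNS:
        df[f"{col}_z"] = np.nan
    for plate, idx in df.groupby(group_col).groups.items():
        sub = df.loc[idx]
        compounds = sub[sub["role"] == "compound"]
        if len(compounds) < config.min_compound_wells:
            raise DataError(
                f"plate {plate}: {len(compounds)} compound wells "
                f"(< {config.min_compound_wells}) for Z-scoring"
            )
        for col in PARAM_COLUMNS:
            values = compounds[f"{col}_pct"].to_numpy(dtype=float)
            if np.all(np.isnan(values)):
                continue
            if config.robust_z:
                center = np.nanmedian(values)
                scale = 1.4826 * np.nanmedian(np.abs(values - center))
            else:
                center = np.nanmean(values)
                scale = np.nanstd(values, ddof=1)
            if scale == 0.0 or np.isnan(scale):
                warnings.warn(
                    f"plate {plate}: zero spread in {col}; Z set to 0", stacklevel=2
                )
                df.loc[idx, f"{col}_z"] = 0.0
            else:
                df.loc[idx, f"{col}_z"] = (sub[f"{col}_pct"] - center) / scale
    return df


def call_activity(
    zscores: pd.Series | dict,
    config: SelectionConfig | None = None,
) -> tuple[bool, str]:
    """(active, direction) for one compound x agonist from its Z map.

    Active when >= ``min_active_params`` of the activity parameters exceed
    |Z| > threshold.  Direction comes from the direction parameters that
    exceed the threshold: all negative -> inhibitor, all positive ->
    potentiator, otherwise mixed; inactive compounds have direction none.
    """
    config = config or SelectionConfig()
    z = {p: zscores.get(f"{p}_z", np.nan) for p in config.active_parameters}
    exceed = {p: v for p, v in z.items() if np.isfinite(v) and abs(v) > config.z_threshold}
    active = len(exceed) >= config.min_active_params
    if not active:
        return False, "none"
    dir_hits = [exceed[p] for p in config.direction_parameters if p in exceed]
    if not dir_hits:
        direction = "mixed"
    elif all(v < 0 for v in dir_hits):
        direction = "inhibitor"
    elif all(v > 0 for v in dir_hits):
        direction = "potentiator"
    else:
        direction = "mixed"
    return True, direction


def log2_effect_matrix(normalized: pd.DataFrame, index: str = "compound_id") -> pd.DataFrame:
    """log2(percent-of-control / 100) per parameter; non-positive -> missing."""
    cols = {f"{p}_pct": p.upper() for p in PARAM_COLUMNS}
    sub = normalized[[index] + list(cols)].set_index(index).rename(columns=cols)
    with np.errstate(divide="ignore", invalid="ignore"):
        mat = np.log2(sub.where(sub > 0) / 100.0)
    return mat


def _pair_qc(pair, profiles: dict[str, pd.DataFrame], qc_config: QCConfig,
             profiling_config: ProfilingConfig) -> pd.DataFrame:
    """DI + artifact flags per compound for one A/B plate pair."""
    placement = pair.layout_a.compound_placement()
    agonist = pair.agonist
    rows = []
    flags_per_plate = {}
    for layout, traces in ((pair.layout_a, pair.traces_a), (pair.layout_b, pair.traces_b)):
        prof = profiles[layout.plate_id].set_index("well")
        controls = layout.wells_with_role("agonist_control") + layout.wells_with_role(
            "buffer_control"
        )
        inj_idx = int(prof["injection_index"].iloc[0])
        pre_summary = control_pre_median_summary(traces, controls, inj_idx)
        ctrl_prof = profiles[layout.plate_id]
        ctrl_p2 = ctrl_prof.loc[ctrl_prof["role"] == "agonist_control", "p2"]
        p2_summary = (float(ctrl_p2.median()), float((ctrl_p2 - ctrl_p2.median()).abs().median()))
        per_well = {}
        for well, cid in placement.items():
            trace = traces[well]
            inj = int(prof.loc[well, "injection_index"])
            flags = detect_interference(trace, inj, pre_summary, qc_config)
            params = _profiling.CurveParameters(
                plate_id=layout.plate_id,
                well_id=well,
                p1_baseline_au=float(prof.loc[well, "p1"]),
                p2_max_increase_au=float(prof.loc[well, "p2"]),
                p3_slope1_au_s=float(prof.loc[well, "p3"]),
                p4_peak_au=float(prof.loc[well, "p4"]),
                p5_slope2_au_s=float(prof.loc[well, "p5"]),
                p6_slope3_au_s=float(prof.loc[well, "p6"]),
                p7_auc_au_s=float(prof.loc[well, "p7"]),
                f0_au=float(prof.loc[well, "f0"]),
                injection_index=inj,
                peak_index=int(prof.loc[well, "peak_index"]),
            )
            flags.injection_failure = detect_injection_failure(
                trace, inj, params, p2_summary, qc_config
            )
            per_well[cid] = flags
        flags_per_plate[layout.duplicate_tag] = per_well

    prof_a = profiles[pair.layout_a.plate_id].set_index("well")
    prof_b = profiles[pair.layout_b.plate_id].set_index("well")
    for well, cid in sorted(placement.items()):
        assessment = difference_index(
            pair.traces_a[well],
            pair.traces_b[well],
            qc_config,
            injection_index_a=int(prof_a.loc[well, "injection_index"]),
            injection_index_b=int(prof_b.loc[well, "injection_index"]),
            compound_id=cid,
            agonist=agonist,
        )
        fa = flags_per_plate["A"][cid]
        fb = flags_per_plate["B"][cid]
        interference = "none"
        for flag in (fa.interference, fb.interference):
            if flag != "none":
                interference = flag
        rows.append(
            {
                "compound_id": cid,
                "agonist": agonist,
                "well": well,
                "di": assessment.di,
                "consistent": assessment.consistent,
                "interference": interference,  # pair-level OR of well flags
                "injection_failure": fa.injection_failure or fb.injection_failure,
            }
        )
    return pd.DataFrame(rows)


STAGE_NAMES = [
    "screened",
    "duplicate_consistent",
    "active",
    "agonist_specific",
    "inhibitor",
    "artifact_free",
    "admet_pass",
]


def run_cascade(
    dataset: ScreenDataset,
    profiling_config: ProfilingConfig | None = None,
    qc_config: QCConfig | None = None,
    config: SelectionConfig | None = None,
    profiles: dict[str, pd.DataFrame] | None = None,
    qc: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Profile, QC, normalize, Z-score and filter a whole screen.

    Returns (verdicts table, SelectionReport).  ``profiles`` and ``qc`` may
    be supplied to reuse precomputed stage outputs; otherwise they are
    computed here.
    """
    profiling_config = profiling_config or ProfilingConfig()
    qc_config = qc_config or QCConfig()
    config = config or SelectionConfig()

    if profiles is None:
        profiles = {}
        for pair in dataset.plate_pairs:
            for layout, traces in (
                (pair.layout_a, pair.traces_a),
                (pair.layout_b, pair.traces_b),
            ):
                profiles[layout.plate_id] = profile_plate(layout, traces, profiling_config)

    if qc is None:
        qc_frames = [
            _pair_qc(pair, profiles, qc_config, profiling_config)
            for pair in dataset.plate_pairs
        ]
        qc = pd.concat(qc_frames, ignore_index=True)

    # normalize per plate, average A/B per compound, Z per pair group
    normalized_pairs = []
    for pair in dataset.plate_pairs:
        frames = []
        for layout, _ in ((pair.layout_a, None), (pair.layout_b, None)):
            norm = normalize_to_controls(profiles[layout.plate_id], layout, config)
            frames.append(norm)
        both = pd.concat(frames, ignore_index=True)
        pct_cols = [f"{p}_pct" for p in PARAM_COLUMNS]
        averaged = (
            both.groupby(["role", "compound_id", "well"], as_index=False)[pct_cols]
            .mean()
        )
        averaged["plate"] = pair.pair_id
        averaged["agonist"] = pair.agonist
        normalized_pairs.append(averaged)
    merged = pd.concat(normalized_pairs, ignore_index=True)
    zscored = zscore_per_plate(merged, config, group_col="plate")

    # activity per compound x agonist
    compound_rows = zscored[zscored["role"] == "compound"]
    activity: dict[tuple[str, str], tuple[bool, str]] = {}
    for _, row in compound_rows.iterrows():
        activity[(row["compound_id"], row["agonist"])] = call_activity(row, config)

    qc_idx = qc.set_index(["compound_id", "agonist"])
    annotations = dataset.annotations
    admet: dict[str, object] = {}
    if annotations is not None:
        admet = dict(zip(annotations["compound_id"], annotations["admet_fail"]))

    agonists = sorted({pair.agonist for pair in dataset.plate_pairs})
    all_ids = {ag: sorted({cid for cid, a in activity if a == ag}) for ag in agonists}

    def is_consistent(cid: str, ag: str) -> bool:
        try:
            return bool(qc_idx.loc[(cid, ag), "consistent"])
        except KeyError:
            return False

    def is_active(cid: str, ag: str) -> bool:
        # activity usable only when the duplicate pair was consistent
        return is_consistent(cid, ag) and activity.get((cid, ag), (False, "none"))[0]

    stages: dict[str, list[dict]] = {}
    verdict_rows = []
    for ag in agonists:
        others = [o for o in agonists if o != ag]
        ids0 = all_ids[ag]
        s1 = [c for c in ids0 if is_consistent(c, ag)]
        s2 = [c for c in s1 if activity[(c, ag)][0]]
        s3 = []
        for c in s2:
            if not others or any((c, o) not in activity for o in others):
                warnings.warn(
                    f"{c}: screened with only one agonist; treated as non-specific",
                    stacklevel=2,
                )
                continue
            if not any(is_active(c, o) for o in others):
                s3.append(c)
        s4 = [c for c in s3 if activity[(c, ag)][1] == "inhibitor"]
        s5 = []
        for c in s4:
            row = qc_idx.loc[(c, ag)]
            if not row["injection_failure"] and row["interference"] == "none":
                s5.append(c)
        s6 = []
        for c in s5:
            flag = admet.get(c, pd.NA)
            if flag is True:
                continue
            s6.append(c)
        stage_sets = [ids0, s1, s2, s3, s4, s5, s6]
        stages[ag] = [
            {"stage": name, "count": len(ids), "ids": list(ids)}
            for name, ids in zip(STAGE_NAMES, stage_sets)
        ]

    for cid in sorted({c for ids in all_ids.values() for c in ids}):
        per_agonist = {}
        for ag in agonists:
            act, direction = activity.get((cid, ag), (False, "none"))
            per_agonist[ag] = {
                "consistent": is_consistent(cid, ag),
                "active": act,
                "direction": direction,
            }
        active_for = [ag for ag in agonists if is_active(cid, ag)]
        if len(active_for) == 2:
            specific = "both"
        elif active_for == ["CRP"]:
            specific = "CRP_only"
        elif active_for == ["thrombin"]:
            specific = "thrombin_only"
        else:
            specific = "none"
        artifact = False
        for ag in agonists:
            try:
                row = qc_idx.loc[(cid, ag)]
                artifact = artifact or bool(row["injection_failure"]) or row["interference"] != "none"
            except KeyError:
                pass
        final = "none"
        for ag in agonists:
            if cid in stages[ag][-1]["ids"]:
                final = ag
        verdict_rows.append(
            {
                "compound_id": cid,
                "specific_agonist": specific,
                "artifact_rejected": artifact,
                "admet_rejected": admet.get(cid, pd.NA),
                "final_hit_for": final,
                **{
                    f"{ag}_{key}": per_agonist[ag][key]
                    for ag in agonists
                    for key in ("consistent", "active", "direction")
                },
            }
        )

    config_snapshot = {
        "selection": asdict(config),
        "qc": asdict(qc_config),
        "profiling": asdict(profiling_config),
    }
    snap_json = json.dumps(config_snapshot, sort_keys=True, default=str)
    report = SelectionReport(
        stages=stages,
        provenance={
            "config": config_snapshot,
            "config_hash": hashlib.sha256(snap_json.encode()).hexdigest()[:16],
            "n_plate_pairs": len(dataset.plate_pairs),
        },
    )
    return pd.DataFrame(verdict_rows), report
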