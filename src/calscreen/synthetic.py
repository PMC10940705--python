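"""Synthetic plate-screen generator with known ground truth.

Generates phenomenological Ca2+ fluorescence traces: a drifting baseline
(dye leakage), an injection fluorescence drop (large-volume agonist
addition plus tip light-path interference), a linear rise to peak, and
either a transient decay back toward baseline (thrombin-like, 5 min
recording) or a sustained plateau (CRP-like, 10 min recording).  Planted
compound effects scale the baseline-subtracted response (inhibitors and
potentiators), scale the whole trace (autofluorescent and quenching
interferers), or suppress the injection entirely (failed injections).

No receptor kinetics or store-release ODEs are modeled; the templates are
purely descriptive of the assay's observable trace shapes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .plate_model import (
    DEFAULT_1536_ROLE_COUNTS,
    FORMATS,
    PlateLayout,
    PlatePair,
    ScreenDataset,
    WellAssignment,
    WellTrace,
    rowcol_to_well,
)

EFFECT_KINDS = (
    "none",
    "inhibitor",
    "potentiator",
    "autofluorescent",
    "quencher",
    "injection_failure",
)
SELECTIVITIES = ("CRP_only", "thrombin_only", "both")


@dataclass(frozen=True)
class TraceTemplate:
    """Piecewise-linear trace shape for one agonist.

    ``decay_rate_au_s`` is the post-peak decline rate: for transient
    (thrombin-like) responses it runs until the response returns to
    baseline; for sustained (CRP-like) responses it lasts only
    ``post_peak_decay_duration_s`` and is followed by a slow late phase
    with slope ``plateau_slope_au_s`` (a small positive value models the
    secondary late increase of sustained responses).  ``sustained``
    selects between the two shapes.
    """

    agonist: str
    baseline_au: float = 100.0
    injection_drop_au: float = 60.0
    rise_rate_au_s: float = 3.5
    peak_au: float = 500.0
    decay_rate_au_s: float = 2.0
    plateau_slope_au_s: float = 0.03
    post_peak_decay_duration_s: float = 120.0
    sustained: bool = False
    duration_s: float = 360.0
    sample_interval_s: float = 2.0
    leakage_slope_au_s: float = 0.02
    injection_time_s: float = 60.0
    artifact_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.peak_au < self.baseline_au:
            raise ParameterError("template peak must be >= baseline")
        post = self.duration_s - self.injection_time_s
        minimum = 600.0 if self.sustained else 300.0
        if post < minimum:
            raise ParameterError(
                f"{self.agonist} template covers only {post} s after injection; "
                f"needs >= {minimum} s"
            )


def default_templates() -> dict[str, TraceTemplate]:
    """Study-condition templates: CRP sustained 10 min, thrombin 5 min."""
    return {
        "CRP": TraceTemplate(
            agonist="CRP",
            sustained=True,
            duration_s=660.0,
            rise_rate_au_s=2.8,
            decay_rate_au_s=1.0,
        ),
        "thrombin": TraceTemplate(agonist="thrombin", sustained=False),
    }


@dataclass(frozen=True)
class PlantedEffect:
    """Known compound effect planted into the generated screen."""

    compound_id: str
    kind: str = "none"
    magnitude: float = 1.0
    agonist_selectivity: str = "both"

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ParameterError(f"unknown effect kind {self.kind!r}")
        if self.agonist_selectivity not in SELECTIVITIES:
            raise ParameterError(
                f"unknown agonist selectivity {self.agonist_selectivity!r}"
            )
        if self.kind == "inhibitor" and not self.magnitude < 1:
            raise ParameterError("inhibitor magnitude must be < 1")
        if self.kind == "potentiator" and not self.magnitude > 1:
            raise ParameterError("potentiator magnitude must be > 1")
        if self.kind == "none" and self.magnitude != 1.0:
            raise ParameterError("kind='none' requires magnitude 1")
        if self.magnitude < 0:
            raise ParameterError("magnitude must be >= 0")

    def applies_to(self, agonist: str) -> bool:
        if self.kind == "none":
            return False
        if self.agonist_selectivity == "both":
            return True
        return (self.agonist_selectivity == "CRP_only") == (agonist == "CRP")


@dataclass
class GroundTruth:
    """Planted-effect map plus the noise level and master seed used."""

    effects: dict[str, PlantedEffect]
    noise_sd_au: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": e.compound_id,
                "kind": e.kind,
                "magnitude": e.magnitude,
                "selectivity": e.agonist_selectivity,
            }
            for e in self.effects.values()
        ]
        return pd.DataFrame(rows).sort_values("compound_id").reset_index(drop=True)

    def ids_with(self, kind: str, selectivity: str | None = None) -> list[str]:
        return sorted(
            cid
            for cid, e in self.effects.items()
            if e.kind == kind
            and (selectivity is None or e.agonist_selectivity == selectivity)
        )


NO_EFFECT = PlantedEffect(compound_id="", kind="none")


def _well_rng(seed: int, plate_id: str, well_id: str) -> np.random.Generator:
    """Deterministic per-well substream, independent of generation order."""
    key = zlib.crc32(f"{plate_id}/{well_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def noiseless_trace(
    template: TraceTemplate,
    effect: PlantedEffect = NO_EFFECT,
    injection_time_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (time, fluorescence) arrays before noise is added."""
    t_inj = template.injection_time_s if injection_time_s is None else injection_time_s
    if not (0 < t_inj < template.duration_s):
        raise ParameterError("injection time must lie inside the trace span")
    t = np.arange(0.0, template.duration_s + 1e-9, template.sample_interval_s)
    base = template.baseline_au + template.leakage_slope_au_s * t
    f = base.copy()
    if effect.kind != "injection_failure":
        tau = t - t_inj
        post = tau > 0
        # injection artifact: fluorescence drop while the tip disturbs the
        # light path, recovering linearly as the tip withdraws; independent
        # of any compound effect on the response
        artifact = np.where(
            post & (tau <= template.artifact_duration_s),
            -template.injection_drop_au
            * (1.0 - np.clip(tau, 0.0, None) / template.artifact_duration_s),
            0.0,
        )
        # agonist response: linear rise to the peak amplitude, then either
        # transient decay back toward baseline or a sustained plateau
        amplitude = template.peak_au - template.baseline_au
        rise_end = amplitude / template.rise_rate_au_s
        r = np.zeros_like(t)
        rising = post & (tau <= rise_end)
        r[rising] = template.rise_rate_au_s * tau[rising]
        late = post & (tau > rise_end)
        if template.sustained:
            # brief partial decline off the peak, then a slow late phase
            since_peak = tau[late] - rise_end
            dur = template.post_peak_decay_duration_s
            r[late] = (
                amplitude
                - template.decay_rate_au_s * np.minimum(since_peak, dur)
                + template.plateau_slope_au_s * np.maximum(since_peak - dur, 0.0)
            )
        else:
            r[late] = amplitude - template.decay_rate_au_s * (tau[late] - rise_end)
            r[late] = np.maximum(r[late], 0.0)  # decay stops at baseline
        scale = effect.magnitude if effect.kind in ("inhibitor", "potentiator") else 1.0
        f = base + artifact + scale * r
    if effect.kind in ("autofluorescent", "quencher"):
        f = effect.magnitude * f
    return t, f


def generate_trace(
    template: TraceTemplate,
    effect: PlantedEffect,
    injection_time_s: float,
    noise_sd_au: float,
    seed: int,
    plate_id: str = "synthetic",
    well_id: str = "A1",
) -> WellTrace:
    """One seeded noisy trace; identical arguments give bit-identical output."""
    if noise_sd_au < 0:
        raise ParameterError("noise SD must be >= 0")
    applied = effect if effect.applies_to(template.agonist) else NO_EFFECT
    t, f = noiseless_trace(template, applied, injection_time_s)
    if noise_sd_au > 0:
        rng = _well_rng(seed, plate_id, well_id)
        f = f + rng.normal(0.0, noise_sd_au, size=f.size)
    return WellTrace(plate_id=plate_id, well_id=well_id, time_s=t, fluorescence_au=f)


DEFAULT_EFFECT_SPEC: dict[tuple[str, str], float] = {
    # (kind, selectivity) -> fraction of compounds
    ("inhibitor", "CRP_only"): 0.025,
    ("inhibitor", "thrombin_only"): 0.025,
    ("inhibitor", "both"): 0.0125,
    ("potentiator", "CRP_only"): 0.0125,
    ("autofluorescent", "CRP_only"): 0.0125,
    ("quencher", "CRP_only"): 0.0125,
    ("injection_failure", "CRP_only"): 0.0125,
}

DEFAULT_MAGNITUDES = {
    "inhibitor": 0.2,
    "potentiator": 1.5,
    "autofluorescent": 3.0,
    "quencher": 0.2,
    "injection_failure": 1.0,
    "none": 1.0,
}

DEFAULT_NOISE_SD_AU = 8.0  # ~2 % of the 400 AU control response


def _build_layout(
    plate_id: str,
    agonist: str,
    tag: str,
    compound_ids: list[str],
    injection_time_s: float,
    source_plate: str,
) -> PlateLayout:
    """1536-format layout: controls in the outer columns, compounds inside.

    Agonist controls (192) fill columns 1-3, buffer controls (64) fill
    column 4 plus the first 32 wells of column 48, compounds fill the rest
    row-major.  The exact geometry is arbitrary but fixed, so placement is
    reproducible and identical across duplicates.
    """
    n_rows, n_cols = FORMATS["well1536"]
    wells: dict[str, WellAssignment] = {}
    order = [(r, c) for c in range(n_cols) for r in range(n_rows)]
    agonist_slots = order[: DEFAULT_1536_ROLE_COUNTS["agonist_control"]]
    buffer_slots = order[len(agonist_slots) : len(agonist_slots) + DEFAULT_1536_ROLE_COUNTS["buffer_control"]]
    compound_slots = order[len(agonist_slots) + len(buffer_slots) :]
    if len(compound_ids) > len(compound_slots):
        raise ParameterError("more compounds than compound wells on one plate")
    for r, c in agonist_slots:
        wells[rowcol_to_well(r, c)] = WellAssignment(role="agonist_control")
    for r, c in buffer_slots:
        wells[rowcol_to_well(r, c)] = WellAssignment(role="buffer_control")
    for cid, (r, c) in zip(compound_ids, compound_slots):
        wells[rowcol_to_well(r, c)] = WellAssignment(
            role="compound", compound_id=cid, concentration_um=10.0
        )
    return PlateLayout(
        plate_id=plate_id,
        format="well1536",
        agonist=agonist,
        duplicate_tag=tag,
        injection_time_s=injection_time_s,
        wells=wells,
        source_plate=source_plate,
    )


def assign_effects(
    compound_ids: list[str],
    effect_spec: dict[tuple[str, str], float],
    magnitudes: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, PlantedEffect]:
    """Randomly assign planted effects at the requested fractions."""
    total = sum(effect_spec.values())
    if total > 1 + 1e-12:
        raise ParameterError(f"effect fractions sum to {total} > 1")
    n = len(compound_ids)
    shuffled = list(compound_ids)
    rng.shuffle(shuffled)
    effects: dict[str, PlantedEffect] = {}
    pos = 0
    for (kind, selectivity), fraction in effect_spec.items():
        count = int(round(fraction * n))
        for cid in shuffled[pos : pos + count]:
            effects[cid] = PlantedEffect(
                compound_id=cid,
                kind=kind,
                magnitude=magnitudes.get(kind, 1.0),
                agonist_selectivity=selectivity,
            )
        pos += count
    for cid in shuffled[pos:]:
        effects[cid] = PlantedEffect(compound_id=cid, kind="none")
    return effects


def generate_screen(
    n_compounds: int,
    effect_spec: dict[tuple[str, str], float] | None = None,
    templates: dict[str, TraceTemplate] | None = None,
    seed: int = 0,
    noise_sd_au: float = DEFAULT_NOISE_SD_AU,
    magnitudes: dict[str, float] | None = None,
    agonists: tuple[str, ...] = ("CRP", "thrombin"),
) -> tuple[ScreenDataset, GroundTruth]:
    """Generate duplicate A/B plate pairs for each agonist plus ground truth.

    Compounds beyond 1280 spill onto additional plate pairs.  Control wells
    always carry no effect; A and B replicates share placement and planted
    effects but have independent noise (per-well substreams keyed on plate
    and well id, so generation order is irrelevant).
    """
    if n_compounds < 1:
        raise ParameterError("need at least one compound")
    templates = templates or default_templates()
    effect_spec = DEFAULT_EFFECT_SPEC if effect_spec is None else effect_spec
    magnitudes = {**DEFAULT_MAGNITUDES, **(magnitudes or {})}
    compound_ids = [f"CMP{i:05d}" for i in range(1, n_compounds + 1)]
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xA551]))
    effects = assign_effects(compound_ids, effect_spec, magnitudes, rng)

    per_plate = DEFAULT_1536_ROLE_COUNTS["compound"]
    chunks = [
        compound_ids[i : i + per_plate] for i in range(0, n_compounds, per_plate)
    ]
    pairs: list[PlatePair] = []
    for agonist in agonists:
        template = templates[agonist]
        for chunk_no, chunk in enumerate(chunks, start=1):
            source = f"SRC{chunk_no:02d}"
            plate_traces: dict[str, dict[str, WellTrace]] = {}
            plate_layouts: dict[str, PlateLayout] = {}
            for tag in ("A", "B"):
                plate_id = f"{source}-{agonist}-{tag}"
                layout = _build_layout(
                    plate_id, agonist, tag, chunk, template.injection_time_s, f"{source}-{agonist}"
                )
                traces = {}
                for well_id, assign in layout.wells.items():
                    effect = (
                        effects[assign.compound_id]
                        if assign.role == "compound"
                        else NO_EFFECT
                    )
                    if assign.role == "buffer_control":
                        # resting wells: buffer injected instead of agonist;
                        # the drop artifact occurs but no response follows
                        effect = PlantedEffect(
                            compound_id="", kind="inhibitor", magnitude=0.0
                        )
                    traces[well_id] = generate_trace(
                        template,
                        effect,
                        template.injection_time_s,
                        noise_sd_au,
                        seed,
                        plate_id=plate_id,
                        well_id=well_id,
                    )
                plate_traces[tag] = traces
                plate_layouts[tag] = layout
            pairs.append(
                PlatePair(
                    layout_a=plate_layouts["A"],
                    traces_a=plate_traces["A"],
                    layout_b=plate_layouts["B"],
                    traces_b=plate_traces["B"],
                )
            )
    truth = GroundTruth(effects=effects, noise_sd_au=noise_sd_au, seed=seed)
    return ScreenDataset(plate_pairs=pairs), truth


def four_pl(conc_um: np.ndarray, bottom: float, top: float, hill: float, ic50_um: float) -> np.ndarray:
    """Four-parameter logistic response (percent of control)."""
    conc_um = np.asarray(conc_um, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc_um / ic50_um) ** hill)


def generate_dose_response(
    ic50_um: float,
    hill: float,
    bottom_pct: float,
    top_pct: float,
    concentrations_um: np.ndarray,
    noise_sd_pct: float,
    seed: int,
) -> pd.DataFrame:
    """Seeded noisy 4PL series; columns concentration_um, response_pct."""
    conc = np.asarray(concentrations_um, dtype=float)
    if ic50_um <= 0:
        raise ParameterError("ic50 must be > 0")
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")
    if noise_sd_pct < 0:
        raise ParameterError("noise SD must be >= 0")
    resp = four_pl(conc, bottom_pct, top_pct, hill, ic50_um)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD05E]))
        resp = resp + rng.normal(0.0, noise_sd_pct, size=conc.size)
    return pd.DataFrame({"concentration_um": conc, "response_pct": resp})
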