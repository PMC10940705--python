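"""Data model and file I/O for kinetic fluorescence plate screens.

The canonical on-disk trace format is long (tidy) delimited text with
columns ``plate, well, time_s, fluorescence`` -- one row per sample.  Wide
per-plate matrices (time in the first column, one column per well) are
supported read-only through a dialect flag.  Plate layouts are a CSV of
well roles plus a YAML sidecar with per-plate metadata (agonist,
duplicate tag, injection time).

Well ids are letter+number ("A1" ... "AF48" for a 1536-well plate) in all
user-facing input and output; internally rows/columns are 0-based.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, PairingError, ParseError

AGONISTS = ("CRP", "thrombin")
ROLES = ("compound", "agonist_control", "buffer_control")
FORMATS = {"well96": (8, 12), "well1536": (32, 48)}

# Default 1536-well role counts: 192 agonist controls (vehicle),
# 64 buffer controls (resting), 1280 compound wells.
DEFAULT_1536_ROLE_COUNTS = {
    "agonist_control": 192,
    "buffer_control": 64,
    "compound": 1280,
}


def well_to_rowcol(well_id: str) -> tuple[int, int]:
    """Convert "A1"/"AF48" style well ids to 0-based (row, col)."""
    letters = ""
    i = 0
    while i < len(well_id) and well_id[i].isalpha():
        letters += well_id[i].upper()
        i += 1
    digits = well_id[i:]
    if not letters or not digits.isdigit():
        raise FormatError(f"malformed well id {well_id!r}")
    row = 0
    for ch in letters:
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(digits) - 1


def rowcol_to_well(row: int, col: int) -> str:
    """Inverse of :func:`well_to_rowcol` ("A".."Z","AA".."AF",...)."""
    if row < 0 or col < 0:
        raise ValueError("row/col must be non-negative")
    letters = ""
    r = row + 1
    while r > 0:
        r, rem = divmod(r - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return f"{letters}{col + 1}"


@dataclass
class WellTrace:
    """One well's fluorescence time series.

    Attributes
    ----------
    plate_id, well_id : str
        Identity of the well on its plate.
    time_s : ndarray
        Seconds from recording start, strictly increasing.
    fluorescence_au : ndarray
        Raw fluorescence in arbitrary units, same length as ``time_s``.
    """

    plate_id: str
    well_id: str
    time_s: np.ndarray
    fluorescence_au: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence_au = np.asarray(self.fluorescence_au, dtype=float)
        if self.time_s.shape != self.fluorescence_au.shape:
            raise DataError(
                f"{self.plate_id}/{self.well_id}: time and fluorescence lengths differ"
            )
        if self.time_s.size < 10:
            raise DataError(
                f"{self.plate_id}/{self.well_id}: need >= 10 samples, got {self.time_s.size}"
            )
        if not np.all(np.diff(self.time_s) > 0):
            raise DataError(f"{self.plate_id}/{self.well_id}: time not strictly increasing")
        if not np.all(np.isfinite(self.fluorescence_au)):
            raise DataError(f"{self.plate_id}/{self.well_id}: non-finite fluorescence")

    def __len__(self) -> int:
        return int(self.time_s.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WellTrace):
            return NotImplemented
        return (
            self.plate_id == other.plate_id
            and self.well_id == other.well_id
            and np.array_equal(self.time_s, other.time_s)
            and np.array_equal(self.fluorescence_au, other.fluorescence_au)
        )


@dataclass(frozen=True)
class WellAssignment:
    role: str
    compound_id: str = ""
    concentration_um: float | None = None


@dataclass
class PlateLayout:
    """Role/compound assignment and metadata for one physical plate."""

    plate_id: str
    format: str
    agonist: str
    duplicate_tag: str
    injection_time_s: float
    wells: dict[str, WellAssignment] = field(default_factory=dict)
    source_plate: str = ""

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise FormatError(f"unknown plate format {self.format!r}")
        if self.agonist not in AGONISTS:
            raise FormatError(f"unknown agonist {self.agonist!r}")
        if self.duplicate_tag not in ("A", "B"):
            raise FormatError(f"duplicate_tag must be 'A' or 'B', got {self.duplicate_tag!r}")
        n_rows, n_cols = FORMATS[self.format]
        if len(self.wells) > n_rows * n_cols:
            raise DataError(
                f"{self.plate_id}: {len(self.wells)} wells exceeds {self.format} capacity"
            )
        for well_id, assign in self.wells.items():
            row, col = well_to_rowcol(well_id)
            if row >= n_rows or col >= n_cols:
                raise DataError(f"{self.plate_id}: well {well_id} outside {self.format}")
            if assign.role not in ROLES:
                raise FormatError(
                    f"{self.plate_id}/{well_id}: unknown role {assign.role!r} "
                    f"(expected one of {ROLES})"
                )
            if assign.role == "compound" and not assign.compound_id:
                raise DataError(f"{self.plate_id}/{well_id}: compound well lacks compound_id")
        if not self.source_plate:
            self.source_plate = _strip_tag(self.plate_id, self.duplicate_tag)

    def role_counts(self) -> dict[str, int]:
        counts = {role: 0 for role in ROLES}
        for assign in self.wells.values():
            counts[assign.role] += 1
        return counts

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, a in self.wells.items() if a.role == role]

    def compound_placement(self) -> dict[str, str]:
        """Map well_id -> compound_id for compound wells."""
        return {
            w: a.compound_id for w, a in self.wells.items() if a.role == "compound"
        }


def _strip_tag(plate_id: str, tag: str) -> str:
    for sep in ("-", "_", "."):
        suffix = f"{sep}{tag}"
        if plate_id.endswith(suffix):
            return plate_id[: -len(suffix)]
    return plate_id


@dataclass
class PlatePair:
    """A/B duplicate plates sharing agonist and compound placement."""

    layout_a: PlateLayout
    traces_a: dict[str, WellTrace]
    layout_b: PlateLayout
    traces_b: dict[str, WellTrace]

    @property
    def agonist(self) -> str:
        return self.layout_a.agonist

    @property
    def pair_id(self) -> str:
        return f"{self.layout_a.source_plate}:{self.agonist}"

    def compound_ids(self) -> list[str]:
        return sorted(set(self.layout_a.compound_placement().values()))


@dataclass
class ScreenDataset:
    """All plate pairs of a screen plus optional compound annotations."""

    plate_pairs: list[PlatePair]
    annotations: pd.DataFrame | None = None  # columns: compound_id, library, admet_fail

    def compound_ids(self) -> list[str]:
        ids: set[str] = set()
        for pair in self.plate_pairs:
            ids.update(pair.compound_ids())
        return sorted(ids)

    def pairs_for(self, agonist: str) -> list[PlatePair]:
        return [p for p in self.plate_pairs if p.agonist == agonist]


# ---------------------------------------------------------------------------
# Trace I/O


def read_traces(
    path: str | Path,
    dialect: str = "long",
    plate_id: str | None = None,
) -> list[WellTrace]:
    """Read well traces from delimited text.

    ``dialect="long"`` expects columns ``plate, well, time_s, fluorescence``;
    row order in the file is irrelevant.  ``dialect="wide"`` (read-only)
    expects ``time_s`` in the first column and one column per well, with the
    plate id taken from ``plate_id`` or the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        return _read_traces_long(path)
    if dialect == "wide":
        return _read_traces_wide(path, plate_id or path.stem)
    raise FormatError(f"unknown trace dialect {dialect!r}")


def _read_traces_long(path: Path) -> list[WellTrace]:
    df = pd.read_csv(path, dtype=str)
    for col in ("plate", "well", "time_s", "fluorescence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("time_s", "fluorescence"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-numeric {col!r} value {df.loc[bad.idxmax(), col]!r} on line {line}"
            )
        if numeric.isna().any():
            line = int(df.index[numeric.isna()][0]) + 2
            raise ParseError(f"{path}: missing {col!r} value on line {line}")
        # astype is correctly rounded (bit-exact round trip); to_numeric is not
        df[col] = df[col].astype(float)
    dup = df.duplicated(subset=["plate", "well", "time_s"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataError(
            f"{path}: duplicate sample for plate={row['plate']} well={row['well']} "
            f"time_s={row['time_s']}"
        )
    traces = []
    for (plate, well), grp in df.groupby(["plate", "well"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            WellTrace(
                plate_id=str(plate),
                well_id=str(well),
                time_s=grp["time_s"].to_numpy(),
                fluorescence_au=grp["fluorescence"].to_numpy(),
            )
        )
    return traces


def _read_traces_wide(path: Path, plate_id: str) -> list[WellTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: wide dialect requires first column 'time_s'")
    time_s = pd.to_numeric(df["time_s"], errors="raise").to_numpy()
    traces = []
    for col in df.columns[1:]:
        traces.append(
            WellTrace(
                plate_id=plate_id,
                well_id=str(col),
                time_s=time_s,
                fluorescence_au=pd.to_numeric(df[col], errors="raise").to_numpy(),
            )
        )
    return traces


def write_traces(traces: Iterable[WellTrace], path: str | Path) -> None:
    """Write traces in the long dialect at full float precision."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "plate": tr.plate_id,
                    "well": tr.well_id,
                    "time_s": tr.time_s,
                    "fluorescence": tr.fluorescence_au,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Layout I/O


def read_layout(path: str | Path, sidecar: str | Path | None = None) -> PlateLayout:
    """Read a plate layout CSV plus its YAML sidecar.

    The CSV has columns ``well, role, compound_id, concentration_um``; the
    sidecar (default: same stem with ``.yaml``) carries ``plate_id, format,
    agonist, duplicate_tag, injection_time_s`` and optionally
    ``source_plate``.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    meta = yaml.safe_load(sidecar.read_text())
    if not isinstance(meta, dict):
        raise FormatError(f"{sidecar}: sidecar must be a key: value mapping")
    for key in ("plate_id", "agonist", "duplicate_tag", "injection_time_s"):
        if key not in meta:
            raise FormatError(f"{sidecar}: missing sidecar key {key!r}")
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("well", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    wells: dict[str, WellAssignment] = {}
    for _, row in df.iterrows():
        conc = row.get("concentration_um", "")
        wells[str(row["well"])] = WellAssignment(
            role=str(row["role"]),
            compound_id=str(row.get("compound_id", "")),
            concentration_um=float(conc) if conc not in ("", None) else None,
        )
    return PlateLayout(
        plate_id=str(meta["plate_id"]),
        format=str(meta.get("format", "well1536")),
        agonist=str(meta["agonist"]),
        duplicate_tag=str(meta["duplicate_tag"]),
        injection_time_s=float(meta["injection_time_s"]),
        wells=wells,
        source_plate=str(meta.get("source_plate", "")),
    )


def write_layout(layout: PlateLayout, path: str | Path, sidecar: str | Path | None = None) -> None:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(".yaml")
    rows = [
        {
            "well": w,
            "role": a.role,
            "compound_id": a.compound_id,
            "concentration_um": "" if a.concentration_um is None else repr(a.concentration_um),
        }
        for w, a in layout.wells.items()
    ]
    pd.DataFrame(rows, columns=["well", "role", "compound_id", "concentration_um"]).to_csv(
        path, index=False
    )
    meta = {
        "plate_id": layout.plate_id,
        "format": layout.format,
        "agonist": layout.agonist,
        "duplicate_tag": layout.duplicate_tag,
        "injection_time_s": float(layout.injection_time_s),
        "source_plate": layout.source_plate,
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a compound annotation table (compound_id, library, admet_fail).

    ``admet_fail`` is parsed as boolean where present; empty/missing values
    are kept as NA (unknown) and never invented.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "compound_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'compound_id'")
    if "library" not in df.columns:
        df["library"] = ""
    truthy = {"true", "1", "yes", "y"}
    falsy = {"false", "0", "no", "n"}

    def parse_flag(v: str):
        s = str(v).strip().lower()
        if s in truthy:
            return True
        if s in falsy:
            return False
        if s == "":
            return pd.NA
        raise ParseError(f"{path}: cannot parse admet_fail value {v!r}")

    if "admet_fail" in df.columns:
        df["admet_fail"] = df["admet_fail"].map(parse_flag)
    else:
        df["admet_fail"] = pd.NA
    return df[["compound_id", "library", "admet_fail"]]


# ---------------------------------------------------------------------------
# Pairing


def pair_plates(
    layouts_and_traces: Sequence[tuple[PlateLayout, Mapping[str, WellTrace]]],
    annotations: pd.DataFrame | None = None,
) -> ScreenDataset:
    """Group plates into A/B duplicate pairs per (agonist, source plate).

    Raises :class:`PairingError` listing orphan plates when a group does not
    contain exactly one A and one B plate, and :class:`DataError` naming the
    first mismatched well when paired plates disagree on compound placement.
    """
    groups: dict[tuple[str, str], dict[str, tuple[PlateLayout, dict[str, WellTrace]]]] = {}
    for layout, traces in layouts_and_traces:
        traces = dict(traces)
        for well_id in traces:
            if well_id not in layout.wells:
                raise DataError(
                    f"{layout.plate_id}: trace well {well_id} not present in layout"
                )
        key = (layout.agonist, layout.source_plate)
        slot = groups.setdefault(key, {})
        if layout.duplicate_tag in slot:
            raise PairingError(
                f"two {layout.duplicate_tag!r} plates for agonist={key[0]} "
                f"source={key[1]}"
            )
        slot[layout.duplicate_tag] = (layout, traces)

    orphans = [
        f"{key[1]} ({key[0]}, only {'/'.join(sorted(slot))})"
        for key, slot in groups.items()
        if set(slot) != {"A", "B"}
    ]
    if orphans:
        raise PairingError("unpaired plates: " + "; ".join(sorted(orphans)))

    pairs = []
    for key in sorted(groups):
        (layout_a, traces_a) = groups[key]["A"]
        (layout_b, traces_b) = groups[key]["B"]
        placement_a = layout_a.compound_placement()
        placement_b = layout_b.compound_placement()
        for well in sorted(set(placement_a) | set(placement_b)):
            if placement_a.get(well) != placement_b.get(well):
                raise DataError(
                    f"placement mismatch at well {well}: "
                    f"{layout_a.plate_id} has {placement_a.get(well)!r}, "
                    f"{layout_b.plate_id} has {placement_b.get(well)!r}"
                )
        pairs.append(PlatePair(layout_a, traces_a, layout_b, traces_b))
    return ScreenDataset(plate_pairs=pairs, annotations=annotations)


# ---------------------------------------------------------------------------
# Dataset round trip


def write_dataset(dataset: ScreenDataset, out_dir: str | Path) -> Path:
    """Persist a dataset as plate CSVs plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for pair in dataset.plate_pairs:
        for layout, traces in (
            (pair.layout_a, pair.traces_a),
            (pair.layout_b, pair.traces_b),
        ):
            stem = layout.plate_id.replace("/", "_")
            trace_path = out_dir / f"{stem}.traces.csv"
            layout_path = out_dir / f"{stem}.layout.csv"
            write_traces(traces.values(), trace_path)
            write_layout(layout, layout_path)
            entries.append(
                {
                    "traces": trace_path.name,
                    "layout": layout_path.name,
                    "sidecar": layout_path.with_suffix(".yaml").name,
                }
            )
    manifest = {"plates": entries}
    if dataset.annotations is not None:
        ann_path = out_dir / "annotations.csv"
        dataset.annotations.to_csv(ann_path, index=False)
        manifest["annotations"] = ann_path.name
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def read_dataset(manifest_path: str | Path) -> ScreenDataset:
    """Load a dataset from a manifest written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    items = []
    for entry in manifest["plates"]:
        trace_path = base / entry["traces"]
        layout_path = base / entry["layout"]
        for p in (trace_path, layout_path):
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        layout = read_layout(layout_path, base / entry.get("sidecar", layout_path.with_suffix(".yaml").name))
        traces = {tr.well_id: tr for tr in read_traces(trace_path)}
        items.append((layout, traces))
    annotations = None
    if "annotations" in manifest:
        annotations = read_annotations(base / manifest["annotations"])
    return pair_plates(items, annotations=annotations)


def dataset_checksum(manifest_path: str | Path) -> str:
    """SHA-256 over the manifest and every file it references (provenance)."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    digest = hashlib.sha256()
    paths = [manifest_path]
    for entry in manifest.get("plates", []):
        for key in ("traces", "layout", "sidecar"):
            if key in entry:
                paths.append(manifest_path.parent / entry[key])
    if "annotations" in manifest:
        paths.append(manifest_path.parent / manifest["annotations"])
    for p in sorted(set(paths)):
        digest.update(p.name.encode())
        digest.update(p.read_bytes())
    return digest.hexdigest()
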