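"""Defensive importer for externally supplied screening result tables.

Large screening campaigns distribute per-compound duplicate results as
supplementary spreadsheets whose exact schema varies.  This reader
accepts delimited text (and .xlsx where openpyxl is installed), sniffs
the delimiter, lower-cases and de-spaces headers, and maps common aliases
onto the pipeline's canonical column names.  It never guesses values:
columns it cannot identify are carried through untouched, and the caller
decides whether enough of the schema was recognized.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError

_ALIASES = {
    "compound_id": {"compound_id", "compound", "cmpd", "cmpd_id", "id", "sample_id"},
    "agonist": {"agonist", "stimulus", "trigger"},
    "di": {"di", "difference_index", "diff_index"},
    "p1": {"p1", "baseline"},
    "p2": {"p2", "max_increase", "maximal_increase"},
    "p3": {"p3", "slope1", "slope_1"},
    "p4": {"p4", "peak"},
    "p5": {"p5", "slope2", "slope_2"},
    "p6": {"p6", "slope3", "slope_3"},
    "p7": {"p7", "auc", "area_under_curve"},
}


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read an external screen-results table with schema sniffing.

    Returns a DataFrame with recognized columns renamed to canonical
    names; raises :class:`FormatError` when no compound identifier column
    can be found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_").replace("-", "_")
        for canonical, aliases in _ALIASES.items():
            if key in aliases and canonical not in rename.values():
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    if "compound_id" not in df.columns:
        raise FormatError(
            f"{path}: no recognizable compound identifier column among "
            f"{list(df.columns)}"
        )
    return df
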