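"""Reference count tables from the published scelionid-aposematism study.

Two small summary tables are shipped with the package: the ungrouped
behavioral-response counts from the live-prey trials (954 individual actions
across 136 spider-wasp trials, by wasp color) and the three 2x2 false-prey
contingency tables (30 automated-cage lure trials).  The raw per-trial
records were not deposited, so these printed summaries are the only exact
inputs available for the contingency and bookkeeping analyses.
"""

from __future__ import annotations

import io

import pandas as pd

from .contingency import ContingencyTable

__all__ = ["load_behavior_counts", "load_false_prey_tables"]

_BEHAVIOR_COUNTS_CSV = """\
code,behavior,black,bob
1,Alert and swivel,160,192
2,Follow or stalk,99,111
3,"Crouch, jump and contact prey",99,101
4,Pierce and ingest,8,0
5,Prey undetected or ignored,83,48
6,Detect visually and withdraw,14,37
7,None,2,0
"""

# response (same=1 / different=2) x covariate level, 30 lure trials
_FALSE_PREY = {
    "background": {"cols": ("white", "black"), "counts": ((13, 8), (3, 6))},
    "first_detected": {"cols": ("black", "BOB"), "counts": ((15, 6), (6, 3))},
    "silk": {"cols": ("no", "yes"), "counts": ((16, 5), (7, 2))},
}


def load_behavior_counts() -> pd.DataFrame:
    """Ungrouped behavioral-response counts per wasp color, plus totals."""
    df = pd.read_csv(io.StringIO(_BEHAVIOR_COUNTS_CSV))
    df["total"] = df["black"] + df["bob"]
    return df


def load_false_prey_tables() -> dict[str, ContingencyTable]:
    """The three same/different-response contingency tables from the lure trials."""
    out = {}
    for name, spec in _FALSE_PREY.items():
        out[name] = ContingencyTable(
            counts=spec["counts"],
            row_labels=("same", "different"),
            col_labels=spec["cols"],
            name=name,
        )
    return out
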