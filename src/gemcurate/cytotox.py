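"""MTT viability and cytotoxicity from plate absorbance tables.

An MTT assay reads absorbance at 595 nm as a proxy for viable cell number.
Two viability conventions are implemented and never silently corrected:

* ``ratio`` (the default): viability% = 100 * Abs(sample) / Abs(control) —
  the reading under which "cytotoxicity = 100 - viability" yields high
  cytotoxicity at high doses;
* ``printed_difference``: viability% = 100 * (Abs(control) - Abs(sample)) /
  Abs(control) — the literal difference form some protocols print.

The two are exact complements: they sum to 100 for the same inputs.
Control aggregation uses the mean of the control wells of each
(cell line, exposure time) stratum.  No blank subtraction is applied by
default (``blank`` hook available).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "CONVENTIONS",
    "viability_percent",
    "summarize_plate",
    "dilution_series",
    "load_plate",
    "PLATE_COLUMNS",
]

CONVENTIONS = ("ratio", "printed_difference")

PLATE_COLUMNS = [
    "cell_line",
    "concentration_mg_ml",
    "time_h",
    "replicate",
    "absorbance",
    "is_control",
]


def viability_percent(
    abs_sample: float, abs_control: float, convention: str = "ratio"
) -> float:
    """Single-well viability percentage under the chosen convention."""
    if abs_control <= 0:
        raise ValueError("control absorbance must be positive")
    if convention == "ratio":
        return 100.0 * abs_sample / abs_control
    if convention == "printed_difference":
        return 100.0 * (abs_control - abs_sample) / abs_control
    raise ValueError(f"unknown convention {convention!r}")


def summarize_plate(
    plate: pd.DataFrame, convention: str = "ratio", blank: float = 0.0
) -> pd.DataFrame:
    """Per-(cell line, concentration, time) viability summary.

    Each stratum's sample wells are normalized by the mean control absorbance
    of the matching (cell line, time) stratum; the result carries the mean
    and sd of replicate viabilities, the replicate count, and
    cytotoxicity = 100 - viability.  A stratum without any control well is an
    error naming the stratum.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    df = plate.copy()
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    if (df["absorbance"] < 0).any():
        raise ValueError("absorbances must be >= 0")
    df["absorbance"] = df["absorbance"] - blank
    controls = (
        df[df["is_control"]]
        .groupby(["cell_line", "time_h"])["absorbance"]
        .mean()
    )
    rows = []
    samples = df[~df["is_control"]]
    for (line, conc, time), grp in samples.groupby(
        ["cell_line", "concentration_mg_ml", "time_h"], sort=True
    ):
        try:
            ctrl = controls.loc[(line, time)]
        except KeyError:
            raise ValueError(
                f"no control wells for stratum cell_line={line!r}, "
                f"time_h={time!r}"
            ) from None
        viab = grp["absorbance"].map(
            lambda a: viability_percent(a, ctrl, convention)
        )
        rows.append(
            {
                "cell_line": line,
                "concentration_mg_ml": conc,
                "time_h": time,
                "viability_mean": viab.mean(),
                "viability_sd": viab.std(ddof=1) if len(viab) > 1 else 0.0,
                "n": len(viab),
                "cytotoxicity_mean": 100.0 - viab.mean(),
                "convention": convention,
            }
        )
    return pd.DataFrame(rows)


def dilution_series(start: float, factor: float, n: int) -> list[float]:
    """Geometric serial dilution: [start, start/factor, ...], length n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    return [start / factor**i for i in range(n)]


def load_plate(path: str | Path) -> pd.DataFrame:
    """Read ``plate.csv`` (cell_line, concentration_mg_ml, time_h, replicate,
    absorbance, is_control)."""
    df = pd.read_csv(path)
    df["is_control"] = df["is_control"].astype(bool)
    return df
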