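"""Formula/adduct mass arithmetic and ppm-tolerance LC-MS annotation.

Monoisotopic masses are computed from a fixed in-code element table (most
abundant isotope masses, CODATA-consistent to ~1e-8 Da), which reproduces
published 4-decimal neutral-mass tables for plant-extract compound libraries.
Annotation matches observed feature m/z values against every polarity-
compatible (library entry, adduct) pair within a signed ppm tolerance
(default 10 ppm, a common Q-TOF setting), ranking hits by absolute ppm error.

Singly charged adducts only; ionic m/z uses the proton-mass convention
(``[M+H]+ = M + 1.007276``).  Electron mass on the chloride anion is applied
only when ``electron_mass=True`` is requested; the default (off) matches the
neutral-mass convention of printed 4-decimal tables.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "AdductSpec",
    "Feature",
    "LibraryEntry",
    "AnnotationHit",
    "default_adducts",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate",
    "relative_area",
    "collision_energy",
    "class_summary",
    "load_feature_table",
    "load_library",
    "load_reference_library",
]

#: Monoisotopic masses of the most abundant isotopes, Da.
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207069,
    "Na": 22.98976928,
    "Cl": 34.96885268,
    "K": 38.96370649,
    "F": 18.99840316,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858
_H2O = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]  # 18.010565
_HCOOH = (
    ELEMENT_MASSES["C"] + 2 * ELEMENT_MASSES["H"] + 2 * ELEMENT_MASSES["O"]
)  # 46.005480

#: Default m/z acquisition window (full-scan Q-TOF).
ACQUISITION_RANGE = (70.0, 1100.0)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class AdductSpec:
    name: str
    polarity: str  # '+' or '-'
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if abs(self.charge) != 1:
            raise ValueError("only singly charged adducts are supported")
        if (self.charge > 0) != (self.polarity == "+"):
            raise ValueError(
                f"adduct {self.name!r}: polarity inconsistent with charge"
            )


def default_adducts(electron_mass: bool = False) -> dict[str, AdductSpec]:
    """The registry of common ESI adducts for small-molecule annotation."""
    cl_delta = ELEMENT_MASSES["Cl"] + (ELECTRON_MASS if electron_mass else 0.0)
    specs = [
        AdductSpec("[M+H]+", "+", PROTON_MASS, +1),
        AdductSpec("[M-H]-", "-", -PROTON_MASS, -1),
        # Na - H + proton and Na - electron agree to < 1e-8 Da
        AdductSpec(
            "[M+Na]+",
            "+",
            ELEMENT_MASSES["Na"] - ELEMENT_MASSES["H"] + PROTON_MASS,
            +1,
        ),
        AdductSpec("[M+HCOOH-H]-", "-", _HCOOH - PROTON_MASS, -1),
        AdductSpec("[M+Cl]-", "-", cl_delta, -1),
        AdductSpec("[M+H-H2O]+", "+", PROTON_MASS - _H2O, +1),
        AdductSpec("[M-H-H2O]-", "-", -PROTON_MASS - _H2O, -1),
    ]
    return {s.name: s for s in specs}


def normalize_adduct_name(name: str) -> str:
    """Printed tables use typographic minus signs; normalize to ASCII."""
    return name.replace("−", "-").replace("–", "-").replace("^", "")


@dataclass
class Feature:
    """One observed LC-MS molecular feature."""

    mz: float
    rt: float
    area: float
    polarity: str

    def validate(self, acquisition_range: tuple[float, float] = ACQUISITION_RANGE) -> None:
        lo, hi = acquisition_range
        if not lo <= self.mz <= hi:
            raise ValueError(
                f"feature m/z {self.mz} outside acquisition range {lo}-{hi}"
            )
        if self.area < 0:
            raise ValueError("feature area must be >= 0")


@dataclass
class LibraryEntry:
    name: str
    formula: str
    compound_class: str = ""
    subclass: str = ""


@dataclass
class AnnotationHit:
    feature_index: int
    entry: LibraryEntry
    adduct: str
    theoretical_mz: float
    ppm_error: float
    confidence_level: int = 3  # tentative candidate by default

    def __post_init__(self) -> None:
        if not 1 <= self.confidence_level <= 5:
            raise ValueError("confidence_level must be in 1..5")


# ----------------------------------------------------------------------
# Mass arithmetic
# ----------------------------------------------------------------------

def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C21H30O2`` into element counts.

    Counts are positive integers; an unknown element symbol raises naming it.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        pos = match.end()
        sym, num = match.group(1), match.group(2)
        if sym not in ELEMENT_MASSES:
            raise ValueError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass in Da (sum of count x isotope mass)."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    for sym in counts:
        if sym not in ELEMENT_MASSES:
            raise ValueError(f"unknown element {sym!r}")
    return sum(ELEMENT_MASSES[s] * n for s, n in counts.items())


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str,
              registry: dict[str, AdductSpec] | None = None) -> float:
    """Ionic m/z of a neutral mass under an adduct: (M + delta)/|z|."""
    if isinstance(adduct, str):
        registry = registry if registry is not None else default_adducts()
        name = normalize_adduct_name(adduct)
        if name not in registry:
            raise KeyError(f"adduct {adduct!r} is not registered")
        adduct = registry[name]
    return (neutral_mass + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def collision_energy(mz: float) -> float:
    """Ramped collision energy (eV) for MS/MS: CE = 3.6 * (m/z)/100 + 4.8."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    return 3.6 * mz / 100.0 + 4.8


# ----------------------------------------------------------------------
# Annotation
# ----------------------------------------------------------------------

def annotate(
    features: list[Feature],
    library: list[LibraryEntry],
    adducts: dict[str, AdductSpec] | None = None,
    tol_ppm: float = 10.0,
) -> list[list[AnnotationHit]]:
    """Match features against all polarity-compatible (entry, adduct) pairs.

    Returns one hit list per feature (empty when nothing matches), each
    ranked ascending by absolute ppm error with ties broken by library
    order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if adducts is None:
        adducts = default_adducts()
    # precompute theoretical m/z for each (entry, adduct) pair
    theo: list[tuple[int, LibraryEntry, AdductSpec, float]] = []
    for j, entry in enumerate(library):
        mass = monoisotopic_mass(entry.formula)
        for spec in adducts.values():
            theo.append((j, entry, spec, adduct_mz(mass, spec)))
    out: list[list[AnnotationHit]] = []
    for i, feat in enumerate(features):
        hits: list[tuple[float, int, AnnotationHit]] = []
        for j, entry, spec, mz_t in theo:
            if spec.polarity != feat.polarity:
                continue
            err = ppm_error(feat.mz, mz_t)
            if abs(err) <= tol_ppm:
                hits.append(
                    (
                        abs(err),
                        j,
                        AnnotationHit(
                            feature_index=i,
                            entry=entry,
                            adduct=spec.name,
                            theoretical_mz=mz_t,
                            ppm_error=err,
                        ),
                    )
                )
        hits.sort(key=lambda t: (t[0], t[1]))
        out.append([h for _, _, h in hits])
    return out


def relative_area(features: list[Feature]) -> list[float]:
    """Per-feature percentage of the summed feature area (sums to 100)."""
    total = sum(f.area for f in features)
    if total <= 0:
        raise ValueError("total feature area must be positive")
    return [100.0 * f.area / total for f in features]


def class_summary(
    hits: list[AnnotationHit],
    class_map: dict[str, str] | None = None,
) -> dict[tuple[str, str], int]:
    """Distinct annotated compounds per (class, polarity-of-adduct) bucket.

    ``class_map`` overrides the entry's own compound class; entries with no
    class anywhere are bucketed as ``unclassified`` with a warning.
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for hit in hits:
        cls = (class_map or {}).get(hit.entry.name) or hit.entry.compound_class
        if not cls:
            logger.warning("entry %r has no compound class", hit.entry.name)
            cls = "unclassified"
        mode = "+" if hit.adduct.endswith("+") else "-"
        seen.setdefault((cls, mode), set()).add(hit.entry.name)
    return {key: len(names) for key, names in sorted(seen.items())}


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def load_feature_table(path: str | Path) -> list[Feature]:
    """Read ``features.csv`` with columns mz, rt_min, area, polarity."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Feature(
                    mz=float(row["mz"]),
                    rt=float(row["rt_min"]),
                    area=float(row["area"]),
                    polarity=row["polarity"],
                )
            )
    return out


def load_library(path: str | Path) -> list[LibraryEntry]:
    """Read ``library.csv`` with columns name, formula, class, subclass."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                LibraryEntry(
                    name=row["name"],
                    formula=row["formula"],
                    compound_class=row.get("class", ""),
                    subclass=row.get("subclass", ""),
                )
            )
    return out


def load_reference_library() -> list[dict]:
    """The packaged 79-compound C. sativa leaf-extract annotation table.

    Each row carries the compound name, elemental formula, the neutral
    monoisotopic mass as printed in the source table (4 decimals), retention
    time, reported ppm error, adduct, detection polarity, identification
    confidence level, and relative area percentage.  Rows are stored exactly
    as printed, including one chemically inconsistent name/formula pair that
    is documented rather than patched.
    """
    out = []
    ref = resources.files("gemcurate.data").joinpath(
        "leaf_extract_annotations.csv"
    )
    with ref.open(newline="") as fh:
        for row in csv.DictReader(fh):
            row["printed_mass"] = float(row["printed_mass"])
            row["rt_min"] = float(row["rt_min"])
            row["mass_error_ppm"] = float(row["mass_error_ppm"])
            row["area_percent"] = float(row["area_percent"])
            out.append(row)
    return out
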