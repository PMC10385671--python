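"""Seeded generators for networks, LC-MS feature tables, and MTT plates.

Each generator is deterministic for a fixed seed and returns, alongside the
generated data, a ground-truth object sufficient to score the downstream
stage (gap recall, annotation recall, viability recovery) with no external
data.

Network generator
    Builds a connected backbone pathway (uptake exchange -> chain -> sink
    exchange), optional shortcut reactions and extra exchanges up to the
    requested counts, then plants pathologies *on top* of that backbone:
    each planted gap adds one branch metabolite whose sole producer is
    removed (and emitted as the closing candidate) plus a demand reaction,
    making that metabolite a root no-production gap; each planted dead end
    adds one reaction producing a metabolite that nothing consumes, which is
    blocked by construction.  ``n_metabolites``/``n_reactions``/
    ``n_exchanges`` refer to the backbone before planting.

Feature generator
    Applies registered adduct transforms to library formulas and perturbs
    the m/z by a Normal relative error of ``ppm_noise_sd`` ppm, emulating a
    Q-TOF full scan over 70-1100 m/z; decoy features are drawn uniformly
    over the acquisition range and rejected within 10 ppm of any library
    adduct mass so truth labels stay unambiguous.

Plate generator
    Samples wells from a sigmoidal (Hill) dose-response
    ``Abs = control_abs / (1 + (c / ec50)^hill_slope)`` with additive
    Gaussian noise, over a geometric dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import CandidateReaction
from .cytotox import dilution_series
from .metabolomics import (
    ACQUISITION_RANGE,
    AdductSpec,
    Feature,
    LibraryEntry,
    adduct_mz,
    default_adducts,
    monoisotopic_mass,
    ppm_error,
)
from .network import DEFAULT_BOUND, Metabolite, Network, Reaction

__all__ = [
    "NetworkGenSpec",
    "NetworkGroundTruth",
    "FeatureGenSpec",
    "PlateGenSpec",
    "generate_network",
    "generate_features",
    "generate_plate",
    "write_features",
    "write_plate",
]

_COMPARTMENT_CYCLE = ["c", "d", "m", "x", "v", "r", "g", "n", "w"]


@dataclass
class NetworkGenSpec:
    n_compartments: int = 3
    n_metabolites: int = 12
    n_reactions: int = 18
    n_exchanges: int = 3
    planted_gaps: int = 0
    planted_deadends: int = 0
    transport_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_compartments <= len(_COMPARTMENT_CYCLE):
            raise ValueError("n_compartments out of range")
        if self.n_metabolites < 2:
            raise ValueError("need at least 2 backbone metabolites")
        min_rxns = (self.n_metabolites - 1) + 2
        if self.n_reactions < min_rxns:
            raise ValueError(
                f"n_reactions must be >= {min_rxns} for a connected backbone"
            )
        if not 2 <= self.n_exchanges <= self.n_metabolites:
            raise ValueError("n_exchanges must be in [2, n_metabolites]")
        if self.planted_gaps > self.n_metabolites:
            raise ValueError("planted_gaps must be <= n_metabolites")
        if not 0.0 <= self.transport_fraction <= 1.0:
            raise ValueError("transport_fraction must be in [0, 1]")


@dataclass
class NetworkGroundTruth:
    gap_metabolites: list[str] = field(default_factory=list)
    deadend_reactions: list[str] = field(default_factory=list)
    closing_candidates: list[CandidateReaction] = field(default_factory=list)


def generate_network(
    spec: NetworkGenSpec,
) -> tuple[Network, NetworkGroundTruth]:
    rng = np.random.default_rng(spec.seed)
    codes = _COMPARTMENT_CYCLE[: spec.n_compartments]
    n = spec.n_metabolites

    # backbone compartment assignment: a transport step switches compartment
    comps = ["c"] * n
    n_transport = int(round(spec.transport_fraction * (n - 1)))
    transport_steps = set(
        rng.choice(n - 1, size=n_transport, replace=False).tolist()
    )
    for i in range(1, n):
        prev = comps[i - 1]
        if (i - 1) in transport_steps and len(codes) > 1:
            choices = [c for c in codes if c != prev]
            comps[i] = choices[int(rng.integers(len(choices)))]
        else:
            comps[i] = prev

    net = Network()
    met_ids = [f"cpd{10000 + i:05d}_{comps[i]}" for i in range(n)]
    for i, mid in enumerate(met_ids):
        net.add_metabolite(Metabolite(id=mid, name=f"backbone metabolite {i}"))

    # boundary exchanges at both ends, uptake at the head
    net.add_reaction(
        Reaction(
            id="EX_head",
            stoichiometry={met_ids[0]: -1},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
        )
    )
    net.add_reaction(
        Reaction(
            id="EX_tail",
            stoichiometry={met_ids[-1]: -1},
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
        )
    )
    for i in range(n - 1):
        net.add_reaction(
            Reaction(
                id=f"rxn{20000 + i:05d}",
                stoichiometry={met_ids[i]: -1, met_ids[i + 1]: 1},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )

    # extra exchanges on random interior metabolites
    n_extra_ex = spec.n_exchanges - 2
    if n_extra_ex > 0:
        interior = rng.choice(
            range(1, n - 1), size=min(n_extra_ex, n - 2), replace=False
        )
        for i in sorted(int(x) for x in interior):
            net.add_reaction(
                Reaction(
                    id=f"EX_{met_ids[i]}",
                    stoichiometry={met_ids[i]: -1},
                    lower_bound=-DEFAULT_BOUND,
                    upper_bound=DEFAULT_BOUND,
                )
            )

    # forward shortcut reactions up to the requested reaction count
    n_shortcuts = spec.n_reactions - (n - 1) - 2 - max(n_extra_ex, 0)
    used_pairs: set[tuple[int, int]] = {(i, i + 1) for i in range(n - 1)}
    k = 0
    attempt = 0
    while k < n_shortcuts and attempt < 100 * max(n_shortcuts, 1):
        attempt += 1
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))
        if (i, j) in used_pairs:
            continue
        used_pairs.add((i, j))
        net.add_reaction(
            Reaction(
                id=f"rxn{30000 + k:05d}",
                stoichiometry={met_ids[i]: -1, met_ids[j]: 1},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
        k += 1

    truth = NetworkGroundTruth()

    # planted production gaps: branch metabolite whose sole producer is
    # removed and emitted as the closing candidate
    for g in range(spec.planted_gaps):
        src = met_ids[int(rng.integers(0, n))]
        comp = src.rsplit("_", 1)[1]
        gap_id = f"cpd{90000 + g:05d}_{comp}"
        net.add_metabolite(Metabolite(id=gap_id, name=f"planted gap {g}"))
        net.add_reaction(
            Reaction(
                id=f"DM_{gap_id}",
                stoichiometry={gap_id: -1},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
        truth.gap_metabolites.append(gap_id)
        truth.closing_candidates.append(
            CandidateReaction(
                external_id=f"rxn{90000 + g:05d}",
                source_namespace="other",
                stoichiometry={src: -1, gap_id: 1},
                target_compartment=comp,
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                provenance=f"planted closing reaction for {gap_id}",
            )
        )

    # planted dead ends: produced metabolite with no consumer or sink
    for d in range(spec.planted_deadends):
        src = met_ids[int(rng.integers(0, n))]
        comp = src.rsplit("_", 1)[1]
        dead_met = f"cpd{80000 + d:05d}_{comp}"
        rid = f"rxn{80000 + d:05d}"
        net.add_metabolite(Metabolite(id=dead_met, name=f"dead-end product {d}"))
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={src: -1, dead_met: 1},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
            )
        )
        truth.deadend_reactions.append(rid)

    return net, truth


# ----------------------------------------------------------------------
# LC-MS features
# ----------------------------------------------------------------------

@dataclass
class FeatureGenSpec:
    library: list[LibraryEntry]
    adducts: dict[str, AdductSpec] | None = None
    ppm_noise_sd: float = 3.0
    decoy_fraction: float = 0.0
    n_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.library:
            raise ValueError("library must be non-empty")
        if self.ppm_noise_sd < 0:
            raise ValueError("ppm_noise_sd must be >= 0")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must be in [0, 1]")


def generate_features(
    spec: FeatureGenSpec,
) -> tuple[list[Feature], list[tuple[int, str] | None]]:
    """Features plus a truth list: (library index, adduct name) per planted
    feature, None per decoy.

    Truth labels must stay unambiguous under the ppm noise, so the planting
    pool collapses duplicate (formula, adduct) combinations to their first
    library entry and excludes any combination whose theoretical m/z lies
    within 10 ppm of a *different* polarity-matched combination (the same
    rule that rejects decoys near library masses).  Excluded combinations
    remain matchable at annotation time; they are just never planted.
    """
    rng = np.random.default_rng(spec.seed)
    adducts = spec.adducts if spec.adducts is not None else default_adducts()
    lo, hi = ACQUISITION_RANGE
    # all in-range (entry, adduct) combinations, deduplicated by
    # (formula, adduct name)
    seen: set[tuple[str, str]] = set()
    candidates: list[tuple[int, AdductSpec, float, str]] = []
    all_in_range: list[tuple[float, str, tuple[str, str]]] = []
    for j, entry in enumerate(spec.library):
        mass = monoisotopic_mass(entry.formula)
        for ad in adducts.values():
            mz = adduct_mz(mass, ad)
            if not lo <= mz <= hi:
                continue
            key = (entry.formula, ad.name)
            all_in_range.append((mz, ad.polarity, key))
            if key in seen:
                continue
            seen.add(key)
            candidates.append((j, ad, mz, entry.formula))
    pool = [
        (j, ad, mz)
        for j, ad, mz, formula in candidates
        if not any(
            pol == ad.polarity
            and key != (formula, ad.name)
            and abs(ppm_error(mz, other_mz)) <= 10.0
            for other_mz, pol, key in all_in_range
        )
    ]
    if not pool:
        raise ValueError("no unambiguous library adduct falls inside the acquisition range")
    n_features = (
        spec.n_features if spec.n_features is not None else len(spec.library)
    )
    n_decoys = int(round(spec.decoy_fraction * n_features))
    n_true = n_features - n_decoys
    features: list[Feature] = []
    truth: list[tuple[int, str] | None] = []
    for _ in range(n_true):
        j, ad, mz_t = pool[int(rng.integers(len(pool)))]
        eps = rng.normal(0.0, spec.ppm_noise_sd * 1e-6)
        features.append(
            Feature(
                mz=mz_t * (1.0 + eps),
                rt=float(rng.uniform(0.5, 18.0)),
                area=float(10 ** rng.uniform(3, 7)),
                polarity=ad.polarity,
            )
        )
        truth.append((j, ad.name))
    all_theoretical = [(mz, ad.polarity) for _, ad, mz in pool]
    for _ in range(n_decoys):
        polarity = "+" if rng.random() < 0.5 else "-"
        while True:
            mz = float(rng.uniform(lo, hi))
            near = any(
                pol == polarity and abs(ppm_error(mz, mz_t)) <= 10.0
                for mz_t, pol in all_theoretical
            )
            if not near:
                break
        features.append(
            Feature(
                mz=mz,
                rt=float(rng.uniform(0.5, 18.0)),
                area=float(10 ** rng.uniform(3, 7)),
                polarity=polarity,
            )
        )
        truth.append(None)
    return features, truth


# ----------------------------------------------------------------------
# MTT plates
# ----------------------------------------------------------------------

@dataclass
class PlateGenSpec:
    cell_lines: tuple[str, ...] = ("AGS", "A375", "A549", "Vero", "HFF")
    start_concentration: float = 0.05  # mg/mL
    dilution_factor: float = 2.0
    n_dilutions: int = 8
    times_h: tuple[int, ...] = (24, 72)
    replicates: int = 3
    n_controls: int = 3
    ec50: float = 0.02  # mg/mL
    hill_slope: float = 2.0
    control_abs: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.control_abs <= 0:
            raise ValueError("control_abs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_plate(spec: PlateGenSpec) -> pd.DataFrame:
    """Well-level plate table following the Hill dose-response."""
    rng = np.random.default_rng(spec.seed)
    concs = dilution_series(
        spec.start_concentration, spec.dilution_factor, spec.n_dilutions
    )
    rows = []
    for line in spec.cell_lines:
        for time in spec.times_h:
            for rep in range(spec.n_controls):
                ab = spec.control_abs + rng.normal(0.0, spec.noise_sd)
                rows.append(
                    {
                        "cell_line": line,
                        "concentration_mg_ml": 0.0,
                        "time_h": time,
                        "replicate": rep,
                        "absorbance": max(ab, 0.0),
                        "is_control": True,
                    }
                )
            for conc in concs:
                frac = 1.0 / (1.0 + (conc / spec.ec50) ** spec.hill_slope)
                for rep in range(spec.replicates):
                    ab = spec.control_abs * frac + rng.normal(0.0, spec.noise_sd)
                    rows.append(
                        {
                            "cell_line": line,
                            "concentration_mg_ml": conc,
                            "time_h": time,
                            "replicate": rep,
                            "absorbance": max(ab, 0.0),
                            "is_control": False,
                        }
                    )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# File emission (text formats readable by the module loaders)
# ----------------------------------------------------------------------

def write_features(
    features: list[Feature],
    truth: list[tuple[int, str] | None],
    directory,
) -> None:
    """Emit features.csv plus a truth.csv mapping rows to planted labels."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["mz,rt_min,area,polarity"]
    for f in features:
        lines.append(f"{f.mz!r},{f.rt!r},{f.area!r},{f.polarity}")
    (directory / "features.csv").write_text("\n".join(lines) + "\n")
    tlines = ["feature_index,library_index,adduct"]
    for i, t in enumerate(truth):
        if t is None:
            tlines.append(f"{i},,")
        else:
            tlines.append(f"{i},{t[0]},{t[1]}")
    (directory / "truth.csv").write_text("\n".join(tlines) + "\n")


def write_plate(plate: pd.DataFrame, path) -> None:
    """Emit plate.csv in the layout :func:`gemcurate.cytotox.load_plate` reads."""
    cols = [
        "cell_line",
        "concentration_mg_ml",
        "time_h",
        "replicate",
        "absorbance",
        "is_control",
    ]
    plate[cols].to_csv(path, index=False, float_format="%.10g")
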