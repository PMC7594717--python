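"""Tracer inputs, natural-abundance correction, and measurement handling.

Measured mass isotopomer distributions (MIDs) mix two signals: the tracer
labeling of the carbon backbone (the quantity of interest) and natural
isotope abundance — heavier isotopes of H/N/O/P/S in the detected ion plus
natural 13C in backbone positions that did not come from tracer. Both are
removed by a linear correction: the raw MID is M @ true where M is a
lower-triangular-by-mass matrix assembled from element isotope abundances.
The backbone-carbon part of M is column dependent (a molecule already at
mass shift j has only n - j carbons left to pick up natural 13C), which is
what makes the correction an exact inverse of natural-abundance forward
simulation for pure 13C tracers.

Measurements are organized in groups (one per metabolite here); each group
carries a multiplicative scale factor fitted analytically inside the
objective (variable projection).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from chemoflux.emu import EMU, EMUSystem, emu

# IUPAC 2021 isotopic abundances, as mass-shift distributions per element.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

C13_NATURAL = NATURAL_ABUNDANCE["C"][1]

_FORMULA = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    consumed = 0
    for m in _FORMULA.finditer(formula):
        if not m.group(1):
            continue
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        consumed += len(m.group(0))
    if consumed != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


# ---------------------------------------------------------------------------
# tracer mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TracerMixture:
    """Mixture of glucose labeling species over the 6 glucose carbons."""

    species: tuple[tuple[tuple[int, ...], float], ...]

    def __post_init__(self):
        total = sum(f for _, f in self.species)
        if any(f < 0 for _, f in self.species):
            raise ValueError("negative mixture fraction")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, not 1")
        for pattern, _ in self.species:
            if len(pattern) != 6 or any(b not in (0, 1) for b in pattern):
                raise ValueError(f"pattern {pattern} is not a binary 6-vector")

    @staticmethod
    def from_dict(d: dict[str, float]) -> "TracerMixture":
        """Build from names like 'U-13C', '1-13C', '1,2-13C', 'U-12C'."""
        species = []
        for name, frac in d.items():
            species.append((pattern_from_name(name), float(frac)))
        return TracerMixture(tuple(species))


def pattern_from_name(name: str) -> tuple[int, ...]:
    name = name.upper().replace("GLUCOSE", "").strip(" -_")
    if name.startswith("U-13C") or name == "U13C":
        return (1,) * 6
    if name.startswith("U-12C") or name == "U12C":
        return (0,) * 6
    m = re.match(r"^([\d,]+)-?13C$", name)
    if not m:
        raise ValueError(f"unknown tracer species {name!r}")
    pattern = [0] * 6
    for p in m.group(1).split(","):
        pattern[int(p) - 1] = 1
    return tuple(pattern)


#: the labeling experiment's mixture: 67% U-13C + 33% 1-13C glucose
PAPER_MIXTURE = TracerMixture.from_dict({"U-13C": 0.67, "1-13C": 0.33})


def _position_dist(labeled: int, natural_abundance: bool) -> np.ndarray:
    if labeled:
        return np.array([0.0, 1.0])
    if natural_abundance:
        return np.array([1.0 - C13_NATURAL, C13_NATURAL])
    return np.array([1.0, 0.0])


def mixture_emu_mid(
    mixture: TracerMixture, atoms: tuple[int, ...], natural_abundance: bool = False
) -> np.ndarray:
    """MID of a glucose EMU (atom subset) under a tracer mixture."""
    out = np.zeros(len(atoms) + 1)
    for pattern, frac in mixture.species:
        mid = np.array([1.0])
        for a in atoms:
            mid = np.convolve(mid, _position_dist(pattern[a - 1], natural_abundance))
        out += frac * mid
    return out


def natural_mid(n: int, natural_abundance: bool = True) -> np.ndarray:
    """MID of an n-carbon unlabeled pool (binomial at natural 13C)."""
    mid = np.array([1.0])
    for _ in range(n):
        mid = np.convolve(mid, _position_dist(0, natural_abundance))
    return mid


def tracer_input_mids(
    system: EMUSystem | list[EMU],
    mixture: TracerMixture = PAPER_MIXTURE,
    natural_abundance: bool = False,
    glucose_pool: str = "GLC_ext",
) -> dict[EMU, np.ndarray]:
    """Input-EMU MIDs for a simulation.

    Glucose EMUs are marginalized from the mixture; every other input pool
    (protocatechuate, CO2) is unlabeled — at natural 13C abundance when
    ``natural_abundance`` is set, else pure 12C. With natural abundance
    off, the full 6-carbon glucose EMU of the bundled mixture is
    [0, 0.33, 0, 0, 0, 0, 0.67].
    """
    emus = system.input_emus if isinstance(system, EMUSystem) else list(system)
    out: dict[EMU, np.ndarray] = {}
    for e in emus:
        if e.met == glucose_pool:
            out[e] = mixture_emu_mid(mixture, e.atoms, natural_abundance)
        else:
            out[e] = natural_mid(e.size, natural_abundance)
    return out


def input_isotopomers(
    model,
    mixture: TracerMixture = PAPER_MIXTURE,
    natural_abundance: bool = False,
    glucose_pool: str = "GLC_ext",
) -> dict[str, np.ndarray]:
    """Positional isotopomer tensors of all input pools (oracle format)."""
    out = {}
    for m in model.metabolites.values():
        if m.role != "input":
            continue
        if m.id == glucose_pool:
            t = np.zeros((2,) * m.n_carbons)
            for pattern, frac in mixture.species:
                pat = list(pattern[: m.n_carbons])
                tt = np.array([1.0])
                sub = np.zeros((2,) * m.n_carbons)
                # independent per-position distributions
                dists = [
                    _position_dist(p, natural_abundance) for p in pat
                ]
                grid = dists[0]
                for d in dists[1:]:
                    grid = np.multiply.outer(grid, d)
                sub = grid
                t += frac * sub
                del tt
            out[m.id] = t
        else:
            dists = [_position_dist(0, natural_abundance)] * m.n_carbons
            grid = dists[0]
            for d in dists[1:]:
                grid = np.multiply.outer(grid, d)
            out[m.id] = grid if m.n_carbons else np.array(1.0)
    return out


# ---------------------------------------------------------------------------
# natural abundance correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A detected ion: metabolite, carbon backbone size, elemental formula."""

    metabolite: str
    backbone: int
    formula: dict[str, int] = field(default_factory=dict)
    pool: str | None = None

    def __post_init__(self):
        if self.formula.get("C", self.backbone) < self.backbone:
            raise ValueError(
                f"{self.metabolite}: formula carbon count below backbone size"
            )
        if any(v < 0 for v in self.formula.values()):
            raise ValueError(f"{self.metabolite}: negative element count")

    @staticmethod
    def make(metabolite: str, backbone: int, formula: str, pool: str | None = None):
        return Fragment(metabolite, backbone, parse_formula(formula), pool or metabolite)


def _element_dist(n_atoms: int, shifts: tuple[float, ...], length: int) -> np.ndarray:
    dist = np.zeros(length)
    dist[0] = 1.0
    base = np.asarray(shifts, float)
    for _ in range(n_atoms):
        dist = np.convolve(dist, base)[:length]
    return dist


def correction_matrix(
    fragment: Fragment,
    abundances: dict[str, tuple[float, ...]] | None = None,
    correct_backbone: bool = True,
) -> np.ndarray:
    """Natural-abundance correction matrix M with raw = M @ true.

    Column j (true mass shift j) is the mass-shift distribution added by
    (i) all non-backbone atoms of the ion formula and (ii), when
    ``correct_backbone`` is set, natural 13C in the ``n - j`` backbone
    carbons not labeled by tracer. Rows are truncated at mass shift n, so
    columns sum to <= 1. With all abundances zeroed M is the identity.
    """
    ab = dict(NATURAL_ABUNDANCE)
    if abundances:
        ab.update(abundances)
    n = fragment.backbone
    length = n + 1
    fixed = np.zeros(length)
    fixed[0] = 1.0
    for el, count in fragment.formula.items():
        n_eff = count - n if el == "C" else count
        if el == "C" and n_eff == 0:
            continue
        fixed = np.convolve(fixed, _element_dist(n_eff, ab.get(el, (1.0,)), length))[
            :length
        ]
    M = np.zeros((length, length))
    for j in range(length):
        col = fixed.copy()
        if correct_backbone:
            col = np.convolve(col, _element_dist(n - j, ab["C"], length))[:length]
        M[j:, j] = col[: length - j]
    return M


def correct_mid(
    raw: np.ndarray,
    fragment: Fragment,
    abundances: dict[str, tuple[float, ...]] | None = None,
    correct_backbone: bool = True,
    negative_tol: float = 1e-3,
) -> np.ndarray:
    """Correct a raw MID for natural isotope abundance.

    Solves M @ corrected = raw, clips small negative entries (more negative
    than ``negative_tol`` raises) and renormalizes to sum 1.
    """
    raw = np.asarray(raw, float)
    M = correction_matrix(fragment, abundances, correct_backbone)
    if np.linalg.cond(M) > 1e8:
        raise np.linalg.LinAlgError(
            f"correction matrix for {fragment.metabolite} is ill-conditioned"
        )
    x = np.linalg.solve(M, raw)
    if np.min(x) < -negative_tol:
        raise ValueError(
            f"{fragment.metabolite}: corrected MID has entry {x.min():.4g} < -{negative_tol}"
        )
    x = np.clip(x, 0.0, None)
    return x / x.sum()


def apply_natural_abundance(
    true_mid: np.ndarray, fragment: Fragment, **kwargs
) -> np.ndarray:
    """Forward map: add natural-abundance contributions to a tracer-only MID."""
    M = correction_matrix(fragment, **kwargs)
    return M @ np.asarray(true_mid, float)


# ---------------------------------------------------------------------------
# measurements and groups
# ---------------------------------------------------------------------------

DEFAULT_MID_SD = 0.025  # mol fraction, flat 2.5 mol%


@dataclass
class MIDMeasurement:
    fragment: Fragment
    mid: np.ndarray
    sd: np.ndarray
    group: str

    def __post_init__(self):
        self.mid = np.asarray(self.mid, float)
        self.sd = np.broadcast_to(
            np.asarray(self.sd, float), self.mid.shape
        ).copy()
        if np.any(self.sd <= 0):
            raise ValueError(f"{self.fragment.metabolite}: non-positive SD")


@dataclass
class MeasurementGroup:
    group: str
    measurements: list[MIDMeasurement]
    scale: float = 1.0


def fit_group_scale(simulated: np.ndarray, measured: np.ndarray, sd: np.ndarray) -> float:
    """Scale factor minimizing sum(((w*s - m)/sd)^2), in closed form."""
    s = np.asarray(simulated, float).ravel()
    m = np.asarray(measured, float).ravel()
    v = np.asarray(sd, float).ravel() ** 2
    denom = np.sum(s * s / v)
    if denom == 0:
        raise ValueError("all simulated values zero; scale undefined")
    return float(np.sum(s * m / v) / denom)


def load_panel(name: str = "panel") -> list[Fragment]:
    """The bundled 28-metabolite measurement panel (full backbones)."""
    from importlib import resources

    doc = yaml.safe_load(
        resources.files("chemoflux.data").joinpath(f"{name}.yaml").read_text()
    )
    frags = []
    for row in doc["panel"]:
        formula = parse_formula(row["formula"])
        frags.append(
            Fragment(
                metabolite=row["metabolite"],
                backbone=formula["C"],
                formula=formula,
                pool=row.get("pool", row["metabolite"]),
            )
        )
    return frags


def panel_target_emus(model, fragments: list[Fragment]) -> list[EMU]:
    return [
        emu(f.pool, range(1, model.metabolites[f.pool].n_carbons + 1))
        for f in fragments
    ]


def measurements_to_frame(measurements: list[MIDMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        formula = "".join(
            f"{el}{c}" for el, c in sorted(m.fragment.formula.items())
        )
        for k in range(len(m.mid)):
            rows.append(
                {
                    "metabolite": m.fragment.metabolite,
                    "formula": formula,
                    "backbone_size": m.fragment.backbone,
                    "group": m.group,
                    "mass_shift": k,
                    "value": m.mid[k],
                    "sd": m.sd[k],
                }
            )
    return pd.DataFrame(rows)


def measurements_from_frame(df: pd.DataFrame) -> list[MIDMeasurement]:
    out = []
    for (met, formula, backbone, group), sub in df.groupby(
        ["metabolite", "formula", "backbone_size", "group"], sort=False
    ):
        sub = sub.sort_values("mass_shift")
        frag = Fragment.make(met, int(backbone), str(formula))
        out.append(
            MIDMeasurement(
                fragment=frag,
                mid=sub["value"].to_numpy(),
                sd=sub["sd"].to_numpy(),
                group=str(group),
            )
        )
    return out
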