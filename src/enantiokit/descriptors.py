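"""Per-conformer descriptor catalogue and ensemble-level aggregation.

Each stationary-point structure (radical-capture TS, Ni(III) intermediate,
reductive-elimination TS, or a cheap surrogate) is described by a catalogue of

* geometric parameters — bond lengths, angles, dihedrals over
  template-conserved atoms;
* steric parameters — percent buried volume (%V_bur) on grids, Sterimol
  L/B1/B5, solvent-accessible surface area (Shrake–Rupley);
* electronic parameters computed upstream and passed through — frontier
  orbital energies, global hardness η = ε_LUMO − ε_HOMO, atomic charges,
  spin densities, dispersion potentials.

Every descriptor is evaluated per conformer inside a free-energy window
(default 5 kcal/mol) and aggregated into four statistics — minimum, maximum,
Boltzmann-weighted average, and the value of the lowest-energy conformer.
The default catalogue holds 114 steric/geometric + 75 electronic = 189
descriptors, hence 756 aggregated values per structure, and the compact
three-stage reaction representation (steric: min/max/boltz; electronic:
boltz only) has 3 × (114×3 + 75) = 1,251 columns.

Atom indices are 1-based in catalogue files and 0-based in code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .conformers import AGGREGATION_WINDOW, boltzmann_weights, filter_energy_window
from .structio import AGGREGATIONS, ConformerEnsemble, FeatureMatrix, Structure

# Bondi van-der-Waals radii, Å (common elements; 1.70 fallback).
BONDI_RADII = {
    "H": 1.20, "He": 1.40, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "Ni": 1.63, "Cu": 1.40, "Zn": 1.39, "Ga": 1.87, "As": 1.85, "Se": 1.90,
    "Br": 1.85, "Kr": 2.02, "Pd": 1.63, "Ag": 1.72, "Cd": 1.58, "In": 1.93,
    "Sn": 2.17, "Sb": 2.06, "Te": 2.06, "I": 1.98, "Xe": 2.16, "Pt": 1.75,
    "Au": 1.66, "Hg": 1.55, "Li": 1.82, "Na": 2.27, "K": 2.75, "Mg": 1.73,
}
DEFAULT_VDW = 1.70

#: Radii scale factor for %V_bur (buried-volume literature convention).
VBUR_SCALE = 1.17

STERIC_KINDS = frozenset(
    {"distance", "angle", "dihedral", "vbur", "sterimol_L", "sterimol_B1", "sterimol_B5", "sasa"}
)
ELECTRONIC_KINDS = frozenset(
    {"scalar_passthrough", "atom_charge", "atom_spin", "hardness", "dispersion_potential"}
)

_ATOM_PROPERTY_COLUMN = {
    "atom_charge": "q",
    "atom_spin": "spin",
    "dispersion_potential": "disp",
}


def vdw_radius(element: str) -> float:
    return BONDI_RADII.get(element, DEFAULT_VDW)


# ---------------------------------------------------------------------------
# Specs and geometry primitives
# ---------------------------------------------------------------------------


@dataclass
class VburSpec:
    """Percent-buried-volume sphere about a center atom (0-based index)."""

    center: int
    radius: float = 3.5  # sphere radius, Å
    scale: float = VBUR_SCALE  # van-der-Waals radii scale
    excluded: tuple[int, ...] = ()
    grid_spacing: float = 0.05  # Å

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.scale <= 0 or self.grid_spacing <= 0:
            raise ValueError("radius, scale and grid spacing must be > 0")


@dataclass
class SterimolSpec:
    """Sterimol axis: base atom (origin) → attached atom (direction); 0-based."""

    base: int
    attached: int
    cutoff: float | None = None  # drop atoms farther than this from base, Å
    excluded: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.base == self.attached:
            raise ValueError("Sterimol base and attached atoms must differ")


def distance(structure: Structure, i: int, j: int) -> float:
    c = structure.coords
    return float(np.linalg.norm(c[i] - c[j]))


def angle(structure: Structure, i: int, j: int, k: int) -> float:
    """Angle at atom j in degrees, in [0, 180]."""
    c = structure.coords
    u, v = c[i] - c[j], c[k] - c[j]
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(structure: Structure, i: int, j: int, k: int, l: int) -> float:
    """Torsion i-j-k-l in degrees, in (-180, 180], IUPAC sign convention."""
    c = structure.coords
    b1, b2, b3 = c[j] - c[i], c[k] - c[j], c[l] - c[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError(f"colinear atoms in dihedral ({i},{j},{k},{l})")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def geometry_params(structure: Structure, defs: Sequence["DescriptorDef"]) -> dict[str, float]:
    """Evaluate named distance/angle/dihedral definitions on one structure."""
    out: dict[str, float] = {}
    for d in defs:
        try:
            if d.kind == "distance":
                out[d.name] = distance(structure, *d.atoms)
            elif d.kind == "angle":
                out[d.name] = angle(structure, *d.atoms)
            elif d.kind == "dihedral":
                out[d.name] = dihedral(structure, *d.atoms)
            else:
                raise ValueError(f"{d.name}: not a geometry descriptor ({d.kind})")
        except IndexError:
            raise IndexError(f"descriptor {d.name}: atom index out of range") from None
        except ValueError as exc:
            raise ValueError(f"descriptor {d.name}: {exc}") from None
    return out


def buried_volume(structure: Structure, spec: VburSpec) -> float:
    """Percent of a sphere occupied by scaled van-der-Waals spheres.

    Grid integration: uniform Cartesian grid of ``spec.grid_spacing``
    restricted to the sphere centered on the center atom; a point is buried
    when inside any non-excluded atom's scaled vdW sphere (the center atom
    itself never contributes occupancy).
    """
    if spec.center >= structure.n_atoms:
        raise IndexError(f"center atom {spec.center} out of range")
    center = structure.coords[spec.center]
    h, radius = spec.grid_spacing, spec.radius
    ax = np.arange(-radius, radius + h / 2, h)
    d2 = ax**2
    in_sphere = (d2[:, None, None] + d2[None, :, None] + d2[None, None, :]) <= radius**2
    occupied = np.zeros_like(in_sphere)
    skip = set(spec.excluded) | {spec.center}
    for idx, el in enumerate(structure.elements):
        if idx in skip:
            continue
        r = spec.scale * vdw_radius(el)
        pos = structure.coords[idx] - center
        if np.linalg.norm(pos) > radius + r:
            continue  # cannot intersect the sphere
        # only the grid slab overlapping this atom's vdW sphere
        slabs = [np.searchsorted(ax, [pos[k] - r, pos[k] + r], side="left") for k in range(3)]
        (i0, i1), (j0, j1), (k0, k1) = [(lo, min(hi + 1, len(ax))) for lo, hi in slabs]
        dx2 = (ax[i0:i1] - pos[0]) ** 2
        dy2 = (ax[j0:j1] - pos[1]) ** 2
        dz2 = (ax[k0:k1] - pos[2]) ** 2
        mask = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) <= r**2
        occupied[i0:i1, j0:j1, k0:k1] |= mask
    total = int(in_sphere.sum())
    if total == 0:
        return 0.0
    return 100.0 * float((occupied & in_sphere).sum()) / float(total)


def _perpendicular_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(axis, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _b_widths(vperp: np.ndarray, radii: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Width of the substituent silhouette along each in-plane direction."""
    dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)  # (T, 2)
    proj = vperp @ dirs.T  # (n_atoms, T)
    return (proj + radii[:, None]).max(axis=0)


def sterimol(structure: Structure, spec: SterimolSpec) -> tuple[float, float, float]:
    """Sterimol (L, B1, B5) in Å with unscaled Bondi radii.

    The axis runs from the base atom toward the attached atom.  L is the
    maximal extent along the axis measured from the base atom (no historical
    +0.40 Å correction); B5 the maximal width perpendicular to it; B1 the
    minimal width, found by a 1°-step rotational scan of the perpendicular
    plane followed by a fine local scan.
    """
    coords = structure.coords
    if spec.base >= structure.n_atoms or spec.attached >= structure.n_atoms:
        raise IndexError("Sterimol axis atom out of range")
    base = coords[spec.base]
    axis = coords[spec.attached] - base
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ValueError("Sterimol axis atoms coincide")
    axis = axis / norm
    skip = set(spec.excluded) | {spec.base}
    idx = [i for i in range(structure.n_atoms) if i not in skip]
    if spec.cutoff is not None:
        idx = [i for i in idx if np.linalg.norm(coords[i] - base) <= spec.cutoff]
    if not idx:
        raise ValueError("no substituent atoms remain after exclusion/cutoff")
    pos = coords[idx] - base
    radii = np.array([vdw_radius(structure.elements[i]) for i in idx])
    proj = pos @ axis
    L = float((proj + radii).max())
    e1, e2 = _perpendicular_basis(axis)
    vperp = np.stack([pos @ e1, pos @ e2], axis=1)
    B5 = float((np.linalg.norm(vperp, axis=1) + radii).max())
    coarse = np.radians(np.arange(0.0, 360.0, 1.0))
    widths = _b_widths(vperp, radii, coarse)
    best = coarse[int(np.argmin(widths))]
    fine = best + np.radians(np.arange(-1.5, 1.5, 0.005))
    B1 = float(_b_widths(vperp, radii, fine).min())
    return L, B1, B5


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    excluded: Sequence[int] = (),
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area (total, per-atom) in Å².

    Each atom's sphere of radius r_vdW + probe is sampled with a Fibonacci
    lattice; a point is accessible when outside every other atom's probe-
    augmented sphere.  Excluded atoms neither contribute area nor occlude.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    keep = [i for i in range(structure.n_atoms) if i not in set(excluded)]
    coords = structure.coords[keep]
    radii = np.array([vdw_radius(structure.elements[i]) + probe_radius for i in keep])
    unit = fibonacci_sphere(n_points)
    per_atom = np.zeros(structure.n_atoms)
    for a, (pos, r) in enumerate(zip(coords, radii)):
        pts = pos + r * unit
        accessible = np.ones(n_points, dtype=bool)
        for b, (pos_b, r_b) in enumerate(zip(coords, radii)):
            if b == a or np.linalg.norm(pos - pos_b) > r + r_b:
                continue
            d2 = np.einsum("ij,ij->i", pts - pos_b, pts - pos_b)
            accessible &= d2 > r_b**2
        per_atom[keep[a]] = accessible.mean() * 4.0 * math.pi * r**2
    return float(per_atom.sum()), per_atom


def hardness(eps_homo: float, eps_lumo: float) -> float:
    """Global hardness η = ε_LUMO − ε_HOMO (units follow the inputs)."""
    return eps_lumo - eps_homo


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------


@dataclass
class DescriptorDef:
    """One named descriptor definition (atom indices 0-based here)."""

    name: str
    kind: str
    atoms: tuple[int, ...] = ()
    radius: float = 3.5
    scale: float = VBUR_SCALE
    excluded: tuple[int, ...] = ()
    grid_spacing: float = 0.05
    cutoff: float | None = None
    probe_radius: float = 1.4
    source: str = ""  # electronic property column

    def __post_init__(self) -> None:
        if self.kind not in STERIC_KINDS | ELECTRONIC_KINDS:
            raise ValueError(f"{self.name}: unknown descriptor kind {self.kind!r}")

    @property
    def descriptor_class(self) -> str:
        return "steric" if self.kind in STERIC_KINDS else "electronic"


@dataclass
class DescriptorCatalogue:
    steric_geometric_defs: list[DescriptorDef]
    electronic_defs: list[DescriptorDef]
    is_default: bool = False

    def __post_init__(self) -> None:
        names = [d.name for d in self.steric_geometric_defs + self.electronic_defs]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate descriptor names: {dup}")
        if any(d.descriptor_class != "steric" for d in self.steric_geometric_defs):
            raise ValueError("electronic kind listed among steric/geometric definitions")
        if any(d.descriptor_class != "electronic" for d in self.electronic_defs):
            raise ValueError("steric kind listed among electronic definitions")
        if self.is_default and (
            len(self.steric_geometric_defs) != 114 or len(self.electronic_defs) != 75
        ):
            raise ValueError(
                "default catalogue must hold exactly 114 steric/geometric and "
                f"75 electronic descriptors, got {len(self.steric_geometric_defs)}"
                f"/{len(self.electronic_defs)}"
            )

    @property
    def all_defs(self) -> list[DescriptorDef]:
        return self.steric_geometric_defs + self.electronic_defs

    def __len__(self) -> int:
        return len(self.steric_geometric_defs) + len(self.electronic_defs)


def make_default_catalogue(n_atoms: int = 24, grid_spacing: float = 0.05) -> DescriptorCatalogue:
    """Template catalogue with the canonical 114 + 75 = 189 descriptors.

    Atom indices refer to template-conserved positions of the modelled
    scaffold; they are generated deterministically over the first ``n_atoms``
    atoms (n_atoms >= 24 required so that the electronic per-atom sets close).
    """
    if n_atoms < 24:
        raise ValueError("default catalogue requires a template with >= 24 atoms")
    steric: list[DescriptorDef] = []
    # 30 distances: 23 consecutive bonds + 7 skip-one contacts
    for i in range(23):
        steric.append(DescriptorDef(f"d_{i + 1}_{i + 2}", "distance", (i, i + 1)))
    for i in range(7):
        steric.append(DescriptorDef(f"d_{i + 1}_{i + 3}", "distance", (i, i + 2)))
    # 25 angles
    for i in range(22):
        steric.append(DescriptorDef(f"a_{i + 1}_{i + 2}_{i + 3}", "angle", (i, i + 1, i + 2)))
    for i in range(3):
        steric.append(
            DescriptorDef(f"a_{i + 1}_{i + 3}_{i + 5}", "angle", (i, i + 2, i + 4))
        )
    # 20 dihedrals
    for i in range(20):
        steric.append(
            DescriptorDef(
                f"t_{i + 1}_{i + 2}_{i + 3}_{i + 4}", "dihedral", (i, i + 1, i + 2, i + 3)
            )
        )
    # 12 buried volumes: 4 centers x 3 sphere radii
    for center in range(4):
        for radius in (2.0, 4.0, 4.5):
            steric.append(
                DescriptorDef(
                    f"vbur_{center + 1}_r{radius:g}",
                    "vbur",
                    (center,),
                    radius=radius,
                    grid_spacing=grid_spacing,
                )
            )
    # 15 Sterimol values: 5 axes x (L, B1, B5)
    for base in range(5):
        for comp in ("L", "B1", "B5"):
            steric.append(
                DescriptorDef(
                    f"sterimol_{comp}_{base + 1}_{base + 2}",
                    f"sterimol_{comp}",
                    (base, base + 1),
                    cutoff=4.5,
                )
            )
    # 12 SASA values: total + 11 atoms
    steric.append(DescriptorDef("sasa_total", "sasa", ()))
    for i in range(11):
        steric.append(DescriptorDef(f"sasa_{i + 1}", "sasa", (i,)))
    electronic: list[DescriptorDef] = [
        DescriptorDef("eps_homo", "scalar_passthrough", source="eps_homo"),
        DescriptorDef("eps_lumo", "scalar_passthrough", source="eps_lumo"),
        DescriptorDef("hardness", "hardness", source="eps_homo,eps_lumo"),
    ]
    for i in range(24):
        electronic.append(DescriptorDef(f"q_{i + 1}", "atom_charge", (i,), source="q"))
    for i in range(24):
        electronic.append(DescriptorDef(f"spin_{i + 1}", "atom_spin", (i,), source="spin"))
    for i in range(24):
        electronic.append(
            DescriptorDef(f"disp_{i + 1}", "dispersion_potential", (i,), source="disp")
        )
    return DescriptorCatalogue(steric, electronic, is_default=True)


def load_catalogue(path: str | Path) -> DescriptorCatalogue:
    """Load a catalogue from YAML/JSON (atom indices 1-based on disk)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    steric, electronic = [], []
    for entry in raw.get("descriptors", []):
        entry = dict(entry)
        atoms = tuple(int(a) - 1 for a in entry.pop("atoms", []))
        excluded = tuple(int(a) - 1 for a in entry.pop("excluded", []))
        d = DescriptorDef(atoms=atoms, excluded=excluded, **entry)
        (steric if d.descriptor_class == "steric" else electronic).append(d)
    return DescriptorCatalogue(steric, electronic, is_default=bool(raw.get("default", False)))


# ---------------------------------------------------------------------------
# Per-conformer evaluation and aggregation
# ---------------------------------------------------------------------------


def _electronic_value(d: DescriptorDef, record: dict[str, object]) -> float:
    if d.kind == "scalar_passthrough":
        if d.source not in record:
            raise KeyError(f"descriptor {d.name}: property column {d.source!r} missing")
        return float(record[d.source])  # type: ignore[arg-type]
    if d.kind == "hardness":
        homo_col, lumo_col = (d.source or "eps_homo,eps_lumo").split(",")
        for col in (homo_col, lumo_col):
            if col not in record:
                raise KeyError(f"descriptor {d.name}: property column {col!r} missing")
        return hardness(float(record[homo_col]), float(record[lumo_col]))  # type: ignore[arg-type]
    col = d.source or _ATOM_PROPERTY_COLUMN[d.kind]
    if col not in record:
        raise KeyError(f"descriptor {d.name}: property column {col!r} missing")
    arr = np.asarray(record[col], dtype=float)
    atom = d.atoms[0]
    if atom >= arr.size:
        raise IndexError(f"descriptor {d.name}: atom index {atom + 1} beyond property array")
    return float(arr[atom])


def evaluate_descriptors(
    structure: Structure,
    catalogue: DescriptorCatalogue,
    property_record: dict[str, object] | None = None,
) -> dict[str, float]:
    """All catalogue descriptors for one conformer."""
    values: dict[str, float] = {}
    sasa_cache: dict[tuple, tuple[float, np.ndarray]] = {}
    for d in catalogue.steric_geometric_defs:
        if d.kind in ("distance", "angle", "dihedral"):
            values.update(geometry_params(structure, [d]))
        elif d.kind == "vbur":
            spec = VburSpec(
                center=d.atoms[0],
                radius=d.radius,
                scale=d.scale,
                excluded=d.excluded,
                grid_spacing=d.grid_spacing,
            )
            values[d.name] = buried_volume(structure, spec)
        elif d.kind.startswith("sterimol"):
            spec = SterimolSpec(
                base=d.atoms[0], attached=d.atoms[1], cutoff=d.cutoff, excluded=d.excluded
            )
            L, B1, B5 = sterimol(structure, spec)
            values[d.name] = {"sterimol_L": L, "sterimol_B1": B1, "sterimol_B5": B5}[d.kind]
        elif d.kind == "sasa":
            key = (d.excluded, d.probe_radius)
            if key not in sasa_cache:
                sasa_cache[key] = sasa(structure, d.probe_radius, d.excluded)
            total, per_atom = sasa_cache[key]
            values[d.name] = total if not d.atoms else float(per_atom[d.atoms[0]])
    if catalogue.electronic_defs:
        if property_record is None:
            raise ValueError("electronic descriptors requested but no property record given")
        for d in catalogue.electronic_defs:
            values[d.name] = _electronic_value(d, property_record)
    return values


@dataclass
class StructureFeatures:
    """Aggregated descriptor statistics for one structure.

    ``values[name]`` maps aggregation ('min'/'max'/'boltz'/'lowE') → float;
    ``classes[name]`` is 'steric' or 'electronic'.
    """

    values: dict[str, dict[str, float]]
    classes: dict[str, str]
    stage_label: str
    n_conformers_used: int

    def as_series(self) -> pd.Series:
        data = {
            f"{name}__{self.stage_label}__{agg}": self.values[name][agg]
            for name in self.values
            for agg in AGGREGATIONS
        }
        return pd.Series(data)


def featurize_structure(
    ensemble: ConformerEnsemble,
    catalogue: DescriptorCatalogue,
    temperature: float = 298.15,
    window: float = AGGREGATION_WINDOW,
) -> StructureFeatures:
    """Window-filter, evaluate the catalogue per conformer, and aggregate.

    With the default 189-descriptor catalogue this yields 756 values
    (189 × {min, max, boltz, lowE}).
    """
    surv = filter_energy_window(ensemble, window)
    bw = boltzmann_weights(surv.free_energies, temperature)
    low_idx = int(np.argmin(surv.free_energies))
    per_conf: list[dict[str, float]] = []
    for conf in surv.conformers:
        record = surv.properties.get(conf.id) if surv.properties else None
        per_conf.append(evaluate_descriptors(conf, catalogue, record))
    names = list(per_conf[0])
    values: dict[str, dict[str, float]] = {}
    for name in names:
        v = np.array([pc[name] for pc in per_conf])
        values[name] = {
            "min": float(v.min()),
            "max": float(v.max()),
            "boltz": float(np.dot(bw.weights, v)),
            "lowE": float(v[low_idx]),
        }
    classes = {d.name: d.descriptor_class for d in catalogue.all_defs}
    return StructureFeatures(
        values=values,
        classes=classes,
        stage_label=surv.stage_label,
        n_conformers_used=len(surv),
    )


#: Aggregations entering the reaction representation per scheme and class.
REPRESENTATION_SCHEMES = {
    "full": {"steric": ("min", "max", "boltz", "lowE"), "electronic": ("min", "max", "boltz", "lowE")},
    "compact": {"steric": ("min", "max", "boltz"), "electronic": ("boltz",)},
}


def build_reaction_representation(
    stage_features: dict[str, StructureFeatures],
    scheme: str = "compact",
    stages: Sequence[str] | None = None,
) -> pd.Series:
    """Concatenate per-stage aggregated features into one reaction vector.

    The compact scheme keeps min/max/Boltzmann averages for steric
    descriptors and the Boltzmann average only for electronic ones; over the
    three mechanism stages with the default catalogue this gives
    3 × (114×3 + 75) = 1,251 provenance-tagged columns.  Column order is
    stage, then catalogue order, then aggregation.
    """
    if scheme not in REPRESENTATION_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {list(REPRESENTATION_SCHEMES)}")
    if stages is None:
        stages = list(stage_features)
    missing = [s for s in stages if s not in stage_features]
    if missing:
        raise ValueError(f"missing stages: {missing}")
    aggs_for = REPRESENTATION_SCHEMES[scheme]
    data: dict[str, float] = {}
    for stage in stages:
        feats = stage_features[stage]
        for name, stats in feats.values.items():
            for agg in aggs_for[feats.classes[name]]:
                data[f"{name}__{stage}__{agg}"] = stats[agg]
    return pd.Series(data)


def representation_matrix(rows: dict[str, pd.Series]) -> FeatureMatrix:
    """Stack per-reaction representation vectors into a FeatureMatrix."""
    df = pd.DataFrame({rid: s for rid, s in rows.items()}).T
    df.index = df.index.astype(str)
    return FeatureMatrix(df)
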