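"""Boltzmann statistics, energy-window filtering and RMSD deduplication.

Conformer ensembles from metadynamics searches carry near-duplicates and
high-energy outliers.  Before descriptor aggregation we (1) drop conformers
outside a free-energy window above the minimum, (2) collapse geometric
duplicates by greedy energy-ordered leader clustering on heavy-atom Kabsch
RMSD, and (3) weight the survivors by their Boltzmann populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .selectivity import R_KCAL
from .structio import ConformerEnsemble, Structure

#: Default window (kcal/mol) for duplicate removal.
DEDUP_WINDOW = 10.0
#: Default window (kcal/mol) for descriptor aggregation.
AGGREGATION_WINDOW = 5.0


@dataclass
class BoltzmannWeights:
    """Per-conformer populations at a temperature.

    ``reference_energy`` is the ensemble minimum; weights are computed from
    energies relative to it, so adding a constant to all energies changes
    nothing.
    """

    weights: np.ndarray
    temperature: float
    reference_energy: float


def boltzmann_weights(free_energies, temperature: float) -> BoltzmannWeights:
    """Boltzmann populations w_i ∝ exp(-(G_i - G_min)/RT).

    Energies in kcal/mol, temperature in K.
    """
    energies = np.asarray(free_energies, dtype=float)
    if energies.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(energies)):
        raise ValueError("non-finite free energies")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    ref = float(energies.min())
    w = np.exp(-(energies - ref) / (R_KCAL * temperature))
    w /= w.sum()
    return BoltzmannWeights(weights=w, temperature=temperature, reference_energy=ref)


def filter_energy_window(ensemble: ConformerEnsemble, window: float = AGGREGATION_WINDOW) -> ConformerEnsemble:
    """Keep conformers with G_i - G_min <= window (kcal/mol); order preserved."""
    if window <= 0:
        raise ValueError("window must be > 0 kcal/mol")
    g = ensemble.free_energies
    keep = np.flatnonzero(g - g.min() <= window)
    return ensemble.subset(keep)


def _heavy_mask(structure: Structure) -> np.ndarray:
    return np.array([el != "H" for el in structure.elements])


def rmsd_kabsch(a: Structure, b: Structure, heavy_only: bool = False) -> float:
    """Minimum RMSD (Å) between two conformers over rigid rotation+translation.

    Uses the Kabsch solution (proper rotation enforced) via
    scipy's ``Rotation.align_vectors`` after centering both geometries.
    """
    if a.elements != b.elements:
        raise ValueError("structures differ in element sequence")
    pa, pb = a.coords, b.coords
    if heavy_only:
        mask = _heavy_mask(a)
        if mask.any():
            pa, pb = pa[mask], pb[mask]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return float(rssd) / np.sqrt(len(pa))


def dedup_by_rmsd(
    ensemble: ConformerEnsemble, threshold: float = 0.25, heavy_only: bool = True
) -> ConformerEnsemble:
    """Greedy energy-ordered leader clustering.

    Conformers are visited in ascending free energy; one is kept iff its RMSD
    to every previously kept leader exceeds ``threshold`` (Å).  Deterministic
    and idempotent; the global minimum always survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 Å")
    order = np.argsort(ensemble.free_energies, kind="stable")
    kept: list[int] = []
    for i in order:
        candidate = ensemble.conformers[i]
        if all(
            rmsd_kabsch(candidate, ensemble.conformers[j], heavy_only=heavy_only) > threshold
            for j in kept
        ):
            kept.append(int(i))
    kept.sort()  # preserve input order in the result
    return ensemble.subset(kept)
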