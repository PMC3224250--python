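"""Solvent-accessible surface area and buried crystallographic waters.

SASA is computed with the Shrake–Rupley method: each atom's sphere of
radius (vdW + probe) is sampled at quasi-uniform points (a Fibonacci
lattice); the accessible area is the fraction of points not inside any
neighbor's expanded sphere, times 4π(r+p)².

Buried waters are counted by iterative surface peeling: treat every
retained water as a single sphere (default radius 1.4 Å), compute the
waters' SASA in the context of the polymer plus the other retained waters,
remove *all* waters whose area exceeds a small tolerance in the same pass,
and repeat until a fixed point.  Waters shielded only by exposed waters
are thereby peeled away layer by layer; the survivors are the buried set.
The loop removes at least one water per iteration or stops, so it runs at
most n_waters + 1 passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ResidueKey, Structure


@lru_cache(maxsize=8)
def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


@dataclass
class SasaResult:
    """Per-atom accessible areas (Å²) at a stated probe and point count."""

    areas: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())


def _sasa_areas(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    n_points: int,
    targets: np.ndarray,
) -> np.ndarray:
    """Shrake–Rupley areas for the ``targets`` subset of atoms."""
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = float(expanded.max())
    areas = np.empty(len(targets))
    for k, i in enumerate(targets):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = expanded[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[k] = frac * 4.0 * np.pi * ri * ri
    return areas


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Solvent-accessible surface area of every atom in the structure."""
    if n_points < 92:
        raise ValueError("n_points must be at least 92 for a usable quadrature")
    coords = structure.coords()
    radii = structure.radii()
    areas = _sasa_areas(coords, radii, probe_radius, n_points, np.arange(len(coords)))
    return SasaResult(areas=areas, probe_radius=probe_radius, n_points=n_points)


@dataclass
class BurialResult:
    """Outcome of iterative water peeling."""

    iterations: list[list[ResidueKey]]  # waters removed at each pass
    buried_keys: list[ResidueKey]
    count: int
    probe_radius: float
    water_radius: float


def count_buried_waters(
    structure: Structure,
    probe_radius: float = 1.4,
    water_radius: float = 1.4,
    n_points: int = 960,
    area_tolerance: float = 0.01,
) -> BurialResult:
    """Count crystallographic waters that survive iterative surface peeling.

    The context for SASA is the polymer plus currently retained waters
    (each water a single sphere of ``water_radius``); non-water
    heteroatoms are excluded, mirroring the void analysis.  The
    ``area_tolerance`` (Å²) absorbs quadrature noise — the final count is
    insensitive to it over several orders of magnitude.
    """
    protein_idx = [i for i, a in enumerate(structure.atoms)
                   if not a.is_water and not a.is_hetero]
    water_idx = [i for i, a in enumerate(structure.atoms) if a.is_water]
    if not water_idx:
        return BurialResult([], [], 0, probe_radius, water_radius)

    prot_coords = structure.coords()[protein_idx] if protein_idx else np.empty((0, 3))
    prot_radii = (
        structure.subset(protein_idx).radii() if protein_idx else np.empty(0)
    )
    water_coords = structure.coords()[water_idx]
    water_keys = [structure.atoms[i].residue_key for i in water_idx]

    retained = list(range(len(water_idx)))
    iterations: list[list[ResidueKey]] = []
    while retained:
        wc = water_coords[retained]
        coords = np.vstack([prot_coords, wc])
        radii = np.concatenate([prot_radii, np.full(len(retained), water_radius)])
        targets = np.arange(len(prot_coords), len(coords))
        areas = _sasa_areas(coords, radii, probe_radius, n_points, targets)
        exposed = [retained[k] for k in range(len(retained)) if areas[k] > area_tolerance]
        if not exposed:
            break
        iterations.append([water_keys[i] for i in exposed])
        exposed_set = set(exposed)
        retained = [i for i in retained if i not in exposed_set]
    buried = [water_keys[i] for i in retained]
    return BurialResult(
        iterations=iterations,
        buried_keys=buried,
        count=len(buried),
        probe_radius=probe_radius,
        water_radius=water_radius,
    )


def count_buried_waters_per_chain(
    structure: Structure, **kwargs
) -> dict[str, BurialResult]:
    """Run burial per polymer chain; useful for multi-chain entries.

    Each chain is peeled against its own polymer atoms plus the waters
    assigned to that chain (or all waters when none share its chain id).
    Multi-chain reports average the per-chain counts.
    """
    chains = sorted(
        {a.chain_id for a in structure.atoms if not a.is_water and not a.is_hetero}
    )
    out: dict[str, BurialResult] = {}
    for chain in chains:
        idx = [
            i
            for i, a in enumerate(structure.atoms)
            if (not a.is_water and not a.is_hetero and a.chain_id == chain)
        ]
        wat = [
            i for i, a in enumerate(structure.atoms)
            if a.is_water and a.chain_id == chain
        ]
        if not wat:
            wat = [i for i, a in enumerate(structure.atoms) if a.is_water]
        out[chain] = count_buried_waters(structure.subset(idx + wat), **kwargs)
    return out


def mean_buried_count(per_chain: dict[str, BurialResult]) -> float:
    if not per_chain:
        return 0.0
    return sum(r.count for r in per_chain.values()) / len(per_chain)
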