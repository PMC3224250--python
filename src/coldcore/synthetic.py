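"""Synthetic structures and cohorts with planted, analytically known truth.

Nothing here attempts physical realism — no rotamers, no energetics, no
real protein geometry.  The generators target the *contracts* of the
pipeline instead:

* ``make_cage`` builds a sealed spherical shell of pseudo-atoms whose
  interior is probe-accessible with an exactly known analytic volume,
  (4/3)π(inner − atom − probe)³ — the oracle for the void detector;
* ``make_open_pocket`` opens a spherical cap wide enough for the probe,
  turning the cavity into a pocket with one mouth;
* ``make_bottleneck_cage`` gives the mouth a fixed aperture so that small
  probes pass (pocket) while water-sized probes do not (cavity) — the
  geometric mechanism behind probe-size-dependent cavity counts;
* tight sub-probe "water cages" seal a single crystallographic water with
  zero SASA while presenting no probe-accessible interior at any probe in
  the standard sweep, so planted buried-water counts never perturb the
  void statistics;
* ``plant_b_profile`` writes per-residue Cα B-values with
  secondary-structure-specific shifts, Gaussian noise, and multiplicative
  planted outliers (×5 the median, guaranteed to trip the M > 3.5 filter);
* ``make_cohort`` assembles paired psychrophile/mesophile structures with
  planted mean cavity-size difference, acidic wall bias, extra buried
  waters, and per-class flexibility shifts, together with a truth table.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydration import fibonacci_sphere
from .structure_io import AtomRecord, SSAnnotation, Structure

DEFAULT_PROBE = 1.4  # Å, water-sized
DEFAULT_ATOM_RADIUS = 1.7  # Å, matches the default (Bondi) carbon radius
WATER_RADIUS = 1.4
MIN_WATER_SPACING = 2.6  # Å, roughly an O···O hydrogen-bond distance

#: Wall-residue class frequencies for an unbiased (mesophile-like) cavity
#: lining; loosely modeled on buried-residue composition.
BASE_WALL_FREQS = {"hydrophobic": 0.45, "polar": 0.30, "basic": 0.12, "acidic": 0.13}

_CLASS_MEMBERS = {
    "hydrophobic": ("LEU", "VAL", "ILE", "ALA", "PHE", "MET"),
    "polar": ("SER", "THR", "ASN", "GLN", "GLY"),
    "basic": ("LYS", "ARG", "HIS"),
    "acidic": ("ASP", "GLU"),
}

class SyntheticError(ValueError):
    pass


class SealError(SyntheticError):
    pass


@dataclass
class CageSpec:
    """Parameters of one spherical cage.

    ``inner_radius`` is the radius of the shell-atom centers; the probe
    center can reach a concentric ball of radius
    inner_radius − atom_radius − probe.  ``n_shell_atoms`` defaults to a
    density of ~0.8 Å² per atom, which overlaps neighbors heavily and
    seals the shell against all probes in the standard sweep.
    """

    inner_radius: float
    atom_radius: float = DEFAULT_ATOM_RADIUS
    n_shell_atoms: int | None = None
    n_interior_waters: int = 0
    n_surface_waters: int = 0
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inner_radius <= self.atom_radius + DEFAULT_PROBE:
            raise SyntheticError(
                "inner_radius must exceed atom_radius + 1.4 Å so a water-sized "
                "probe fits inside"
            )
        if self.jitter_sd < 0:
            raise SyntheticError("jitter_sd must be non-negative")

    @property
    def shell_count(self) -> int:
        if self.n_shell_atoms is not None:
            return self.n_shell_atoms
        return int(math.ceil(4.0 * math.pi * self.inner_radius**2 / 0.8))

    def accessible_radius(self, probe: float = DEFAULT_PROBE) -> float:
        return self.inner_radius - self.atom_radius - probe

    def analytic_volume(self, probe: float = DEFAULT_PROBE) -> float:
        r = self.accessible_radius(probe)
        return 4.0 / 3.0 * math.pi * r**3 if r > 0 else 0.0


class _Builder:
    """Accumulates atom records with consistent serial/residue numbering."""

    def __init__(self) -> None:
        self.atoms: list[AtomRecord] = []
        self._res_counters: dict[str, int] = {}

    def _next_res(self, chain: str) -> int:
        self._res_counters[chain] = self._res_counters.get(chain, 0) + 1
        return self._res_counters[chain]

    def add_pseudo_atom(
        self,
        pos: np.ndarray,
        radius: float,
        chain: str,
        resname: str = "ALA",
        atom_name: str | None = None,
        b_factor: float = 20.0,
    ) -> None:
        if atom_name is None:
            atom_name = "CA" if resname == "GLY" else "CB"
        self.atoms.append(
            AtomRecord(
                serial=len(self.atoms) + 1,
                atom_name=atom_name,
                element="C",
                alt_loc="",
                residue_name=resname,
                chain_id=chain,
                residue_seq=self._next_res(chain),
                insertion_code="",
                coords=np.asarray(pos, dtype=float),
                occupancy=1.0,
                b_factor=b_factor,
                is_hetero=False,
                is_water=False,
                vdw_radius=radius,
            )
        )

    def add_water(self, pos: np.ndarray) -> None:
        self.atoms.append(
            AtomRecord(
                serial=len(self.atoms) + 1,
                atom_name="O",
                element="O",
                alt_loc="",
                residue_name="HOH",
                chain_id="W",
                residue_seq=self._next_res("W"),
                insertion_code="",
                coords=np.asarray(pos, dtype=float),
                occupancy=1.0,
                b_factor=30.0,
                is_hetero=True,
                is_water=True,
                vdw_radius=WATER_RADIUS,
            )
        )

    def add_ca(self, pos: np.ndarray, resname: str, b_factor: float, chain: str = "A") -> None:
        self.atoms.append(
            AtomRecord(
                serial=len(self.atoms) + 1,
                atom_name="CA",
                element="C",
                alt_loc="",
                residue_name=resname,
                chain_id=chain,
                residue_seq=self._next_res(chain),
                insertion_code="",
                coords=np.asarray(pos, dtype=float),
                occupancy=1.0,
                b_factor=float(b_factor),
                is_hetero=False,
                is_water=False,
                vdw_radius=DEFAULT_ATOM_RADIUS,
            )
        )


def _check_sealed(points: np.ndarray, atom_radius: float) -> None:
    """Nearest-neighbor spacing must stay below one atom diameter."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    max_gap = float(d[:, 1].max())
    if max_gap >= 2.0 * atom_radius:
        raise SealError(
            f"shell not sealed: max nearest-neighbor spacing {max_gap:.2f} Å "
            f">= {2 * atom_radius:.2f} Å"
        )


def _shell_points(
    spec: CageSpec,
    rng: np.random.Generator,
    keep=None,
) -> np.ndarray:
    pts = fibonacci_sphere(spec.shell_count) * spec.inner_radius
    if keep is not None:
        pts = pts[keep(pts)]
    if spec.jitter_sd > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sd, pts.shape)
    return pts


def _sample_wall_names(
    rng: np.random.Generator, freqs: dict[str, float], n: int
) -> list[str]:
    classes = list(freqs)
    p = np.array([freqs[c] for c in classes], dtype=float)
    p /= p.sum()
    cls_idx = rng.choice(len(classes), size=n, p=p)
    out = []
    for ci in cls_idx:
        members = _CLASS_MEMBERS[classes[ci]]
        out.append(members[rng.integers(len(members))])
    return out


def _interior_water_positions(
    rng: np.random.Generator, n: int, max_radius: float, center: np.ndarray
) -> list[np.ndarray]:
    if n == 0:
        return []
    if max_radius <= 0:
        raise SyntheticError("cavity too small to hold interior waters")
    # The first water sits at the cage center: that is the one position a
    # snug chamber is guaranteed to seal (zero SASA).
    placed: list[np.ndarray] = [np.zeros(3)]
    for _ in range(20000):
        if len(placed) == n:
            break
        p = rng.uniform(-max_radius, max_radius, 3)
        if np.linalg.norm(p) > max_radius:
            continue
        if all(np.linalg.norm(p - q) >= MIN_WATER_SPACING for q in placed):
            placed.append(p)
    if len(placed) < n:
        raise SyntheticError(
            f"could not place {n} waters at {MIN_WATER_SPACING} Å spacing "
            f"inside radius {max_radius:.2f} Å"
        )
    return [center + p for p in placed[:n]]


def _add_cage_shell(
    builder: _Builder,
    pts: np.ndarray,
    spec: CageSpec,
    center: np.ndarray,
    chain: str,
    rng: np.random.Generator,
    wall_freqs: dict[str, float] | None,
) -> None:
    names = (
        _sample_wall_names(rng, wall_freqs, len(pts))
        if wall_freqs is not None
        else ["ALA"] * len(pts)
    )
    for p, name in zip(pts, names):
        builder.add_pseudo_atom(center + p, spec.atom_radius, chain, resname=name)


def make_cage(
    spec: CageSpec,
    probe: float = DEFAULT_PROBE,
    center=(0.0, 0.0, 0.0),
    chain: str = "C",
    wall_freqs: dict[str, float] | None = None,
    structure_id: str = "cage",
) -> tuple[Structure, float]:
    """Build a sealed spherical cage; returns (structure, analytic volume).

    The analytic volume is the probe-center-accessible interior for the
    given probe.  Interior waters (if any) are placed uniformly inside the
    accessible ball with pairwise spacing ≥ 2.6 Å; surface waters sit just
    outside the shell.  Note that interior waters are only guaranteed
    *zero-SASA* (buried) when the chamber is snug — within ~3 Å of the
    water surface; large chambers leave a lone central water locally
    exposed, exactly as the peeling algorithm defines exposure.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(center, dtype=float)
    builder = _Builder()
    pts = _shell_points(spec, rng)
    _check_sealed(pts, spec.atom_radius)
    _add_cage_shell(builder, pts, spec, center, chain, rng, wall_freqs)
    acc = spec.accessible_radius(probe)
    for pos in _interior_water_positions(rng, spec.n_interior_waters, acc - 0.2, center):
        builder.add_water(pos)
    out_r = spec.inner_radius + spec.atom_radius + WATER_RADIUS + 0.3
    for _ in range(spec.n_surface_waters):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        builder.add_water(center + out_r * u)
    return Structure(id=structure_id, atoms=builder.atoms, resolution=1.8), spec.analytic_volume(probe)


def mouth_aperture(spec: CageSpec, mouth_angle: float) -> float:
    """Clear radius (Å) of the cap opening for a given full mouth angle (deg)."""
    half = math.radians(mouth_angle) / 2.0
    return spec.inner_radius * math.sin(half) - spec.atom_radius


def make_open_pocket(
    spec: CageSpec,
    mouth_angle: float,
    probe: float = DEFAULT_PROBE,
    center=(0.0, 0.0, 0.0),
    chain: str = "C",
    structure_id: str = "pocket",
) -> Structure:
    """Cage with a spherical-cap opening around +z wide enough for the probe.

    ``mouth_angle`` is the full cone angle (degrees) of the removed cap.
    Raises :class:`SealError` when the aperture cannot pass the probe.
    """
    if not 0 < mouth_angle < 120:
        raise SyntheticError("mouth_angle must lie in (0, 120) degrees")
    aperture = mouth_aperture(spec, mouth_angle)
    if aperture <= probe:
        raise SealError(
            f"mouth aperture {aperture:.2f} Å cannot pass probe {probe:.2f} Å"
        )
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(center, dtype=float)
    half = math.radians(mouth_angle) / 2.0
    cos_half = math.cos(half)

    def keep(pts: np.ndarray) -> np.ndarray:
        return pts[:, 2] < cos_half * spec.inner_radius

    builder = _Builder()
    pts = _shell_points(spec, rng, keep=keep)
    _add_cage_shell(builder, pts, spec, center, chain, rng, None)
    return Structure(id=structure_id, atoms=builder.atoms, resolution=1.8)


def make_bottleneck_cage(
    spec: CageSpec,
    aperture: float = 1.3,
    center=(0.0, 0.0, 0.0),
    chain: str = "C",
    wall_freqs: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    n_ring: int = 24,
    structure_id: str = "bottleneck",
) -> Structure:
    """Cage whose single mouth has a fixed clear radius (``aperture``, Å).

    Probes smaller than the aperture can pass (the void is a pocket);
    larger probes cannot (the void is a cavity).  The mouth is a circular
    hole around +z rimmed by a dense ring of atoms on the shell sphere.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    center = np.asarray(center, dtype=float)
    ring_radius = aperture + spec.atom_radius
    if ring_radius >= spec.inner_radius:
        raise SyntheticError("aperture too wide for this cage")
    theta = math.asin(ring_radius / spec.inner_radius)
    z_ring = spec.inner_radius * math.cos(theta)

    def keep(pts: np.ndarray) -> np.ndarray:
        return pts[:, 2] < z_ring

    builder = _Builder()
    pts = _shell_points(spec, rng, keep=keep)
    _add_cage_shell(builder, pts, spec, center, chain, rng, wall_freqs)
    ring_names = (
        _sample_wall_names(rng, wall_freqs, n_ring) if wall_freqs else ["ALA"] * n_ring
    )
    for k, name in enumerate(ring_names):
        phi = 2.0 * math.pi * k / n_ring
        pos = center + np.array(
            [ring_radius * math.cos(phi), ring_radius * math.sin(phi), z_ring]
        )
        builder.add_pseudo_atom(pos, spec.atom_radius, chain, resname=name)
    return Structure(id=structure_id, atoms=builder.atoms, resolution=1.8)


def _add_water_cage(
    builder: _Builder,
    center: np.ndarray,
    chain: str,
    shell_radius: float = 2.25,
    n_atoms: int = 40,
    atom_radius: float = DEFAULT_ATOM_RADIUS,
) -> None:
    """A snug shell sealing one water with zero SASA.

    The shell-center radius (2.25 Å) keeps the interior clear of *probe*
    centers even for a 0.6 Å probe (2.25 < 1.7 + 0.6), so the planted
    water adds no void at any probe in the standard sweep.
    """
    for p in fibonacci_sphere(n_atoms) * shell_radius:
        builder.add_pseudo_atom(center + p, atom_radius, chain, resname="ALA")
    builder.add_water(center)


def make_water_plug_fixture(structure_id: str = "plug") -> tuple[Structure, int]:
    """A chamber-and-channel fixture with a chain of three waters.

    The innermost water sits in a snug chamber (sealed by protein alone);
    two more waters stack in the exit channel.  Peeling must remove the
    outermost water first, then the middle one it was shielding, and stop:
    the planted buried count is exactly 1.
    """
    builder = _Builder()
    chamber_r = 2.95
    hole_half = math.radians(40.0)

    pts = fibonacci_sphere(220) * chamber_r
    pts = pts[pts[:, 2] < math.cos(hole_half) * chamber_r]
    for p in pts:
        builder.add_pseudo_atom(p, DEFAULT_ATOM_RADIUS, "C", resname="ALA")
    # Rim of the chamber hole.
    rim_r = chamber_r * math.sin(hole_half)
    z_rim = chamber_r * math.cos(hole_half)
    for k in range(16):
        phi = 2 * math.pi * k / 16
        builder.add_pseudo_atom(
            np.array([rim_r * math.cos(phi), rim_r * math.sin(phi), z_rim]),
            DEFAULT_ATOM_RADIUS,
            "C",
            resname="ALA",
        )
    # Channel collar above the chamber.
    for z, radius, n in ((3.6, 3.2, 16), (5.0, 3.2, 16)):
        for k in range(n):
            phi = 2 * math.pi * k / n
            builder.add_pseudo_atom(
                np.array([radius * math.cos(phi), radius * math.sin(phi), z]),
                DEFAULT_ATOM_RADIUS,
                "C",
                resname="ALA",
            )
    builder.add_water(np.array([0.0, 0.0, 0.0]))  # buried
    builder.add_water(np.array([0.0, 0.0, 3.6]))  # shielded by the outer water
    builder.add_water(np.array([0.0, 0.0, 6.2]))  # exposed
    return Structure(id=structure_id, atoms=builder.atoms, resolution=1.8), 1


def merge_structures(structures: list[Structure], structure_id: str) -> Structure:
    """Concatenate several structures into one (serials renumbered)."""
    atoms: list[AtomRecord] = []
    for st in structures:
        for a in st.atoms:
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1,
                    atom_name=a.atom_name,
                    element=a.element,
                    alt_loc=a.alt_loc,
                    residue_name=a.residue_name,
                    chain_id=a.chain_id,
                    residue_seq=a.residue_seq + 10000 * structures.index(st),
                    insertion_code=a.insertion_code,
                    coords=a.coords.copy(),
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                    is_hetero=a.is_hetero,
                    is_water=a.is_water,
                    vdw_radius=a.vdw_radius,
                )
            )
    return Structure(id=structure_id, atoms=atoms, resolution=structures[0].resolution)


# --------------------------------------------------------------------------
# B-profiles and secondary structure
# --------------------------------------------------------------------------

_SS_RUN_WEIGHTS = {"H": 0.26, "E": 0.24, "I": 0.09, "T": 0.13, "S": 0.07, "G": 0.06, "-": 0.15}


def random_ss_string(n: int, rng: np.random.Generator) -> str:
    """Random secondary-structure string built from short runs.

    The class mix deliberately over-represents π-helix (I) relative to real
    DSSP output so that per-class statistics have usable sample sizes.
    """
    classes = list(_SS_RUN_WEIGHTS)
    probs = np.array(list(_SS_RUN_WEIGHTS.values()))
    probs /= probs.sum()
    out: list[str] = []
    while len(out) < n:
        cls = str(rng.choice(classes, p=probs))
        run = int(rng.integers(3, 9))
        out.extend([cls] * run)
    return "".join(out[:n])


def plant_b_profile(
    ss_string: str,
    class_shift: dict[str, float] | None = None,
    noise_sd: float = 2.0,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    baseline: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue B-values: baseline + per-class shift + noise + planted outliers.

    Outliers are multiplicative (5× the profile median), which guarantees a
    modified z-score far beyond the 3.5 cutoff for typical noise levels.
    Returns ``(b_values, outlier_indices)``.
    """
    if noise_sd <= 0:
        raise SyntheticError("noise_sd must be positive")
    if not 0 <= outlier_fraction < 0.2:
        raise SyntheticError("outlier_fraction must lie in [0, 0.2)")
    rng = np.random.default_rng(seed)
    shift = class_shift or {}
    n = len(ss_string)
    b = baseline + np.array([shift.get(c, 0.0) for c in ss_string]) + rng.normal(
        0.0, noise_sd, n
    )
    b = np.maximum(b, 1.0)
    n_out = int(round(outlier_fraction * n))
    idx = rng.choice(n, size=n_out, replace=False) if n_out else np.empty(0, dtype=int)
    if n_out:
        b[idx] = 5.0 * np.median(b)
    return b, np.sort(idx)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Planted effects and noise for a paired psychrophile/mesophile cohort.

    The four planted effects mirror the comparative findings the pipeline
    is built to detect: a larger average cavity size in the psychrophile at
    the water-sized probe (``cavity_volume_effect``, realized through a
    bottleneck cavity that only closes off at probes above its 1.3 Å
    aperture), an acidic shift in cavity wall composition
    (``acidic_lining_bias``, moved from the hydrophobic class), extra
    buried waters (``buried_water_effect``), and higher strand/π-helix
    flexibility (``b_effect_by_class``, Å² added to raw Cα B-values).
    """

    n_pairs: int = 20
    base_cavity_volume: float = 30.0  # Å³, mesophile-scale average cavity
    cavity_volume_effect: float = 4.0  # Å³, psychro minus meso in Vol/Cav
    cavity_volume_sd: float = 3.0  # Å³, sd of the pair difference
    acidic_lining_bias: float = 0.15
    base_buried_mean: float = 6.0
    buried_water_effect: float = 3.0
    buried_noise_sd: float = 1.0
    n_surface_waters: int = 8
    b_effect_by_class: dict[str, float] = field(
        default_factory=lambda: {"E": 4.0, "I": 4.0}
    )
    b_baseline: float = 20.0
    b_noise_sd: float = 2.0
    outlier_fraction: float = 0.02
    n_residues: int = 200
    bottleneck_aperture: float = 1.3
    probe: float = DEFAULT_PROBE
    atom_radius: float = DEFAULT_ATOM_RADIUS
    jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise SyntheticError("n_pairs must be at least 2")
        for name in ("cavity_volume_sd", "buried_noise_sd", "b_noise_sd"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be non-negative")
        if not 0 <= self.acidic_lining_bias <= BASE_WALL_FREQS["hydrophobic"]:
            raise SyntheticError(
                "acidic_lining_bias must lie in [0, base hydrophobic frequency]"
            )


@dataclass
class SyntheticPair:
    pair_id: str
    psy: Structure
    mes: Structure
    ss: SSAnnotation  # shared secondary structure of chain A
    sequence: str


def _volume_to_inner_radius(volume: float, atom_radius: float, probe: float) -> float:
    rho = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return rho + atom_radius + probe


def _biased_freqs(bias: float) -> dict[str, float]:
    f = dict(BASE_WALL_FREQS)
    f["acidic"] += bias
    f["hydrophobic"] -= bias
    return f


def _build_member(
    rng: np.random.Generator,
    spec: CohortSpec,
    vol_main: float,
    vol_bottle: float,
    wall_freqs: dict[str, float],
    n_buried: int,
    b_values: np.ndarray,
    sequence: str,
    structure_id: str,
    growth_temp: float,
    thermal_class: str,
) -> Structure:
    builder = _Builder()
    # Main sealed cavity at the origin.
    main_spec = CageSpec(
        inner_radius=_volume_to_inner_radius(vol_main, spec.atom_radius, spec.probe),
        atom_radius=spec.atom_radius,
        jitter_sd=spec.jitter_sd,
        seed=int(rng.integers(2**31)),
    )
    main_rng = np.random.default_rng(main_spec.seed)
    pts = _shell_points(main_spec, main_rng)
    _check_sealed(pts, spec.atom_radius)
    _add_cage_shell(builder, pts, main_spec, np.zeros(3), "C", main_rng, wall_freqs)
    # Bottleneck cavity: sealed at water-sized probes, open below the aperture.
    bottle_spec = CageSpec(
        inner_radius=_volume_to_inner_radius(vol_bottle, spec.atom_radius, spec.probe),
        atom_radius=spec.atom_radius,
        jitter_sd=spec.jitter_sd,
        seed=int(rng.integers(2**31)),
    )
    bottle = make_bottleneck_cage(
        bottle_spec,
        aperture=spec.bottleneck_aperture,
        center=np.array([17.0, 0.0, 0.0]),
        chain="C",
        wall_freqs=wall_freqs,
        rng=np.random.default_rng(bottle_spec.seed),
    )
    for a in bottle.atoms:
        builder.add_pseudo_atom(a.coords, a.vdw_radius, "C", resname=a.residue_name)
    # Cα pseudo-chain carrying the planted B-profile: a dense lattice block
    # (2.6 Å pitch) that is void-free at every probe in the sweep.
    n_res = len(sequence)
    side = int(math.ceil(n_res ** (1.0 / 3.0)))
    origin = np.array([-(side - 1) * 1.3, 18.0, -(side - 1) * 1.3])
    k = 0
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if k >= n_res:
                    break
                pos = origin + 2.6 * np.array([ix, iy, iz])
                builder.add_ca(pos, _one_to_three(sequence[k]), b_values[k])
                k += 1
    # Buried waters, one per snug sub-probe cage.
    for w in range(n_buried):
        row, col = divmod(w, 5)
        center = np.array([-12.0 + 9.0 * col, 0.0, -15.0 - 9.0 * row])
        _add_water_cage(builder, center, "C", atom_radius=spec.atom_radius)
    # Surface waters on the outside of the main cage.
    out_r = main_spec.inner_radius + spec.atom_radius + WATER_RADIUS + 0.3
    for _ in range(spec.n_surface_waters):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        builder.add_water(out_r * u)
    return Structure(
        id=structure_id,
        atoms=builder.atoms,
        resolution=1.8,
        thermal_class=thermal_class,
        growth_temp=growth_temp,
    )


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _one_to_three(one: str) -> str:
    return _ONE_TO_THREE.get(one, "ALA")


def make_cohort(spec: CohortSpec) -> tuple[list[SyntheticPair], pd.DataFrame]:
    """Generate a paired cohort plus its truth table.

    Each pair shares a base fold: the same Cα lattice, sequence, secondary
    structure, and cage layout.  Planted quantities per structure:

    * main cavity volume: base ± N(0, sd/√2) per member (pairs the noise);
    * bottleneck cavity volume: equal to the member's main volume for the
      mesophile, main + 2×effect for the psychrophile, so the planted
      Vol/Cav difference at the reference probe is effect + N(0, sd);
    * buried waters: shared Poisson base per pair, member-level rounding
      noise, plus the planted extra count in the psychrophile;
    * wall composition: acidic share raised by the bias (taken from the
      hydrophobic share) in the psychrophile;
    * Cα B-values: per-class shifts added to the psychrophile member only.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_pairs)
    pairs: list[SyntheticPair] = []
    rows = []
    member_sd = spec.cavity_volume_sd / math.sqrt(2.0)
    for i, seed_i in enumerate(seeds):
        rng = np.random.default_rng(seed_i)
        pair_id = f"SYN{i:03d}"
        sequence = "".join(
            "ARNDCQEGHILKMFPSTWYV"[j] for j in rng.integers(0, 20, spec.n_residues)
        )
        ss_string = random_ss_string(spec.n_residues, rng)
        b_mes, _ = plant_b_profile(
            ss_string,
            class_shift=None,
            noise_sd=spec.b_noise_sd,
            outlier_fraction=spec.outlier_fraction,
            seed=int(rng.integers(2**31)),
            baseline=spec.b_baseline,
        )
        b_psy, _ = plant_b_profile(
            ss_string,
            class_shift=spec.b_effect_by_class,
            noise_sd=spec.b_noise_sd,
            outlier_fraction=spec.outlier_fraction,
            seed=int(rng.integers(2**31)),
            baseline=spec.b_baseline,
        )
        vol_mes = max(8.0, spec.base_cavity_volume + rng.normal(0.0, member_sd))
        vol_psy = max(8.0, spec.base_cavity_volume + rng.normal(0.0, member_sd))
        vol_bottle_mes = vol_mes
        vol_bottle_psy = vol_psy + 2.0 * spec.cavity_volume_effect
        if vol_bottle_psy < 8.0:
            vol_bottle_psy = 8.0
        buried_base = int(rng.poisson(spec.base_buried_mean))
        n_mes = max(0, buried_base + int(round(rng.normal(0.0, spec.buried_noise_sd))))
        n_psy = max(
            0,
            buried_base
            + int(round(rng.normal(spec.buried_water_effect, spec.buried_noise_sd))),
        )
        mes = _build_member(
            rng, spec, vol_mes, vol_bottle_mes, BASE_WALL_FREQS, n_mes,
            b_mes, sequence, f"{pair_id}M", 37.0, "mesophile",
        )
        psy = _build_member(
            rng, spec, vol_psy, vol_bottle_psy, _biased_freqs(spec.acidic_lining_bias),
            n_psy, b_psy, sequence, f"{pair_id}P", 4.0, "psychrophile",
        )
        ss = SSAnnotation(
            {("A", j + 1, ""): ss_string[j] for j in range(spec.n_residues)}
        )
        pairs.append(SyntheticPair(pair_id, psy, mes, ss, sequence))
        for role, st, vm, vb, nb, freqs in (
            ("psy", psy, vol_psy, vol_bottle_psy, n_psy,
             _biased_freqs(spec.acidic_lining_bias)),
            ("mes", mes, vol_mes, vol_bottle_mes, n_mes, BASE_WALL_FREQS),
        ):
            rows.append(
                {
                    "pair_id": pair_id,
                    "role": role,
                    "structure_id": st.id,
                    "true_main_volume": vm,
                    "true_bottleneck_volume": vb,
                    "true_cavity_count": 2,
                    "true_vol_per_cav": (vm + vb) / 2.0,
                    "true_buried_waters": nb,
                    "true_acidic_freq": freqs["acidic"],
                    "b_shift_E": (spec.b_effect_by_class.get("E", 0.0)
                                  if role == "psy" else 0.0),
                    "b_shift_I": (spec.b_effect_by_class.get("I", 0.0)
                                  if role == "psy" else 0.0),
                }
            )
    return pairs, pd.DataFrame(rows)
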