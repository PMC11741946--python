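"""Forward light-transport model: sources, fluence, absorbed energy, noise.

Fluence is computed by solving the FEM-discretized diffusion approximation
(see :mod:`qpamark.fem`) for a set of Gaussian sources placed one grid
spacing inside the boundary, and summing the per-source fields
(superposition — the operator is linear and independent of the sources).
The absorbed energy density is H = mu_a * phi per node; a noisy measurement
H_M is synthesized by adding white Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fem import DiffusionSystem, FEMesh, GridSpec, OpticalMap, assemble_system


@dataclass
class SourceSet:
    """Gaussian sources: ``positions`` (S, 2) in mm, standard deviation
    ``width`` in mm (truncated at 3*width), total power per source."""

    positions: np.ndarray
    width: float
    power: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if not self.width > 0:
            raise ValueError("source width must be positive")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass
class FluenceField:
    """Per-node field on the grid; ``role`` is 'fluence' or 'adjoint'.

    Fluence-role fields are nonnegative; adjoint fields may be signed.
    """

    grid: GridSpec
    values: np.ndarray  # (ny, nx)
    role: str = "fluence"


@dataclass
class AbsorbedEnergyMap:
    """Absorbed energy density H = mu_a * phi per node (arbitrary units).

    ``role`` distinguishes the noiseless model output ('H' / 'H_C') from a
    synthesized measurement ('H_M'), which records the SNR and seed used.
    """

    grid: GridSpec
    values: np.ndarray  # (ny, nx)
    role: str = "H"
    snr_db: float | None = None
    seed: int | None = None


def default_sources(grid: GridSpec, n_sources: int = 10,
                    width: float | None = None, power: float = 1.0) -> SourceSet:
    """``n_sources`` positions equally spaced along the rectangle one grid
    spacing inside the boundary (i.e. at distance h from the boundary-node
    lines), offset by half a spacing so sources avoid the corners.

    Width defaults to the grid spacing h.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    h = grid.h
    x0, x1 = 1.5 * h, (grid.nx - 1.5) * h
    y0, y1 = 1.5 * h, (grid.ny - 1.5) * h
    w, ht = x1 - x0, y1 - y0
    perimeter = 2.0 * (w + ht)
    arcs = (np.arange(n_sources) + 0.5) * perimeter / n_sources
    positions = np.empty((n_sources, 2))
    for k, s in enumerate(arcs):
        if s < w:                       # top edge, left -> right
            positions[k] = (x0 + s, y0)
        elif s < w + ht:                # right edge, top -> bottom
            positions[k] = (x1, y0 + (s - w))
        elif s < 2 * w + ht:            # bottom edge, right -> left
            positions[k] = (x1 - (s - w - ht), y1)
        else:                           # left edge, bottom -> top
            positions[k] = (x0, y1 - (s - 2 * w - ht))
    return SourceSet(positions, width=width if width is not None else h, power=power)


def source_loads(mesh: FEMesh, sources: SourceSet) -> np.ndarray:
    """Nodal load vectors, one row per source, each normalized to ``power``."""
    loads = np.empty((sources.n_sources, mesh.n_nodes))
    cutoff2 = (3.0 * sources.width) ** 2
    for k, (xs, ys) in enumerate(sources.positions):
        d2 = (mesh.nodes[:, 0] - xs) ** 2 + (mesh.nodes[:, 1] - ys) ** 2
        wgt = np.where(d2 <= cutoff2, np.exp(-0.5 * d2 / sources.width**2), 0.0)
        total = wgt.sum()
        if total <= 0:  # pathological width; fall back to the nearest node
            wgt = np.zeros(mesh.n_nodes)
            wgt[np.argmin(d2)] = 1.0
            total = 1.0
        loads[k] = sources.power * wgt / total
    return loads


def solve_fluence(mesh: FEMesh, optics: OpticalMap, sources: SourceSet,
                  system: DiffusionSystem | None = None) -> FluenceField:
    """Total fluence: solve the diffusion system for the summed source load.

    Because the operator does not depend on the sources, superposition lets a
    single solve against the combined right-hand side replace per-source
    solves. An already-assembled ``system`` for the same optics can be passed
    to reuse its factorization.
    """
    if system is None:
        system = assemble_system(mesh, optics)
    b = source_loads(mesh, sources).sum(axis=0)
    phi = system.solve(b)
    return FluenceField(mesh.grid, phi.reshape(mesh.grid.shape), role="fluence")


def absorbed_energy(optics: OpticalMap, phi: FluenceField, role: str = "H") -> AbsorbedEnergyMap:
    """H(i, j) = mu_a(i, j) * phi(i, j), elementwise."""
    if phi.values.shape != optics.grid.shape:
        raise ValueError("fluence shape does not match optics grid")
    return AbsorbedEnergyMap(optics.grid, optics.mu_a * phi.values, role=role)


def add_noise(h: AbsorbedEnergyMap, snr_db: float, seed: int) -> AbsorbedEnergyMap:
    """Additive white Gaussian noise at the given SNR (dB), measured against
    the mean signal power of H. ``snr_db = inf`` disables noise."""
    if math.isinf(snr_db) and snr_db > 0:
        return AbsorbedEnergyMap(h.grid, h.values.copy(), role="H_M",
                                 snr_db=snr_db, seed=seed)
    if not math.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    signal_power = float(np.mean(h.values**2))
    sigma = math.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = h.values + rng.normal(0.0, sigma, size=h.values.shape)
    return AbsorbedEnergyMap(h.grid, noisy, role="H_M", snr_db=snr_db, seed=seed)


def beer_lambert_fluence(phi0: float, mu_a: float, r: float) -> float:
    """Beer–Lambert fluence phi0 * exp(-mu_a * r) at depth r (mm)."""
    if np.any(np.asarray(r) < 0):
        raise ValueError("depth r must be nonnegative")
    if np.any(np.asarray(mu_a) < 0):
        raise ValueError("mu_a must be nonnegative")
    return phi0 * np.exp(-np.asarray(mu_a, float) * r)


def simulate_measurement(optics: OpticalMap, sources: SourceSet,
                         snr_db: float = 30.0, seed: int = 0,
                         mesh: FEMesh | None = None
                         ) -> tuple[FluenceField, AbsorbedEnergyMap, AbsorbedEnergyMap]:
    """Run the forward model end to end: (fluence, noiseless H, noisy H_M)."""
    from .fem import build_mesh

    if mesh is None:
        mesh = build_mesh(optics.grid)
    phi = solve_fluence(mesh, optics, sources)
    h = absorbed_energy(optics, phi)
    h_m = add_noise(h, snr_db, seed)
    return phi, h, h_m
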