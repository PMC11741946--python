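"""Finite-element machinery for the 2D diffusion approximation.

The computational domain is a regular pixel grid. One linear (P1) node is
placed at every pixel center and each grid cell is split into two triangles
by its main diagonal, so optical properties can be assigned to elements
directly from the pixel maps without interpolation.

The discretized operator is

    mu_a * phi  -  div( kappa * grad phi )  =  q0,     kappa = 1/(3*(mu_a + mu_s')),

with a Robin ("exit-only") boundary condition  phi + 2*A*kappa*dphi/dn = 0,
where A accounts for internal reflection at the refractive-index mismatch.
Mass and boundary matrices are lumped (diagonal), which keeps the system an
M-matrix and the computed fluence nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class GridSpec:
    """Regular pixel grid: ``nx`` columns, ``ny`` rows, spacing ``h`` in mm.

    Pixel (i, j) — row i from the top, column j, 0-based — has its center at
    ((j + 0.5)*h, (i + 0.5)*h) in mm, with y increasing downward (image
    convention).
    """

    nx: int
    ny: int
    h: float

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError(f"grid must be at least 3x3, got {self.ny}x{self.nx}")
        if not self.h > 0:
            raise ValueError(f"pixel spacing must be positive, got {self.h}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical size (width, height) in mm."""
        return (self.nx * self.h, self.ny * self.h)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of shape (ny, nx), in mm."""
        x = (np.arange(self.nx) + 0.5) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y)


@dataclass
class OpticalMap:
    """Per-pixel absorption ``mu_a`` and reduced scattering ``mu_s_prime`` (mm^-1).

    ``n_in``/``n_out`` are the refractive indices inside/outside the domain
    boundary (tissue vs. air). The anisotropy factor is absorbed into
    mu_s' = (1 - g) * mu_s and not stored separately.
    """

    grid: GridSpec
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    n_in: float = 1.33
    n_out: float = 1.0

    def __post_init__(self) -> None:
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_s_prime = np.asarray(self.mu_s_prime, dtype=float)
        if self.mu_s_prime.shape == ():
            self.mu_s_prime = np.full(self.grid.shape, float(self.mu_s_prime))
        if self.mu_a.shape != self.grid.shape or self.mu_s_prime.shape != self.grid.shape:
            raise ValueError(
                f"optical maps must have shape {self.grid.shape}, got "
                f"mu_a {self.mu_a.shape}, mu_s_prime {self.mu_s_prime.shape}"
            )
        if np.any(self.mu_a < 0):
            raise ValueError("mu_a must be nonnegative everywhere")
        if np.any(self.mu_s_prime <= 0):
            raise ValueError("mu_s_prime must be positive everywhere")
        if np.max(self.mu_a) >= np.min(self.mu_s_prime):
            warnings.warn(
                "max(mu_a) >= mu_s_prime somewhere: the diffusion approximation "
                "assumes mu_s' >> mu_a and may be inaccurate",
                stacklevel=2,
            )

    def with_mu_a(self, mu_a: np.ndarray) -> "OpticalMap":
        """Copy with a different absorption map (scattering unchanged)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return OpticalMap(self.grid, np.asarray(mu_a, float), self.mu_s_prime,
                              self.n_in, self.n_out)


# element-local geometric stiffness for the two congruent right triangles of a
# cell split by the main diagonal (legs of length h); independent of h in 2D
_S_LOWER = 0.5 * np.array([[1.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 1.0]])
_S_UPPER = 0.5 * np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0], [-1.0, -1.0, 2.0]])


@dataclass
class FEMesh:
    """Triangulation of a :class:`GridSpec` with per-element pixel assignment.

    ``pixel_of_element[e]`` is the flat node/pixel index whose optical
    properties element ``e`` carries (the top-left pixel of its grid cell).
    """

    grid: GridSpec
    nodes: np.ndarray            # (N, 2) mm
    elements: np.ndarray         # (E, 3) node indices
    pixel_of_element: np.ndarray  # (E,) flat pixel index
    element_areas: np.ndarray    # (E,) mm^2
    element_stiffness: np.ndarray  # (E, 3, 3) geometric stiffness (kappa = 1)
    boundary_nodes: np.ndarray   # sorted flat node indices
    boundary_edges: np.ndarray   # (B, 2) node-index pairs, each of length h
    node_areas: np.ndarray = field(default=None)  # (N,) lumped nodal areas, mm^2

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]


def build_mesh(grid: GridSpec) -> FEMesh:
    """Triangulate a pixel grid: nodes at pixel centers, 2 triangles per cell."""
    nx, ny, h = grid.nx, grid.ny, grid.h
    X, Y = grid.pixel_centers()
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    ii, jj = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    n00 = (ii * nx + jj).ravel()
    n01 = n00 + 1
    n10 = n00 + nx
    n11 = n10 + 1
    # lower triangle (n00, n01, n11) and upper triangle (n00, n11, n10),
    # split by the diagonal n00 -> n11, consistent across all cells
    tri_lower = np.column_stack([n00, n01, n11])
    tri_upper = np.column_stack([n00, n11, n10])
    elements = np.empty((2 * n00.size, 3), dtype=np.int64)
    elements[0::2] = tri_lower
    elements[1::2] = tri_upper

    pixel_of_element = np.repeat(n00, 2)  # both triangles take the cell's top-left pixel
    area = 0.5 * h * h
    element_areas = np.full(elements.shape[0], area)
    element_stiffness = np.empty((elements.shape[0], 3, 3))
    element_stiffness[0::2] = _S_LOWER
    element_stiffness[1::2] = _S_UPPER

    I, J = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    on_border = (I == 0) | (I == ny - 1) | (J == 0) | (J == nx - 1)
    boundary_nodes = np.flatnonzero(on_border.ravel())

    edges = []
    top = np.arange(nx)
    bottom = (ny - 1) * nx + np.arange(nx)
    left = np.arange(ny) * nx
    right = np.arange(ny) * nx + (nx - 1)
    for line in (top, bottom):
        edges.append(np.column_stack([line[:-1], line[1:]]))
    for line in (left, right):
        edges.append(np.column_stack([line[:-1], line[1:]]))
    boundary_edges = np.vstack(edges)

    node_areas = np.bincount(elements.ravel(),
                             weights=np.repeat(element_areas / 3.0, 3),
                             minlength=nodes.shape[0])

    return FEMesh(grid, nodes, elements, pixel_of_element, element_areas,
                  element_stiffness, boundary_nodes, boundary_edges,
                  node_areas=node_areas)


def internal_reflection_coefficient(n_in: float, n_out: float) -> float:
    """Robin boundary coefficient A for the exit-only condition.

    Uses the Groenhuis/Schweiger internal-reflection approximation

        A = (2/(1 - R0) - 1 + |cos(theta_c)|^3) / (1 - |cos(theta_c)|^2)

    with relative index n = n_in/n_out, Fresnel normal-incidence reflectance
    R0 = ((n-1)/(n+1))^2 and critical angle theta_c = arcsin(1/n). For a
    matched boundary (n = 1) this reduces to A = 1; for n < 1 the mismatch
    term is dropped and A = 1 is used.
    """
    n_rel = n_in / n_out
    if n_rel <= 1.0 + 1e-12:
        return 1.0
    r0 = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
    cos_tc = np.sqrt(1.0 - (1.0 / n_rel) ** 2)
    return float((2.0 / (1.0 - r0) - 1.0 + cos_tc**3) / (1.0 - cos_tc**2))


class DiffusionSystem:
    """Assembled sparse diffusion operator for one optical-property map.

    Reuses the sparsity pattern across repeated assemblies (the mesh is
    fixed during inversion; only mu_a changes), and caches the sparse LU
    factorization for the multiple right-hand sides of an iteration
    (sources, adjoint).
    """

    def __init__(self, mesh: FEMesh):
        self.mesh = mesh
        elems = mesh.elements
        # COO pattern of the 3x3 element blocks, built once
        self._rows = np.repeat(elems, 3, axis=1).ravel()
        self._cols = np.tile(elems, (1, 3)).ravel()
        n = mesh.n_nodes
        self._shape = (n, n)
        self._factor = None
        self.matrix: sp.csc_matrix | None = None
        self.robin_diag: np.ndarray | None = None
        self.kappa_e: np.ndarray | None = None

    def assemble(self, optics: OpticalMap) -> sp.csc_matrix:
        """Assemble mu_a*M + K(kappa) + R into a CSC matrix and factorize lazily."""
        if optics.grid.shape != self.mesh.grid.shape:
            raise ValueError("optical map does not match mesh grid")
        if np.any(optics.mu_s_prime <= 0):
            raise ValueError("mu_s_prime must be positive")
        return self.assemble_raw(optics.mu_a.ravel(), optics.mu_s_prime.ravel(),
                                 optics.n_in, optics.n_out)

    def assemble_raw(self, mu_a_flat: np.ndarray, mu_s_flat: np.ndarray,
                     n_in: float, n_out: float) -> sp.csc_matrix:
        """Assembly from flat per-pixel arrays, without map validation.

        Used by the inversion loops, whose trial iterates are not required to
        be physically admissible; the kappa denominator is floored to keep
        the stiffness term well defined.
        """
        mesh = self.mesh
        mu_a_e = mu_a_flat[mesh.pixel_of_element]
        mu_s_e = mu_s_flat[mesh.pixel_of_element]
        kappa_e = 1.0 / np.maximum(3.0 * (mu_a_e + mu_s_e), 1e-9)
        self.kappa_e = kappa_e

        stiff = kappa_e[:, None, None] * mesh.element_stiffness
        A = sp.coo_matrix((stiff.ravel(), (self._rows, self._cols)),
                          shape=self._shape).tocsc()

        # lumped absorption mass: area/3 of each adjacent element, times element mu_a
        mass_diag = np.bincount(
            mesh.elements.ravel(),
            weights=np.repeat(mu_a_e * mesh.element_areas / 3.0, 3),
            minlength=mesh.n_nodes,
        )
        # lumped Robin boundary term: (1/(2A)) * edge_length/2 per edge endpoint
        a_coef = internal_reflection_coefficient(n_in, n_out)
        edge_len = mesh.grid.h
        robin = np.zeros(mesh.n_nodes)
        np.add.at(robin, self.mesh.boundary_edges.ravel(),
                  edge_len / (2.0 * 2.0 * a_coef))
        self.robin_diag = robin

        A = A + sp.diags(mass_diag + robin, format="csc")
        self.matrix = A
        self._factor = None
        return A

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve against the last assembled matrix (LU cached across calls)."""
        if self.matrix is None:
            raise RuntimeError("assemble() must be called before solve()")
        if self._factor is None:
            self._factor = sp.linalg.splu(self.matrix)
        x = self._factor.solve(rhs)
        b_norm = np.linalg.norm(rhs)
        if b_norm > 0:
            res = np.linalg.norm(self.matrix @ x - rhs) / b_norm
            if res > 1e-10:
                raise ArithmeticError(
                    f"sparse solve did not reach required residual: {res:.3e} > 1e-10"
                )
        return x


def assemble_system(mesh: FEMesh, optics: OpticalMap) -> DiffusionSystem:
    """Assemble the SPD diffusion system for ``optics`` on ``mesh``."""
    system = DiffusionSystem(mesh)
    system.assemble(optics)
    return system
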