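"""Absorption recovery from measured absorbed-energy maps.

Five routes are provided, all anchored (optionally) by a fluence marker —
a chromophore whose absorption coefficient and location are known:

* :func:`invert_equal_fluence` — Beer–Lambert special case assuming the
  fluence at the unknown chromophore equals that at the marker;
* :func:`invert_beer_lambert_marker` — Beer–Lambert inversion accounting
  for the attenuation over the depth separating unknown and marker;
* :func:`run_sim` — simple iterative method: fixed-point update of mu_a as
  the ratio of measured absorbed energy to the modeled fluence;
* :func:`run_gbm` — quasi-Newton minimization of the absorbed-energy
  misfit with the analytic adjoint gradient, optionally resetting the
  marker pixels to their known value after every iteration;
* :func:`run_gbm_constrained` — the same minimization with the marker
  imposed as a spatial equality constraint (reduced-space optimization
  over the non-marker pixels).

The misfit is the volume-weighted functional

    eps(mu_a) = 1/2 * sum_i w_i * (H_M - H_C(mu_a))_i^2

with lumped nodal areas w_i, and its exact discrete gradient is computed by
one adjoint solve of the same FEM system (see :func:`error_gradient`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, newton

from .fem import DiffusionSystem, FEMesh, GridSpec, OpticalMap, build_mesh
from .forward import AbsorbedEnergyMap, FluenceField, SourceSet, default_sources, source_loads
from .optim import minimize_lbfgs
from .phantoms import MarkerPrior, RegionLabelMap

METHODS = ("BL_DIRECT", "EQUAL_FLUENCE", "SIM", "GBM", "GBM_CONSTRAINED")


@dataclass
class InversionConfig:
    """Knobs shared by the iterative inversion schemes.

    ``sigma`` is the SIM fluence regularizer (fluence units) stabilizing
    low-fluence regions; ``init_mu_a`` is the uniform initial guess — any
    sufficiently small value (<= 1e-5 mm^-1) gives equivalent results.
    """

    method: str = "GBM"
    use_marker: bool = True
    max_iter: int = 700
    sigma: float = 0.002
    init_mu_a: float = 1e-10
    clamp_negative: bool = True
    tol_error: float | None = None
    tol_optimality: float = 1e-12
    seed: int = 0
    lbfgs_memory: int = 10
    armijo_c1: float = 1e-4
    max_linesearch: int = 30

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.init_mu_a < 0:
            raise ValueError("init_mu_a must be nonnegative")


@dataclass
class InversionResult:
    """Recovered absorption map plus convergence diagnostics.

    ``error_trace`` holds log(||H_M - H_C||^2) per iteration (natural log of
    the volume-weighted squared misfit); ``region_traces`` maps region label
    to the per-iteration mean recovered mu_a over that region.
    """

    mu_a_hat: np.ndarray
    error_trace: np.ndarray
    iterations_used: int
    converged: bool
    reason: str
    region_traces: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Direct Beer-Lambert routes
# ---------------------------------------------------------------------------


def invert_equal_fluence(h_unknown: float, h_marker: float, mu_a_marker: float) -> float:
    """Absorption of the unknown chromophore assuming its fluence equals the
    marker's: mu_a = (H_unknown / H_marker) * mu_a_marker."""
    if h_marker <= 0:
        raise ValueError("H_marker must be positive")
    if mu_a_marker <= 0:
        raise ValueError("mu_a_marker must be positive")
    return (h_unknown / h_marker) * mu_a_marker


def invert_beer_lambert_marker(h_unknown: float, h_marker: float,
                               mu_a_marker: float, r: float) -> float:
    """Beer–Lambert marker inversion over a depth separation ``r`` (mm).

    Solves for the unique positive root of

        x * exp(x * r) = (H_unknown / H_marker) * mu_a_marker,

    the relation obtained when light traverses a homogeneous unknown layer of
    thickness r before reaching the marker. At r = 0 this reduces exactly to
    the equal-fluence inversion.
    """
    if h_unknown <= 0 or h_marker <= 0 or mu_a_marker <= 0:
        raise ValueError("energies and mu_a_marker must be positive")
    if r < 0:
        raise ValueError("depth r must be nonnegative")
    c = (h_unknown / h_marker) * mu_a_marker
    if not math.isfinite(c):
        raise ValueError("non-finite right-hand side in marker inversion")
    if r == 0:
        return c

    # solve in log form: ln(x) + x*r = ln(c); monotone in x > 0 and free of
    # the overflow of x*exp(x*r) at large absorption-depth products
    log_c = math.log(c)

    def g(x: float) -> float:
        return math.log(x) + x * r - log_c

    def gprime(x: float) -> float:
        return 1.0 / x + r

    try:
        root = newton(g, x0=1e-5, fprime=gprime, tol=1e-15, maxiter=200)
    except (RuntimeError, ValueError, OverflowError):
        root = brentq(g, 1e-300, max(c, 1.0), xtol=1e-15, rtol=8.9e-16)
    if not math.isfinite(root) or root < 0:
        raise ArithmeticError("marker inversion root finding failed")
    return float(root)


def apply_marker(mu_a: np.ndarray, marker: MarkerPrior) -> np.ndarray:
    """Overwrite the marker pixels with the known marker absorption."""
    out = np.array(mu_a, dtype=float, copy=True)
    out[marker.mask] = marker.mu_a_marker
    return out


# ---------------------------------------------------------------------------
# Shared forward machinery for the iterative schemes
# ---------------------------------------------------------------------------


class ForwardOperator:
    """Mesh, assembled-system cache and source load for one inversion run.

    The scattering map, refractive indices and source configuration are fixed;
    only mu_a changes between evaluations, so the sparsity pattern and the
    source load vector are built once.
    """

    def __init__(self, grid: GridSpec, mu_s_prime, sources: SourceSet | None = None,
                 n_in: float = 1.33, n_out: float = 1.0):
        self.grid = grid
        self.mesh = build_mesh(grid)
        self.system = DiffusionSystem(self.mesh)
        mu_s = np.asarray(mu_s_prime, dtype=float)
        if mu_s.shape == ():
            mu_s = np.full(grid.shape, float(mu_s))
        if mu_s.shape != grid.shape:
            raise ValueError("mu_s_prime shape does not match grid")
        if np.any(mu_s <= 0):
            raise ValueError("mu_s_prime must be positive everywhere")
        self.mu_s_flat = mu_s.ravel()
        self.n_in, self.n_out = n_in, n_out
        self.sources = sources if sources is not None else default_sources(grid)
        self.load = source_loads(self.mesh, self.sources).sum(axis=0)
        self.weights = self.mesh.node_areas

    def fluence(self, mu_a_flat: np.ndarray) -> np.ndarray:
        self.system.assemble_raw(mu_a_flat, self.mu_s_flat, self.n_in, self.n_out)
        return self.system.solve(self.load)

    def misfit(self, mu_a_flat: np.ndarray, h_m_flat: np.ndarray
               ) -> tuple[float, np.ndarray]:
        """Misfit eps and its exact gradient w.r.t. the per-pixel mu_a."""
        w = self.weights
        phi = self.fluence(mu_a_flat)
        h_c = mu_a_flat * phi
        r = h_m_flat - h_c
        eps = 0.5 * float(np.sum(w * r * r))
        phi_star = self.system.solve(w * mu_a_flat * r)
        grad = -w * r * phi + self._system_term(phi, phi_star)
        return eps, grad

    def _system_term(self, phi: np.ndarray, phi_star: np.ndarray) -> np.ndarray:
        """phi*^T (dA/dmu_a_p) phi per pixel p: lumped-mass derivative plus the
        kappa-derivative of the stiffness (dkappa/dmu_a = -3 kappa^2)."""
        mesh = self.mesh
        pa = phi[mesh.elements]        # (E, 3)
        pb = phi_star[mesh.elements]   # (E, 3)
        mass = (mesh.element_areas / 3.0) * np.einsum("ek,ek->e", pb, pa)
        stiff = (-3.0 * self.system.kappa_e**2) * np.einsum(
            "ei,eij,ej->e", pb, mesh.element_stiffness, pa
        )
        return np.bincount(mesh.pixel_of_element, weights=mass + stiff,
                           minlength=mesh.n_nodes)


def solve_adjoint(mesh: FEMesh, optics: OpticalMap, residual: np.ndarray,
                  system: DiffusionSystem | None = None) -> FluenceField:
    """Adjoint field phi*: same (self-adjoint) diffusion system, with nodal
    source w * mu_a * (H_M - H_C) — the volume-weighted residual load."""
    if system is None:
        system = DiffusionSystem(mesh)
        system.assemble(optics)
    rhs = mesh.node_areas * optics.mu_a.ravel() * np.asarray(residual).ravel()
    phi_star = system.solve(rhs)
    return FluenceField(mesh.grid, phi_star.reshape(mesh.grid.shape), role="adjoint")


def error_gradient(mesh: FEMesh, optics: OpticalMap, phi: FluenceField,
                   phi_star: FluenceField, h_m: np.ndarray, h_c: np.ndarray
                   ) -> np.ndarray:
    """Exact discrete gradient of eps = 1/2 sum_i w_i (H_M - H_C)_i^2.

    Per pixel: g = -w * (H_M - H_C) * phi + phi*^T (dA/dmu_a) phi, the
    discrete counterpart of the continuum expression
    -phi (H_M - H_C) + phi phi*.
    """
    op = ForwardOperator.__new__(ForwardOperator)
    op.mesh = mesh
    op.system = DiffusionSystem(mesh)
    mu_a_e = optics.mu_a.ravel()[mesh.pixel_of_element]
    mu_s_e = optics.mu_s_prime.ravel()[mesh.pixel_of_element]
    op.system.kappa_e = 1.0 / (3.0 * (mu_a_e + mu_s_e))
    w = mesh.node_areas
    r = (np.asarray(h_m).ravel() - np.asarray(h_c).ravel())
    g = -w * r * phi.values.ravel() + op._system_term(
        phi.values.ravel(), phi_star.values.ravel()
    )
    return g.reshape(mesh.grid.shape)


# ---------------------------------------------------------------------------
# Iterative schemes
# ---------------------------------------------------------------------------


def _region_means(mu_a_flat: np.ndarray, labels: RegionLabelMap | None
                  ) -> dict[int, float]:
    if labels is None:
        return {}
    flat = labels.labels.ravel()
    return {lab: float(mu_a_flat[flat == lab].mean()) for lab in labels.legend}


def _stack_traces(per_iter: list[dict[int, float]]) -> dict[int, np.ndarray]:
    if not per_iter:
        return {}
    return {lab: np.array([d[lab] for d in per_iter]) for lab in per_iter[0]}


def run_sim(h_m: AbsorbedEnergyMap, mu_s_prime, config: InversionConfig | None = None,
            marker: MarkerPrior | None = None, sources: SourceSet | None = None,
            labels: RegionLabelMap | None = None, n_in: float = 1.33,
            n_out: float = 1.0) -> InversionResult:
    """Simple iterative method: mu_a <- H_M / (phi(mu_a) + sigma).

    Each iteration solves the forward model at the current estimate and
    replaces mu_a by the elementwise ratio of the measurement to the modeled
    fluence, regularized by ``sigma`` in low-fluence regions. Negative values
    (possible where noise makes H_M negative) are clamped to zero, and the
    marker pixels are reset to their known absorption when a marker is given.
    """
    config = config or InversionConfig(method="SIM")
    op = ForwardOperator(h_m.grid, mu_s_prime, sources, n_in, n_out)
    h_m_flat = h_m.values.ravel()
    w = op.weights

    x = np.full(op.mesh.n_nodes, config.init_mu_a)
    trace: list[float] = []
    region_trace: list[dict[int, float]] = []
    reason, converged = "max_iter", False

    for _ in range(config.max_iter):
        if marker is not None:
            x[marker.mask.ravel()] = marker.mu_a_marker
        phi = op.fluence(x)
        r = h_m_flat - x * phi
        sse = float(np.sum(w * r * r))
        trace.append(np.log(max(sse, 1e-300)))
        region_trace.append(_region_means(x, labels))
        if config.tol_error is not None and math.sqrt(sse) <= config.tol_error:
            reason, converged = "tol_error", True
            break
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < 1e-14:
            reason, converged = "stagnation", True
            break
        x = h_m_flat / (phi + config.sigma)
        if config.clamp_negative:
            np.maximum(x, 0.0, out=x)

    if marker is not None:
        x[marker.mask.ravel()] = marker.mu_a_marker
    return InversionResult(
        mu_a_hat=x.reshape(h_m.grid.shape),
        error_trace=np.array(trace),
        iterations_used=len(trace),
        converged=converged,
        reason=reason,
        region_traces=_stack_traces(region_trace),
    )


def _run_gbm_common(h_m: AbsorbedEnergyMap, mu_s_prime, config: InversionConfig,
                    marker: MarkerPrior | None, constrained: bool,
                    sources: SourceSet | None, labels: RegionLabelMap | None,
                    n_in: float, n_out: float) -> InversionResult:
    op = ForwardOperator(h_m.grid, mu_s_prime, sources, n_in, n_out)
    h_m_flat = h_m.values.ravel()
    n = op.mesh.n_nodes
    marker_flat = marker.mask.ravel() if marker is not None else None

    if constrained:
        if marker is None:
            raise ValueError("constrained GBM requires a marker prior")
        free = ~marker_flat
        template = np.empty(n)
        template[marker_flat] = marker.mu_a_marker

        def fun(x_free: np.ndarray) -> tuple[float, np.ndarray]:
            full = template.copy()
            full[free] = x_free
            f, g = op.misfit(full, h_m_flat)
            return f, g[free]

        def project(x_free: np.ndarray) -> np.ndarray:
            return np.maximum(x_free, 0.0) if config.clamp_negative else x_free

        x0 = np.full(int(free.sum()), config.init_mu_a)

        def hook(x_free: np.ndarray, _f: float) -> dict[int, float]:
            full = template.copy()
            full[free] = x_free
            return _region_means(full, labels)

    else:
        def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
            return op.misfit(x, h_m_flat)

        def project(x: np.ndarray) -> np.ndarray:
            return np.maximum(x, 0.0) if config.clamp_negative else x

        x0 = np.full(n, config.init_mu_a)

        def hook(x: np.ndarray, _f: float) -> dict[int, float]:
            return _region_means(x, labels)

    post_step = None
    if not constrained and marker_flat is not None:
        def post_step(x: np.ndarray) -> np.ndarray:  # marker reset, Alg.-2 style
            out = x.copy()
            out[marker_flat] = marker.mu_a_marker
            return out

    tol_f = None
    if config.tol_error is not None:
        tol_f = 0.5 * config.tol_error**2
    res = minimize_lbfgs(
        fun, x0,
        max_iter=config.max_iter,
        memory=config.lbfgs_memory,
        tol_grad=config.tol_optimality,
        tol_f=tol_f,
        c1=config.armijo_c1,
        max_linesearch=config.max_linesearch,
        project=project,
        post_step=post_step,
        iterate_hook=hook if labels is not None else None,
    )

    if constrained:
        mu_a_hat = template.copy()
        mu_a_hat[free] = res.x
    else:
        mu_a_hat = res.x
    error_trace = np.log(np.maximum(2.0 * np.asarray(res.f_trace), 1e-300))
    return InversionResult(
        mu_a_hat=mu_a_hat.reshape(h_m.grid.shape),
        error_trace=error_trace,
        iterations_used=res.n_iter,
        converged=res.converged,
        reason=res.reason,
        region_traces=_stack_traces(res.x_trace_hook_values),
    )


def run_gbm(h_m: AbsorbedEnergyMap, mu_s_prime, config: InversionConfig | None = None,
            marker: MarkerPrior | None = None, sources: SourceSet | None = None,
            labels: RegionLabelMap | None = None, n_in: float = 1.33,
            n_out: float = 1.0) -> InversionResult:
    """Gradient-based method: quasi-Newton minimization of the misfit with
    the analytic adjoint gradient over the full mu_a map.

    When a marker is given, marker pixels are reset to the known absorption
    after every optimizer iteration (and before every trial evaluation);
    negatives are clamped per the configuration.
    """
    config = config or InversionConfig(method="GBM")
    return _run_gbm_common(h_m, mu_s_prime, config, marker, False, sources,
                           labels, n_in, n_out)


def run_gbm_constrained(h_m: AbsorbedEnergyMap, mu_s_prime,
                        config: InversionConfig | None = None,
                        marker: MarkerPrior | None = None,
                        sources: SourceSet | None = None,
                        labels: RegionLabelMap | None = None,
                        n_in: float = 1.33, n_out: float = 1.0) -> InversionResult:
    """Equality-constrained GBM: mu_a at the marker pixels is held exactly at
    the known value and the minimization runs over the remaining pixels
    (reduced space, mathematically equivalent to the linear equality
    constraint Aeq x = beq on the marker set)."""
    config = config or InversionConfig(method="GBM_CONSTRAINED")
    if marker is None:
        raise ValueError("constrained GBM requires a marker prior")
    return _run_gbm_common(h_m, mu_s_prime, config, marker, True, sources,
                           labels, n_in, n_out)
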