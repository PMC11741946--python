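"""Projected limited-memory quasi-Newton minimizer.

A compact L-BFGS (two-loop recursion) with Armijo backtracking, written so
that the iterate can be projected after every trial step. The projection
is how the inversion algorithms impose their side conditions: clamping
negative absorption values to zero and resetting the fluence-marker pixels
to their known value between iterations — operations that a black-box
optimizer interface does not allow mid-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

Objective = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class MinimizeResult:
    x: np.ndarray
    f: float
    grad: np.ndarray
    n_iter: int
    converged: bool
    reason: str
    f_trace: list[float] = field(default_factory=list)
    x_trace_hook_values: list = field(default_factory=list)


def _two_loop(g: np.ndarray, s_list: list, y_list: list, rho_list: list) -> np.ndarray:
    q = g.copy()
    alphas = []
    for s, y, rho in zip(reversed(s_list), reversed(y_list), reversed(rho_list)):
        a = rho * (s @ q)
        alphas.append(a)
        q -= a * y
    if s_list:
        s, y = s_list[-1], y_list[-1]
        q *= (s @ y) / (y @ y)  # Barzilai-Borwein scaling of the seed Hessian
    for (s, y, rho), a in zip(zip(s_list, y_list, rho_list), reversed(alphas)):
        b = rho * (y @ q)
        q += (a - b) * s
    return -q


def minimize_lbfgs(
    fun: Objective,
    x0: np.ndarray,
    max_iter: int = 700,
    memory: int = 10,
    tol_grad: float = 1e-9,
    tol_f: float | None = None,
    c1: float = 1e-4,
    max_linesearch: int = 30,
    project: Callable[[np.ndarray], np.ndarray] | None = None,
    post_step: Callable[[np.ndarray], np.ndarray] | None = None,
    iterate_hook: Callable[[np.ndarray, float], object] | None = None,
) -> MinimizeResult:
    """Minimize ``fun`` (returning value and gradient) from ``x0``.

    ``project``, if given, is applied to every trial point before it is
    evaluated, so the objective only ever sees admissible iterates.
    ``post_step`` is applied once per accepted step, after the line search
    — this is where side conditions that deliberately override the
    optimizer's update (e.g. resetting known-marker pixels) live; if it
    changes the iterate, the objective is re-evaluated there, so the
    recorded objective trace may transiently increase. ``tol_f`` stops when
    the objective value falls at or below it. ``iterate_hook`` is called
    with each accepted iterate (for tracing). One "iteration" is one
    accepted quasi-Newton step.
    """
    x = x0.astype(float).copy()
    if project is not None:
        x = project(x)
    if post_step is not None:
        x = post_step(x)
    f, g = fun(x)

    s_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []
    rho_list: list[float] = []
    result = MinimizeResult(x, f, g, 0, False, "max_iter")

    for k in range(max_iter):
        d = _two_loop(g, s_list, y_list, rho_list)
        gtd = g @ d
        if gtd >= 0:  # not a descent direction; restart with steepest descent
            s_list, y_list, rho_list = [], [], []
            d = -g
            gtd = g @ d
            if gtd >= 0:
                result.reason = "stationary"
                result.converged = True
                break
        # unit quasi-Newton step once curvature information exists
        alpha = 1.0 if s_list else min(1.0, 1.0 / max(np.linalg.norm(g), 1e-30))
        accepted = False
        for _ in range(max_linesearch):
            x_t = x + alpha * d
            if project is not None:
                x_t = project(x_t)
            f_t, g_t = fun(x_t)
            # Armijo sufficient decrease along the projected arc
            if f_t <= f + c1 * (g @ (x_t - x)):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            result.reason = "line_search_failed"
            result.converged = True
            break

        if post_step is not None:
            x_r = post_step(x_t)
            if not np.array_equal(x_r, x_t):
                x_t = x_r
                f_t, g_t = fun(x_t)

        s = x_t - x
        y = g_t - g
        sy = s @ y
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            s_list.append(s)
            y_list.append(y)
            rho_list.append(1.0 / sy)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)
                rho_list.pop(0)

        x, f, g = x_t, f_t, g_t
        result.n_iter = k + 1
        result.f_trace.append(f)
        if iterate_hook is not None:
            result.x_trace_hook_values.append(iterate_hook(x, f))

        # first-order optimality on the projected gradient step
        if project is not None:
            opt = np.max(np.abs(project(x - g) - x))
        else:
            opt = np.max(np.abs(g))
        if opt <= tol_grad:
            result.reason = "tol_optimality"
            result.converged = True
            break
        if tol_f is not None and f <= tol_f:
            result.reason = "tol_error"
            result.converged = True
            break

    result.x, result.f, result.grad = x, f, g
    return result
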