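"""B-spline basis functions on a uniform grid.

These are the building blocks of the learnable edge activations: an edge
activation is a linear combination of ``G + k`` B-spline basis functions
(``G`` grid intervals, polynomial order ``k``) plus an optional smooth
residual term.  Everything here is plain NumPy, vectorized over arbitrary
batches of evaluation points, and returns both values and first derivatives
so the network can be trained by exact backpropagation.

Conventions
-----------
* The *grid* is the vector of ``G + 1`` equispaced break points spanning
  ``grid_range``.  It is extended by ``k`` affinely-continued knots on each
  side, giving ``G + 2k + 1`` knots and ``G + k`` basis functions.
* Inputs beyond the *extended* knot span are handled by linear extrapolation
  of the outermost polynomial piece (value and slope taken at the span edge),
  so standardized inputs that stray far outside the grid still produce
  finite, differentiable activations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "make_grid",
    "extend_grid",
    "bspline_basis",
    "bspline_basis_and_deriv",
    "n_basis",
]


def n_basis(grid_size: int, order: int) -> int:
    """Number of B-spline basis functions for ``G`` intervals and order ``k``."""
    return grid_size + order


def make_grid(grid_size: int, grid_range: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Equispaced break points: ``G + 1`` values from ``lo`` to ``hi``."""
    lo, hi = float(grid_range[0]), float(grid_range[1])
    if not lo < hi:
        raise ValueError(f"grid_range must satisfy lo < hi, got ({lo}, {hi})")
    if grid_size < 1:
        raise ValueError(f"grid_size must be >= 1, got {grid_size}")
    return np.linspace(lo, hi, grid_size + 1)


def extend_grid(grid: np.ndarray, order: int) -> np.ndarray:
    """Pad the break-point vector with ``order`` affinely-extended knots per side."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be a 1-D vector of at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    h = float(grid[1] - grid[0])
    left = grid[0] - h * np.arange(order, 0, -1)
    right = grid[-1] + h * np.arange(1, order + 1)
    return np.concatenate([left, grid, right])


def _basis_interior(x: np.ndarray, knots: np.ndarray, order: int) -> np.ndarray:
    """Cox-de Boor recursion for points inside the knot span.

    ``x``: flat array of points, all within ``[knots[0], knots[-1]]``.
    Returns an array of shape ``(x.size, n_knots - order - 1)``.
    """
    t = knots
    # order-0: indicator of the half-open interval; last interval closed.
    b = (x[:, None] >= t[None, :-1]) & (x[:, None] < t[None, 1:])
    b = b.astype(x.dtype)
    b[:, -1] = np.where((x >= t[-2]) & (x <= t[-1]), 1.0, b[:, -1])
    for m in range(1, order + 1):
        d_left = t[m:-1] - t[: -m - 1]
        d_right = t[m + 1 :] - t[1:-m]
        left = (x[:, None] - t[None, : -m - 1]) / d_left * b[:, :-1]
        right = (t[None, m + 1 :] - x[:, None]) / d_right * b[:, 1:]
        b = left + right
    return b


def _deriv_from_lower(b_lower: np.ndarray, knots: np.ndarray, order: int) -> np.ndarray:
    """First derivative of order-``k`` bases from the order-``k-1`` bases."""
    t = knots
    k = order
    if k == 0:
        return np.zeros((b_lower.shape[0], b_lower.shape[1] - 1), dtype=b_lower.dtype)
    d1 = t[k:-1] - t[: -k - 1]
    d2 = t[k + 1 :] - t[1:-k]
    return k * (b_lower[:, :-1] / d1 - b_lower[:, 1:] / d2)


def _banded_uniform(xf: np.ndarray, lo_ext: float, h: float, n_intervals: int, order: int):
    """The ``k + 1`` nonzero basis values (and derivatives) per point.

    Points must lie inside the extended knot span.  Returns
    ``(j0, values, derivs)`` where ``j0`` is each point's knot interval and
    the banded arrays have shape ``(n, k + 1)`` covering basis indices
    ``j0 - k .. j0`` over the extended knots.  Exploits knot uniformity: the
    recursion depends only on the fractional position within the interval.
    """
    j0 = np.floor((xf - lo_ext) / h).astype(np.int64)
    np.clip(j0, 0, n_intervals - 1, out=j0)
    u = (xf - lo_ext) / h - j0
    b = np.ones((xf.size, 1))
    prev = b
    for d in range(1, order + 1):
        prev = b
        new = np.empty((xf.size, d + 1))
        for i in range(d + 1):
            if i == 0:
                new[:, 0] = (1.0 - u) / d * prev[:, 0]
            elif i == d:
                new[:, d] = (u + d - i) / d * prev[:, d - 1]
            else:
                new[:, i] = (u + d - i) / d * prev[:, i - 1] + (i + 1 - u) / d * prev[:, i]
        b = new
    if order == 0:
        der = np.zeros_like(b)
    else:
        der = np.empty_like(b)
        der[:, 0] = -prev[:, 0] / h
        der[:, order] = prev[:, order - 1] / h
        for i in range(1, order):
            der[:, i] = (prev[:, i - 1] - prev[:, i]) / h
    return j0, b, der


def _scatter_banded(j0: np.ndarray, banded: np.ndarray, order: int, nb: int) -> np.ndarray:
    """Place banded values into the dense ``(n, nb)`` basis matrix.

    Band entries that refer to phantom functions outside the tracked set
    (points in the padded knot zones) are dropped, matching the dense
    recursion's semantics.
    """
    k = order
    n = banded.shape[0]
    dense = np.zeros((n, nb))
    flat = dense.reshape(-1)
    base = np.arange(n) * nb + (j0 - k)
    for i in range(k + 1):
        cols = j0 - k + i
        if cols.min() >= 0 and cols.max() < nb:
            flat[base + i] = banded[:, i]
        else:
            m = (cols >= 0) & (cols < nb)
            flat[base[m] + i] = banded[m, i]
    return dense


def bspline_basis_and_deriv(
    x: np.ndarray | float,
    grid: np.ndarray,
    order: int,
    need_deriv: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Values and first derivatives of all basis functions at ``x``.

    Parameters
    ----------
    x : scalar or array
        Evaluation points; any shape.  Must be finite.
    grid : 1-D array
        The ``G + 1`` break points (un-extended).
    order : int
        Polynomial order ``k >= 0``.
    need_deriv : bool
        When False the dense derivative matrix is not materialized (returned
        as None); skipping it roughly halves the cost on wide layers.

    Returns
    -------
    values, derivs : arrays of shape ``x.shape + (G + k,)``
    """
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError("bspline_basis: evaluation points must be finite")
    grid = np.asarray(grid, dtype=float)
    shape = x_arr.shape
    xf = x_arr.ravel()

    steps = np.diff(grid)
    if steps.size and steps[0] > 0 and np.allclose(steps, steps[0], rtol=1e-9, atol=0):
        # uniform grid: banded evaluation, then scatter to dense
        h = float(steps[0])
        k = order
        if k < 0:
            raise ValueError(f"order must be >= 0, got {order}")
        nb = grid.size - 1 + k
        lo_ext = float(grid[0]) - k * h
        hi_ext = float(grid[-1]) + k * h
        n_intervals = grid.size - 1 + 2 * k
        inside = (xf >= lo_ext) & (xf <= hi_ext)
        xc = np.clip(xf, lo_ext, hi_ext)
        j0, bvals, bder = _banded_uniform(xc, lo_ext, h, n_intervals, k)
        if not np.all(inside):
            out = ~inside
            delta = (xf[out] - xc[out])[:, None]
            bvals[out] += delta * bder[out]
        vals = _scatter_banded(j0, bvals, k, nb)
        der = _scatter_banded(j0, bder, k, nb) if need_deriv else None
        return (
            vals.reshape(shape + (nb,)),
            der.reshape(shape + (nb,)) if der is not None else None,
        )

    knots = extend_grid(grid, order)

    lo, hi = knots[0], knots[-1]
    inside = (xf >= lo) & (xf <= hi)
    xc = np.clip(xf, lo, hi)

    if order == 0:
        vals = _basis_interior(xc, knots, 0)
        der = np.zeros_like(vals)
        nb = vals.shape[1]
        return vals.reshape(shape + (nb,)), der.reshape(shape + (nb,))

    b_lower = _basis_interior(xc, knots, order - 1)
    # one more recursion step for the order-k values
    m = order
    t = knots
    d_left = t[m:-1] - t[: -m - 1]
    d_right = t[m + 1 :] - t[1:-m]
    vals = (xc[:, None] - t[None, : -m - 1]) / d_left * b_lower[:, :-1] + (
        t[None, m + 1 :] - xc[:, None]
    ) / d_right * b_lower[:, 1:]
    der = _deriv_from_lower(b_lower, knots, order)

    if not np.all(inside):
        # linear extrapolation of the edge piece: B(x) = B(xe) + (x - xe) B'(xe)
        out = ~inside
        delta = (xf[out] - xc[out])[:, None]
        vals[out] = vals[out] + delta * der[out]
        # derivative stays at the edge slope

    nb = vals.shape[1]
    return vals.reshape(shape + (nb,)), der.reshape(shape + (nb,))


def bspline_basis(x: np.ndarray | float, grid: np.ndarray, order: int) -> np.ndarray:
    """Values of all ``G + k`` basis functions of ``order`` at ``x``."""
    return bspline_basis_and_deriv(x, grid, order)[0]
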