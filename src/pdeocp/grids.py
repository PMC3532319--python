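"""Uniform spatial grids, quadrature and finite-difference operators.

Fields are stored nodally, endpoints included.  1D fields are arrays of
length ``n`` ordered by increasing coordinate; 2D fields are stored
row-major with the second coordinate (xi2) as the slow axis, i.e.
``field.reshape(n2, n1)[i2, i1]`` is the value at ``(xi1[i1], xi2[i2])``.

Zero-flux (homogeneous Neumann) boundaries are closed by ghost-point
elimination with even reflection; a Robin condition du/dxi = r at the
right endpoint is closed by the shifted reflection ``u[n+k] = u[n-k] +
2*k*h*r``, which reduces to plain reflection when r = 0.  With these
closures the weighted Laplacian ``diag(w) @ A`` is symmetric and
annihilates constants, so the discrete integral of a diffusing field is
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialGrid1D",
    "SpatialGrid2D",
    "DiffOperator",
    "build_grid_1d",
    "build_grid_2d",
    "laplacian_1d",
    "laplacian_2d",
    "chemotactic_flux_divergence",
    "inner_product",
]


@dataclass(frozen=True)
class SpatialGrid1D:
    """Uniform 1D grid on [0, L] with trapezoidal quadrature weights."""

    L: float
    n_nodes: int
    nodes: np.ndarray = field(repr=False)
    h: float = 0.0
    quad_weights: np.ndarray = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int]:
        return (self.n_nodes,)


@dataclass(frozen=True)
class SpatialGrid2D:
    """Uniform tensor-product grid on [0, L1] x [0, L2].

    ``actuator_band_map`` assigns every node to one of ``n_bands`` equal
    width vertical strips in xi1 (band k covers xi1 in
    [k*L1/n_bands, (k+1)*L1/n_bands)); the right domain edge belongs to
    the last band.
    """

    L1: float
    L2: float
    n1: int
    n2: int
    xi1: np.ndarray = field(repr=False)
    xi2: np.ndarray = field(repr=False)
    h1: float = 0.0
    h2: float = 0.0
    quad_weights: np.ndarray = field(default=None, repr=False)
    n_bands: int = 6
    actuator_band_map: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.n1 * self.n2

    @property
    def shape(self) -> tuple[int]:
        return (self.n_nodes,)

    def band_indicators(self) -> np.ndarray:
        """(n_nodes, n_bands) 0/1 matrix of actuator footprints."""
        out = np.zeros((self.n_nodes, self.n_bands))
        out[np.arange(self.n_nodes), self.actuator_band_map] = 1.0
        return out


@dataclass(frozen=True)
class DiffOperator:
    """Affine nodal differential operator ``x -> A @ x + b * r``.

    ``A`` carries the stencil with homogeneous boundary closure and ``b``
    the inhomogeneous boundary contribution, scaled at application time
    by the boundary datum ``r`` (e.g. the Robin mismatch u(t) - x(L)).
    """

    matrix: np.ndarray = field(repr=False)
    boundary_vector: np.ndarray = field(repr=False)
    order: int = 2
    bc: str = "neumann"

    def apply(self, x: np.ndarray, r: float = 0.0) -> np.ndarray:
        out = self.matrix @ x
        if r != 0.0:
            out = out + r * self.boundary_vector
        return out


def build_grid_1d(L: float, n_nodes: int) -> SpatialGrid1D:
    """Uniform grid on [0, L] with endpoints and trapezoidal weights."""
    if n_nodes < 3:
        raise ValueError(f"need at least 3 nodes, got {n_nodes}")
    if L <= 0:
        raise ValueError(f"domain length must be positive, got {L}")
    nodes = np.linspace(0.0, L, n_nodes)
    h = L / (n_nodes - 1)
    w = np.full(n_nodes, h)
    w[0] = w[-1] = h / 2.0
    return SpatialGrid1D(L=float(L), n_nodes=n_nodes, nodes=nodes, h=h, quad_weights=w)


def build_grid_2d(
    L1: float = 200.0,
    L2: float = 200.0,
    n1: int = 49,
    n2: int = 49,
    n_bands: int = 6,
) -> SpatialGrid2D:
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 nodes per axis")
    if L1 <= 0 or L2 <= 0:
        raise ValueError("domain extents must be positive")
    xi1 = np.linspace(0.0, L1, n1)
    xi2 = np.linspace(0.0, L2, n2)
    h1 = L1 / (n1 - 1)
    h2 = L2 / (n2 - 1)
    w1 = np.full(n1, h1)
    w1[0] = w1[-1] = h1 / 2.0
    w2 = np.full(n2, h2)
    w2[0] = w2[-1] = h2 / 2.0
    w = np.outer(w2, w1).ravel()
    # vertical strips in xi1, equal width; right edge joins the last band
    band_of_xi1 = np.minimum((xi1 / (L1 / n_bands)).astype(int), n_bands - 1)
    band_map = np.tile(band_of_xi1, n2)
    return SpatialGrid2D(
        L1=float(L1), L2=float(L2), n1=n1, n2=n2, xi1=xi1, xi2=xi2,
        h1=h1, h2=h2, quad_weights=w, n_bands=n_bands, actuator_band_map=band_map,
    )


def _laplacian_matrix_1d(n: int, h: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflection-closed 1D Laplacian and right-edge Robin injection vector."""
    A = np.zeros((n, n))
    if order == 2:
        for j in range(1, n - 1):
            A[j, j - 1 : j + 2] = [1.0, -2.0, 1.0]
        # ghost x[-1] = x[1] (+ shift for inhomogeneous flux)
        A[0, 0], A[0, 1] = -2.0, 2.0
        A[-1, -1], A[-1, -2] = -2.0, 2.0
        A /= h * h
        b = np.zeros(n)
        b[-1] = 2.0 / h
    elif order == 4:
        c = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / 12.0
        for j in range(2, n - 2):
            A[j, j - 2 : j + 3] = c
        # node 1: ghost x[-1] = x[1]
        A[1, 0:4] = np.array([16.0, -31.0, 16.0, -1.0]) / 12.0
        # node 0: ghosts x[-1] = x[1], x[-2] = x[2]
        A[0, 0:3] = np.array([-30.0, 32.0, -2.0]) / 12.0
        A[n - 2, n - 4 : n] = np.array([-1.0, 16.0, -31.0, 16.0]) / 12.0
        A[n - 1, n - 3 : n] = np.array([-2.0, 32.0, -30.0]) / 12.0
        A /= h * h
        # right-edge ghosts with slope r: x[n+k] = x[n-k] + 2*k*h*r
        b = np.zeros(n)
        b[-1] = 7.0 / (3.0 * h)  # (16*2hr - 4hr)/(12 h^2)
        b[-2] = -1.0 / (6.0 * h)  # (-1)*2hr/(12 h^2)
    else:
        raise ValueError(f"unsupported stencil order {order} (use 2 or 4)")
    return A, b


def _first_derivative_matrix_1d(n: int, h: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Reflection-closed first derivative; boundary vector carries the
    right-edge slope datum r (so rows at/near xi = L return exactly r
    there when applied with the shifted-reflection ghosts)."""
    D = np.zeros((n, n))
    b = np.zeros(n)
    if order == 2:
        for j in range(1, n - 1):
            D[j, j - 1] = -1.0 / (2.0 * h)
            D[j, j + 1] = 1.0 / (2.0 * h)
        # ghosts: even reflection left (slope 0), shifted reflection right
        b[n - 1] = 1.0
    elif order == 4:
        c = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / (12.0 * h)
        for j in range(2, n - 2):
            D[j, j - 2 : j + 3] = c
        D[1, 0:4] = np.array([-8.0, 1.0, 8.0, -1.0]) / (12.0 * h)
        # row 0 is exactly zero (even reflection), row n-1 exactly r
        D[n - 2, n - 4 : n] = np.array([1.0, -8.0, -1.0, 8.0]) / (12.0 * h)
        b[n - 2] = -1.0 / 6.0
        b[n - 1] = 1.0
    else:
        raise ValueError(f"unsupported stencil order {order} (use 2 or 4)")
    return D, b


def first_derivative_1d(grid: SpatialGrid1D, order: int = 4, bc: str = "neumann") -> DiffOperator:
    """First-derivative operator with zero-slope closure at xi = 0.

    With ``bc='robin-right'``, ``apply(x, r)`` realises dx/dxi(L) = r
    (the boundary rows blend in the slope datum); with ``bc='neumann'``
    both walls are zero-slope.
    """
    if bc not in ("neumann", "robin-right"):
        raise ValueError(f"unsupported boundary treatment {bc!r}")
    D, b = _first_derivative_matrix_1d(grid.n_nodes, grid.h, order)
    if bc == "neumann":
        b = np.zeros(grid.n_nodes)
    return DiffOperator(matrix=D, boundary_vector=b, order=order, bc=bc)


def laplacian_1d(grid: SpatialGrid1D, order: int = 4, bc: str = "neumann") -> DiffOperator:
    """Second-derivative operator with zero-flux closure at both ends.

    ``bc='robin-right'`` keeps the zero-flux closure at xi = 0 but makes
    the right-edge closure inhomogeneous: ``apply(x, r)`` then realises
    du/dxi(L) = r.  With ``bc='neumann'`` the boundary vector is zero.
    """
    if bc not in ("neumann", "robin-right"):
        raise ValueError(f"unsupported boundary treatment {bc!r}")
    A, b = _laplacian_matrix_1d(grid.n_nodes, grid.h, order)
    if bc == "neumann":
        b = np.zeros(grid.n_nodes)
    return DiffOperator(matrix=A, boundary_vector=b, order=order, bc=bc)


def laplacian_2d(grid: SpatialGrid2D, order: int = 2):
    """Sparse 5-point (or tensor 4th-order) Laplacian with zero-flux edges.

    Returns a ``scipy.sparse`` matrix acting on flattened fields
    (xi2-major ordering).
    """
    from scipy import sparse

    A1, _ = _laplacian_matrix_1d(grid.n1, grid.h1, order)
    A2, _ = _laplacian_matrix_1d(grid.n2, grid.h2, order)
    I1 = sparse.identity(grid.n1, format="csr")
    I2 = sparse.identity(grid.n2, format="csr")
    return (sparse.kron(I2, sparse.csr_matrix(A1)) + sparse.kron(sparse.csr_matrix(A2), I1)).tocsr()


def chemotactic_flux_divergence(
    grid: SpatialGrid1D, z: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """d/dxi [ z/(1+c)^2 * dc/dxi ] in conservative flux-difference form.

    Fluxes are evaluated at half-nodes from arithmetic means of z and c;
    the chemotactic flux vanishes at both endpoints, so the quadrature
    integral of the result is exactly zero (discrete mass conservation).
    """
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    if z.shape != grid.shape or c.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    h = grid.h
    zm = 0.5 * (z[1:] + z[:-1])
    cm = 0.5 * (c[1:] + c[:-1])
    flux = zm / (1.0 + cm) ** 2 * (c[1:] - c[:-1]) / h  # at half-nodes
    out = np.empty_like(z)
    out[1:-1] = (flux[1:] - flux[:-1]) / h
    # boundary cells have width h/2 under trapezoidal weighting
    out[0] = flux[0] / (h / 2.0)
    out[-1] = -flux[-1] / (h / 2.0)
    return out


def inner_product(f: np.ndarray, g: np.ndarray, grid) -> float:
    """Quadrature approximation of the L2 pairing int_V f g dxi."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != grid.shape or g.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    return float(np.dot(grid.quad_weights, f * g))
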