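"""Extracellular metal concentration field.

Two modes mirror the two experimental regimes:

* ``homogeneous`` — the population is immersed in a well-mixed bath at a
  fixed concentration; the field is constant in space and time.
* ``central_source`` — metal solution is continuously poured at the centre
  of the dish and diffuses outward.  The pour is modelled as a Dirichlet
  clamp: grid nodes within ``source_radius`` of the centre are held at
  ``source_conc`` while the rest of the field evolves by explicit
  finite-difference diffusion (5-point Laplacian, FTCS).

The domain is a square of side ``domain_size`` centred on the origin.  The
explicit scheme requires dt <= dx^2 / (4 D); violating steps are refused
rather than silently shortened.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, OutOfDomainError, StabilityError
from .scenarios import Boundary, FieldMode, ScenarioConfig


@dataclass(frozen=True)
class MetalField:
    """Discretised 2D metal concentration (ug/L) over a square domain."""

    mode: FieldMode
    grid: np.ndarray          # (n, n) concentrations, ug/L
    dx: float                 # um
    D_coeff: float            # um^2/min
    source_radius: float      # um
    source_conc: float        # ug/L
    boundary: Boundary = Boundary.ZERO_FLUX
    source_on: bool = True

    @property
    def n_nodes(self) -> int:
        return self.grid.shape[0]

    @property
    def half_extent(self) -> float:
        """Half the domain side; coordinates run in [-half, +half] um."""
        return 0.5 * (self.n_nodes - 1) * self.dx

    @property
    def node_coords(self) -> np.ndarray:
        """1D coordinates of the grid nodes along either axis, um."""
        return -self.half_extent + self.dx * np.arange(self.n_nodes)

    @property
    def stable_dt(self) -> float:
        """Largest admissible explicit time step, dx^2/(4 D), min."""
        if self.D_coeff == 0:
            return np.inf
        return self.dx**2 / (4.0 * self.D_coeff)

    @property
    def total_mass(self) -> float:
        """Integral of concentration over the domain, ug/L * um^2."""
        return float(self.grid.sum() * self.dx**2)

    def without_source(self) -> "MetalField":
        """Copy with the central pour switched off (for conservation runs)."""
        return replace(self, source_on=False)


def _source_mask(n: int, dx: float, radius: float) -> np.ndarray:
    half = 0.5 * (n - 1) * dx
    coords = -half + dx * np.arange(n)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return xx**2 + yy**2 <= radius**2


def init_field(config: ScenarioConfig) -> MetalField:
    """Build the initial field for a scenario.

    Homogeneous mode fills the grid with the scenario concentration; the
    central-source mode starts from a zero field with the central disk
    clamped at the pour concentration."""
    fp = config.field_params
    n = int(round(fp.domain_size / fp.dx)) + 1
    if n < 3:
        raise ConfigError("domain must span at least 3 grid nodes")
    if fp.mode is FieldMode.HOMOGENEOUS:
        grid = np.full((n, n), float(config.metal_conc))
    else:
        grid = np.zeros((n, n))
        grid[_source_mask(n, fp.dx, fp.source_radius)] = config.metal_conc
    return MetalField(
        mode=fp.mode,
        grid=grid,
        dx=fp.dx,
        D_coeff=fp.D_coeff,
        source_radius=fp.source_radius,
        source_conc=float(config.metal_conc),
        boundary=fp.boundary,
    )


def step_field(field: MetalField, dt: float) -> MetalField:
    """Advance the field by one explicit diffusion step of length ``dt`` min.

    Homogeneous fields are returned unchanged.  In central-source mode the
    update is one FTCS step with the chosen boundary handling, after which
    the source disk (if on) is re-clamped to the pour concentration.
    Raises :class:`StabilityError` when dt exceeds dx^2/(4 D)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if field.mode is FieldMode.HOMOGENEOUS:
        return field
    if dt > field.stable_dt * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt:g} min violates the explicit stability bound "
            f"dx^2/(4D)={field.stable_dt:g} min; use substeps"
        )
    grid = field.grid
    if field.boundary is Boundary.ZERO_FLUX:
        padded = np.pad(grid, 1, mode="edge")          # reflecting ghosts
    else:
        padded = np.pad(grid, 1, mode="constant")      # absorbing: 0 outside
    lap = (
        padded[:-2, 1:-1] + padded[2:, 1:-1]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * grid
    ) / field.dx**2
    new = grid + dt * field.D_coeff * lap
    if field.source_on:
        mask = _source_mask(field.n_nodes, field.dx, field.source_radius)
        new[mask] = field.source_conc
    return replace(field, grid=new)


def advance_field(field: MetalField, dt: float, safety: float = 0.9) -> MetalField:
    """Advance by ``dt`` min using as many stable substeps as needed."""
    if field.mode is FieldMode.HOMOGENEOUS or field.D_coeff == 0:
        return field
    n_sub = max(1, int(np.ceil(dt / (safety * field.stable_dt))))
    sub = dt / n_sub
    for _ in range(n_sub):
        field = step_field(field, sub)
    return field


def concentration_at(field: MetalField, x, y):
    """Bilinear interpolation of the field at point(s) (x, y) in um.

    Accepts scalars or equal-shaped arrays; raises
    :class:`OutOfDomainError` if any point lies outside the domain."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    half = field.half_extent
    tol = 1e-9 * max(half, 1.0)
    if np.any(np.abs(x) > half + tol) or np.any(np.abs(y) > half + tol):
        raise OutOfDomainError(
            f"query outside the [-{half:g}, {half:g}] um domain"
        )
    if field.mode is FieldMode.HOMOGENEOUS:
        bath = float(field.grid.flat[0])
        out = np.full(np.broadcast(x, y).shape, bath)
        return float(out) if out.ndim == 0 else out
    # fractional node indices; clip so edge points use the last cell
    fx = np.clip((x + half) / field.dx, 0.0, field.n_nodes - 1.0)
    fy = np.clip((y + half) / field.dx, 0.0, field.n_nodes - 1.0)
    i0 = np.minimum(fx.astype(int), field.n_nodes - 2)
    j0 = np.minimum(fy.astype(int), field.n_nodes - 2)
    tx = fx - i0
    ty = fy - j0
    g = field.grid
    out = (
        g[i0, j0] * (1 - tx) * (1 - ty)
        + g[i0 + 1, j0] * tx * (1 - ty)
        + g[i0, j0 + 1] * (1 - tx) * ty
        + g[i0 + 1, j0 + 1] * tx * ty
    )
    return float(out) if out.ndim == 0 else out


def radial_profile(field: MetalField, n_bins: int | None = None):
    """Azimuthally averaged concentration vs. distance from the centre.

    Returns (bin centres um, mean concentration per bin); bin width = dx."""
    coords = field.node_coords
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    r = np.hypot(xx, yy).ravel()
    c = field.grid.ravel()
    if n_bins is None:
        n_bins = field.n_nodes // 2
    edges = np.linspace(0.0, field.half_extent, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=c, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    valid = counts > 0
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres[valid], sums[valid] / counts[valid]
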