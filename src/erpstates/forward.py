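"""Forward model: best-fitting sphere, 3-shell spherical head model, source grid,
and the dipole lead field via a truncated Legendre series.

The head is modelled as three concentric spherical shells (brain, skull, scalp)
with piecewise-constant conductivity.  For each spherical-harmonic degree *n*
the radial boundary-value problem is a small linear system; its solution gives
the per-degree attenuation factor of the skull layer, and the surface potential
of a dipole follows from the standard Legendre expansion.  Gray matter is
replaced by a spherical shell — the template-anatomy stand-in — so node
positions are nominal, not anatomical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .types import ElectrodeMontage

logger = logging.getLogger("erpstates")


def fit_sphere(montage: ElectrodeMontage) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; electrodes are radially projected onto it.

    The fitted (center, radius) is stored on the montage and the montage
    positions are replaced by their radial projections.
    """
    pos = montage.positions
    if pos.shape[0] < 4:
        raise ValueError("sphere fit needs at least 4 electrodes")
    centered = pos - pos.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise ValueError("electrodes are coplanar; cannot fit a sphere")
    # algebraic fit: |x|^2 = 2 c·x + (r^2 - |c|^2)
    A = np.hstack([2 * pos, np.ones((pos.shape[0], 1))])
    b = (pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    # Gauss-Newton refinement of the geometric error
    for _ in range(20):
        diff = pos - center
        dist = np.linalg.norm(diff, axis=1)
        resid = dist - radius
        J = np.hstack([-diff / dist[:, None], -np.ones((pos.shape[0], 1))])
        step, *_ = np.linalg.lstsq(J, -resid, rcond=None)
        center = center + step[:3]
        radius = float(radius + step[3])
        if np.linalg.norm(step) < 1e-12:
            break
    diff = pos - center
    dist = np.linalg.norm(diff, axis=1, keepdims=True)
    montage.positions = center + diff / dist * radius
    montage.fitted_sphere = (center, radius)
    return center, radius


@dataclass
class HeadModel:
    """3-shell spherical conductor (radii in mm, conductivities in S/m)."""

    center: np.ndarray
    radii: tuple[float, float, float]  # brain, skull outer, scalp
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        r = self.radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be strictly increasing")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @classmethod
    def from_montage(
        cls,
        montage: ElectrodeMontage,
        ratios: tuple[float, float, float] = (0.87, 0.92, 1.0),
        conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33),
    ) -> "HeadModel":
        """Head model whose scalp sphere is the montage's fitted sphere."""
        if montage.fitted_sphere is None:
            fit_sphere(montage)
        center, radius = montage.fitted_sphere
        return cls(center, tuple(radius * r for r in ratios), conductivities)


@dataclass
class SourceGrid:
    """Regular cubic lattice of source nodes inside a spherical shell."""

    positions: np.ndarray  # (n_nodes, 3) mm, head frame
    spacing: float  # mm
    connection_radius: float  # mm
    adjacency: "object" = None  # scipy.sparse boolean (n, n), symmetric

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]


def _shell_lattice(center: np.ndarray, spacing: float, r_outer: float, r_inner: float) -> np.ndarray:
    m = int(np.floor(r_outer / spacing))
    ax = np.arange(-m, m + 1) * spacing
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    r = np.linalg.norm(pts, axis=1)
    keep = (r >= r_inner) & (r <= r_outer)
    return pts[keep] + center


def build_grid(
    head: HeadModel,
    spacing: float = 6.0,
    shell: tuple[float, float] = (0.45, 0.95),
    target_nodes: int = 3005,
    connection_radius: float = 10.0,
) -> SourceGrid:
    """Cubic lattice ∩ spherical shell, auto-scaled to ≈ ``target_nodes`` nodes.

    The shell (fractions of an effective radius) stands in for gray matter; the
    effective radius is scaled so the node count lands within 5% of the target
    while staying strictly inside the brain shell.
    """
    from scipy import sparse

    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > 2 * head.brain_radius:
        raise ValueError("spacing exceeds the brain diameter; grid would be empty")

    lo, hi = 2 * spacing, head.brain_radius / shell[1] * 0.999
    best = None
    for r_eff in np.linspace(lo, hi, 400):
        pts = _shell_lattice(np.zeros(3), spacing, shell[1] * r_eff, shell[0] * r_eff)
        err = abs(pts.shape[0] - target_nodes)
        if best is None or err < best[0]:
            best = (err, r_eff, pts)
        if pts.shape[0] > 1.3 * target_nodes:
            break
    err, r_eff, pts = best
    if pts.shape[0] == 0:
        raise ValueError("empty source grid")
    if err > 0.05 * target_nodes:
        logger.warning(
            "grid has %d nodes; more than 5%% away from target %d", pts.shape[0], target_nodes
        )
    positions = pts + head.center
    tree = cKDTree(positions)
    pairs = tree.query_pairs(connection_radius, output_type="ndarray")
    n = positions.shape[0]
    if pairs.size:
        ij = np.vstack([pairs, pairs[:, ::-1]])
        adj = sparse.csr_matrix(
            (np.ones(ij.shape[0], bool), (ij[:, 0], ij[:, 1])), shape=(n, n)
        )
    else:
        adj = sparse.csr_matrix((n, n), dtype=bool)
    return SourceGrid(positions=positions, spacing=spacing, connection_radius=connection_radius, adjacency=adj)


@dataclass
class LeadField:
    """Forward gain: channels × (3 × nodes), average-referenced, µV per unit moment."""

    gain: np.ndarray  # (n_channels, 3 * n_nodes); node-major column blocks
    n_nodes: int
    labels: list[str] | None = None

    @property
    def blocks(self) -> np.ndarray:
        """Gain reshaped to (n_channels, n_nodes, 3)."""
        return self.gain.reshape(self.gain.shape[0], self.n_nodes, 3)


def _shell_attenuation(n_arr: np.ndarray, head: HeadModel) -> np.ndarray:
    """Per-degree factor B3(n): surface coefficient relative to the homogeneous sphere.

    Solves, for each degree n, the 4×4 radial boundary-value system (radii
    scaled by the scalp radius so powers stay well-conditioned).  Equal
    conductivities give exactly 1 for every degree.
    """
    s1, s2, s3 = head.conductivities
    R = head.radii[2]
    r1, r2 = head.radii[0] / R, head.radii[1] / R
    out = np.empty(len(n_arr))
    for i, n in enumerate(n_arr):
        k = (n + 1.0) / n  # A3 = k * B3 at unit outer radius (insulating exterior)
        A = np.array(
            [
                [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0],
                [
                    s1 * n * r1 ** (n - 1),
                    -s2 * n * r1 ** (n - 1),
                    s2 * (n + 1) * r1 ** -(n + 2),
                    0.0,
                ],
                [0.0, r2**n, r2 ** -(n + 1), -(k * r2**n + r2 ** -(n + 1))],
                [
                    0.0,
                    s2 * n * r2 ** (n - 1),
                    -s2 * (n + 1) * r2 ** -(n + 2),
                    -s3 * (n * k * r2 ** (n - 1) - (n + 1) * r2 ** -(n + 2)),
                ],
            ]
        )
        rhs = np.array(
            [-(r1 ** -(n + 1)), s1 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0]
        )
        out[i] = np.linalg.solve(A, rhs)[3]
    return out


def dipole_potentials(
    montage: ElectrodeMontage,
    positions: np.ndarray,
    head: HeadModel,
    n_terms: int = 60,
) -> np.ndarray:
    """Surface potentials of unit x/y/z dipoles at ``positions``.

    Returns (n_channels, n_dipoles, 3) in µV per unit dipole moment (µA·mm),
    average-referenced over channels.  Electrodes must lie on the scalp sphere
    (run :func:`fit_sphere` first).
    """
    if montage.fitted_sphere is None:
        raise ValueError("montage must be sphere-fitted before computing the lead field")
    center, radius = montage.fitted_sphere
    R = head.radii[2]
    sigma1 = head.conductivities[0] * 1e-3  # S/m → S/mm so that µA·mm / (S·mm) = µV
    elec = (montage.positions - center) / radius  # unit vectors
    pos = np.atleast_2d(np.asarray(positions, float)) - head.center
    b = np.linalg.norm(pos, axis=1)
    if np.any(b >= head.brain_radius):
        raise ValueError("dipole outside the brain shell")
    ecc = b / head.brain_radius
    if np.any(ecc > 0.95):
        logger.warning(
            "%d dipole(s) at eccentricity > 0.95: Legendre series converges slowly",
            int((ecc > 0.95).sum()),
        )

    n_arr = np.arange(1, n_terms + 1)
    b3 = _shell_attenuation(n_arr, head)

    bhat = np.zeros_like(pos)
    nz = b > 0
    bhat[nz] = pos[nz] / b[nz, None]
    x = np.clip(bhat @ elec.T, -1.0, 1.0)  # (n_dip, n_elec) cos(angle)
    bs = b / R  # scaled source depth

    # Legendre recurrences accumulated over degrees
    p_prev = np.ones_like(x)  # P_0
    p_cur = x.copy()  # P_1
    dp_cur = np.ones_like(x)  # P_1'
    s_rad = np.zeros_like(x)
    s_tan = np.zeros_like(x)
    pw = np.ones_like(b)  # (b/R)^(n-1)
    for n in n_arr:
        w = (2 * n + 1) / n * b3[n - 1] * pw  # (n_dip,)
        s_rad += w[:, None] * n * p_cur
        s_tan += w[:, None] * dp_cur
        pw = pw * bs
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = (n + 1) * p_cur + x * dp_cur
        p_prev, p_cur, dp_cur = p_cur, p_next, dp_next

    scale = 1.0 / (4 * np.pi * sigma1 * R**2)
    out = np.empty((elec.shape[0], pos.shape[0], 3))
    for axis in range(3):
        pr = bhat[:, axis]  # p·b̂ for unit moment along this axis
        pe = elec[:, axis]  # p·r̂_e
        v = s_rad * pr[:, None] + s_tan * (pe[None, :] - x * pr[:, None])
        out[:, :, axis] = scale * v.T
    out -= out.mean(axis=0, keepdims=True)  # average reference
    return out


def leadfield(
    montage: ElectrodeMontage,
    grid: SourceGrid,
    head: HeadModel,
    n_terms: int = 60,
) -> LeadField:
    """Average-referenced forward gain for every grid node (3 orientations each)."""
    pots = dipole_potentials(montage, grid.positions, head, n_terms=n_terms)
    gain = pots.reshape(pots.shape[0], -1)  # node-major: [n0x n0y n0z n1x ...]
    return LeadField(gain=gain, n_nodes=grid.n_nodes, labels=list(montage.labels))
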