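"""Hard-disk Monte Carlo model of the microfibril cross-section.

Cellulose microfibrils seen end-on are modelled as non-penetrating disks
in a periodic square box: a physical (scattering) radius ``R`` and a
larger effective radius ``R_e = R + sep/2`` that encodes the minimum
surface-to-surface separation ``sep`` enforced by an interfacial sheath.
The module provides

* Metropolis equilibration of the packing (random sequential addition
  start, uniform single-disk moves, auto-tuned step, periodic
  minimum-image distances);
* the radial distribution function g(r) and the 2D fluid structure
  factor S(q) via the Hankel (J0) transform of g - 1;
* a tabulated S(phi, x = q R_e) surface with smooth interpolation for
  use inside the scattering model;
* matrix-proximity statistics: the fraction of the non-disk (matrix)
  area lying within a given distance of the nearest disk surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, RectBivariateSpline
from scipy.special import j0

from . import _mc
from .scattering import PHI_CLOSE_PACK

__all__ = [
    "MCSettings",
    "DiskConfiguration",
    "RadialDistribution",
    "StructureFactorTable",
    "ProximityResult",
    "effective_radius",
    "effective_area_fraction",
    "generate_configuration",
    "radial_distribution",
    "structure_factor_from_rdf",
    "direct_structure_factor",
    "build_structure_factor_table",
    "proximity_fractions",
]

_OVERLAP_TOL = 1e-9


def effective_radius(radius: float, min_surface_sep: float) -> float:
    """Non-penetration radius R_e = R + sep/2.

    Two disks of effective radius R_e in contact have surfaces of the
    physical disks separated by exactly ``min_surface_sep``.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if min_surface_sep < 0:
        raise ValueError("minimum surface separation must be non-negative")
    return radius + min_surface_sep / 2.0


def effective_area_fraction(phi_phys: float, radius: float, radius_eff: float) -> float:
    """Effective area fraction phi_eff = phi_phys * (R_e / R)²."""
    if not 0 < phi_phys < 1:
        raise ValueError("physical area fraction must be in (0, 1)")
    if not radius > 0 or radius_eff < radius:
        raise ValueError("need R_e >= R > 0")
    phi_eff = phi_phys * (radius_eff / radius) ** 2
    if phi_eff >= PHI_CLOSE_PACK:
        raise ValueError(
            f"effective area fraction {phi_eff:.4f} exceeds the 2D close-packing "
            f"bound {PHI_CLOSE_PACK:.4f}"
        )
    return phi_eff


@dataclass
class MCSettings:
    """Monte Carlo protocol knobs.

    ``equil_sweeps`` Metropolis sweeps are run before a configuration is
    returned; the displacement half-width delta is auto-tuned every
    ``tune_interval`` sweeps toward 30-50% acceptance.  Random sequential
    addition gives up after ``rsa_max_failures`` consecutive rejected
    insertions; above ``compression_threshold`` effective area fraction
    the generator starts dilute and compresses instead.
    """

    equil_sweeps: int = 2000
    tune_interval: int = 10
    rsa_max_failures: int = 1_000_000
    compression_threshold: float = 0.52
    snapshot_interval: int = 10


@dataclass
class DiskConfiguration:
    """A periodic box of non-overlapping disk centres."""

    box_side: float
    centers: np.ndarray
    radius_eff: float
    radius_phys: float
    seed: int
    sweeps_done: int = 0
    delta: float = 0.0
    periodic: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.ascontiguousarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array")
        if self.centers.shape[0] < 1:
            raise ValueError("need at least one disk")
        if self.radius_phys > self.radius_eff:
            raise ValueError("physical radius cannot exceed effective radius")

    @property
    def n_disks(self) -> int:
        return self.centers.shape[0]

    @property
    def phi_eff(self) -> float:
        return self.n_disks * np.pi * self.radius_eff**2 / self.box_side**2

    @property
    def phi_phys(self) -> float:
        return self.n_disks * np.pi * self.radius_phys**2 / self.box_side**2

    @property
    def density(self) -> float:
        """Number density in disks/Å²."""
        return self.n_disks / self.box_side**2

    def min_pair_distance(self) -> float:
        """Brute-force O(n²) minimum periodic pair distance (oracle check)."""
        if self.n_disks < 2:
            return np.inf
        return float(_mc.min_pair_distance(self.centers, self.box_side))

    def assert_valid(self) -> None:
        if self.n_disks > 1:
            dmin = self.min_pair_distance()
            if dmin < 2.0 * self.radius_eff - _OVERLAP_TOL:
                raise AssertionError(
                    f"overlap: min pair distance {dmin:.6f} < 2 R_e "
                    f"{2 * self.radius_eff:.6f}"
                )

    def save(self, csv_path, json_path=None) -> None:
        """Write centres as CSV plus a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        lines = ["x,y"] + [f"{x:.9g},{y:.9g}" for x, y in self.centers]
        csv_path.write_text("\n".join(lines) + "\n")
        meta = {
            "box_side": self.box_side,
            "radius_eff": self.radius_eff,
            "radius_phys": self.radius_phys,
            "phi_eff": self.phi_eff,
            "phi_phys": self.phi_phys,
            "seed": self.seed,
            "sweeps_done": self.sweeps_done,
            "delta": self.delta,
            **self.metadata,
        }
        jp = Path(json_path) if json_path else csv_path.with_suffix(".json")
        jp.write_text(json.dumps(meta, indent=1) + "\n")


@dataclass
class RadialDistribution:
    """Radial distribution function g(r) of disk centres."""

    r_centers: np.ndarray
    g: np.ndarray
    g_stderr: np.ndarray
    density: float
    box_side: float
    n_snapshots: int


@dataclass
class ProximityResult:
    """Cumulative matrix-to-surface distance statistics."""

    shell_distances: np.ndarray
    matrix_fraction_within: np.ndarray
    grid_spacing: float
    phi_phys: float
    n_matrix_points: int


def _derive_seed(seed: int, salt: int) -> int:
    # keep derived seeds in numba's accepted 32-bit range
    return int((np.uint64(seed) * np.uint64(2654435761) + np.uint64(salt)) % np.uint64(2**31 - 1))


def generate_configuration(
    n_disks: int,
    phi_eff: float,
    radius_eff: float,
    radius_phys: Optional[float] = None,
    seed: int = 0,
    settings: Optional[MCSettings] = None,
) -> DiskConfiguration:
    """Equilibrated hard-disk configuration at the requested area fraction.

    The box side is set from ``n_disks``, ``phi_eff`` and ``radius_eff``;
    disks are first placed by random sequential addition (or, above the
    RSA-practical regime, by dilute insertion plus a compression
    schedule), then relaxed by ``settings.equil_sweeps`` Metropolis
    sweeps.  Deterministic for a fixed seed.
    """
    settings = settings or MCSettings()
    if n_disks < 1:
        raise ValueError("need at least one disk")
    if radius_phys is None:
        radius_phys = radius_eff
    if not 0 < phi_eff < PHI_CLOSE_PACK:
        raise ValueError(
            f"effective area fraction must be in (0, {PHI_CLOSE_PACK:.4f})"
        )
    box = radius_eff * np.sqrt(n_disks * np.pi / phi_eff)
    meta = {"protocol": "rsa+metropolis", "equil_sweeps": settings.equil_sweeps}

    if phi_eff <= settings.compression_threshold or n_disks == 1:
        pos, placed = _mc.rsa_fill(
            n_disks, box, radius_eff, _derive_seed(seed, 1), settings.rsa_max_failures
        )
        if placed < n_disks:
            raise RuntimeError(
                f"random sequential addition stalled at {placed}/{n_disks} disks "
                f"(phi_eff={phi_eff:.3f}); use a lower area fraction or the "
                "compression path"
            )
    else:
        pos, box = _compress_to(
            n_disks, phi_eff, radius_eff, box, seed, settings
        )
        meta["protocol"] = "dilute+compression+metropolis"

    delta = radius_eff * 0.5
    if settings.equil_sweeps > 0:
        delta, rate = _mc.mc_sweeps(
            pos,
            box,
            radius_eff,
            delta,
            settings.equil_sweeps,
            _derive_seed(seed, 2),
            True,
            settings.tune_interval,
        )
        meta["acceptance_rate"] = float(rate)
    cfg = DiskConfiguration(
        box_side=float(box),
        centers=pos,
        radius_eff=radius_eff,
        radius_phys=radius_phys,
        seed=seed,
        sweeps_done=settings.equil_sweeps,
        delta=float(delta),
        metadata=meta,
    )
    return cfg


def _compress_to(n_disks, phi_target, radius_eff, box_target, seed, settings):
    """Dilute RSA start followed by a gradual box compression schedule."""
    phi = min(0.45, phi_target)
    box = radius_eff * np.sqrt(n_disks * np.pi / phi)
    pos, placed = _mc.rsa_fill(
        n_disks, box, radius_eff, _derive_seed(seed, 11), settings.rsa_max_failures
    )
    if placed < n_disks:
        raise RuntimeError("dilute RSA stage failed; lower the area fraction")
    delta = radius_eff * 0.3
    stage = 0
    while box > box_target + 1e-12:
        dmin = _mc.min_pair_distance(pos, box) if n_disks > 1 else box
        # the largest uniform shrink that keeps the packing overlap-free
        f_allowed = 2.0 * radius_eff / dmin if dmin > 0 else 1.0
        f = max(f_allowed, 0.997, box_target / box)
        if f < 1.0 - 1e-12:
            pos *= f
            box *= f
        stage += 1
        delta, _ = _mc.mc_sweeps(
            pos, box, radius_eff, delta, 5, _derive_seed(seed, 100 + stage), True, 1
        )
        if stage > 20000:
            raise RuntimeError("compression schedule failed to converge")
    # land exactly on the target box
    scale = box_target / box
    if scale < 1.0 and n_disks > 1:
        dmin = _mc.min_pair_distance(pos, box)
        if dmin * scale < 2.0 * radius_eff - _OVERLAP_TOL:
            raise RuntimeError("final compression step would create overlap")
    pos *= scale
    return pos, box_target


def _advance(config: DiskConfiguration, n_sweeps: int, salt: int) -> None:
    """Run further sweeps in place (fixed delta, no tuning)."""
    delta = config.delta if config.delta > 0 else config.radius_eff * 0.3
    _mc.mc_sweeps(
        config.centers,
        config.box_side,
        config.radius_eff,
        delta,
        n_sweeps,
        _derive_seed(config.seed, 1000 + salt),
        False,
        10,
    )
    config.sweeps_done += n_sweeps


def radial_distribution(
    config: DiskConfiguration,
    bin_width: float = 0.25,
    r_max: Optional[float] = None,
    n_samples: int = 20,
    settings: Optional[MCSettings] = None,
) -> RadialDistribution:
    """g(r) averaged over decorrelated Monte Carlo snapshots.

    The configuration is advanced in place; each snapshot is separated by
    ``settings.snapshot_interval`` sweeps.  Normalisation is against the
    ideal-gas expectation rho * pi * (r_out² - r_in²) per disk, with the
    finite-N correction (n-1)/n for distinct ordered pairs.
    """
    settings = settings or MCSettings()
    L = config.box_side
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-12:
        raise ValueError("r_max beyond box_side/2 violates the minimum-image convention")
    if n_samples < 1:
        raise ValueError("need at least one snapshot")
    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    n = config.n_disks
    rho = config.density
    per_snap = np.empty((n_samples, n_bins))
    shell_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    # expected pair count per bin for an ideal gas of n points
    expect = 0.5 * n * (n - 1) / L**2 * shell_area
    for s in range(n_samples):
        _advance(config, settings.snapshot_interval, salt=s)
        hist = _mc.pair_histogram(config.centers, L, bin_width, n_bins)
        per_snap[s] = hist / expect
    g = per_snap.mean(axis=0)
    stderr = (
        per_snap.std(axis=0, ddof=1) / np.sqrt(n_samples)
        if n_samples > 1
        else np.full(n_bins, np.inf)
    )
    return RadialDistribution(
        r_centers=0.5 * (edges[1:] + edges[:-1]),
        g=g,
        g_stderr=stderr,
        density=rho,
        box_side=L,
        n_snapshots=n_samples,
    )


def structure_factor_from_rdf(
    rdf: RadialDistribution, q_grid: Sequence[float], taper_fraction: float = 0.2
):
    """S(q) = 1 + 2 pi rho ∫ (g(r) - 1) J0(qr) r dr (2D fluid Hankel transform).

    A raised-cosine taper over the outermost ``taper_fraction`` of the r
    range suppresses truncation ringing.  q values below 2 pi / box_side
    probe scales beyond the simulation box and are rejected.

    Returns (S, S_stderr) arrays on ``q_grid``.
    """
    q = np.asarray(q_grid, dtype=float)
    q_min = 2.0 * np.pi / rdf.box_side
    if np.any(q < q_min):
        raise ValueError(
            f"q below 2*pi/box_side = {q_min:.4g} is unreliable for this box"
        )
    r = rdf.r_centers
    dr = np.diff(r).mean() if r.size > 1 else 1.0
    taper = np.ones_like(r)
    if taper_fraction > 0:
        r0 = r[-1] * (1.0 - taper_fraction)
        sel = r > r0
        taper[sel] = 0.5 * (1.0 + np.cos(np.pi * (r[sel] - r0) / (r[-1] - r0)))
    h = (rdf.g - 1.0) * taper
    kern = j0(np.outer(q, r)) * r * dr  # (nq, nr)
    s_vals = 1.0 + 2.0 * np.pi * rdf.density * kern @ h
    s_err = 2.0 * np.pi * rdf.density * np.sqrt(
        (kern**2) @ ((rdf.g_stderr * taper) ** 2)
    )
    return s_vals, s_err


def direct_structure_factor(
    config: DiskConfiguration,
    q_targets: Sequence[float],
    n_samples: int = 20,
    max_vectors: int = 200,
    settings: Optional[MCSettings] = None,
):
    """S(q) by direct summation over lattice-compatible wave vectors.

    For each target q the reciprocal-lattice vectors (2 pi / L)(nx, ny)
    closest in magnitude (within half a lattice spacing) are collected,
    and S = <|sum_j exp(i q.r_j)|²> / N is averaged over them and over
    decorrelated snapshots.  This is the independent oracle for the
    g(r)-transform route.

    Returns (q_actual, S, S_stderr).
    """
    settings = settings or MCSettings()
    L = config.box_side
    dq = 2.0 * np.pi / L
    q_targets = np.asarray(q_targets, dtype=float)
    groups = []
    for qt in q_targets:
        m = int(np.ceil(qt / dq)) + 2
        nx, ny = np.meshgrid(np.arange(-m, m + 1), np.arange(0, m + 1))
        qv = np.stack([nx.ravel(), ny.ravel()], axis=1) * dq
        mags = np.hypot(qv[:, 0], qv[:, 1])
        sel = (np.abs(mags - qt) < 0.5 * dq) & (mags > 0)
        # keep only one of each +/- pair (ny > 0, or ny == 0 and nx > 0)
        sel &= (qv[:, 1] > 0) | ((qv[:, 1] == 0) & (qv[:, 0] > 0))
        vecs = qv[sel]
        if vecs.shape[0] == 0:
            raise ValueError(f"no lattice vector matches q = {qt:.4g}")
        if vecs.shape[0] > max_vectors:
            idx = np.argsort(np.abs(np.hypot(vecs[:, 0], vecs[:, 1]) - qt))
            vecs = vecs[idx[:max_vectors]]
        groups.append(vecs)
    per_snap = np.empty((n_samples, len(groups)))
    n = config.n_disks
    for s in range(n_samples):
        _advance(config, settings.snapshot_interval, salt=5000 + s)
        for gi, vecs in enumerate(groups):
            phases = config.centers @ vecs.T
            amp2 = np.cos(phases).sum(axis=0) ** 2 + np.sin(phases).sum(axis=0) ** 2
            per_snap[s, gi] = amp2.mean() / n
    s_vals = per_snap.mean(axis=0)
    s_err = (
        per_snap.std(axis=0, ddof=1) / np.sqrt(n_samples)
        if n_samples > 1
        else np.full(len(groups), np.inf)
    )
    q_actual = np.array([np.hypot(v[:, 0], v[:, 1]).mean() for v in groups])
    return q_actual, s_vals, s_err


@dataclass
class StructureFactorTable:
    """Tabulated hard-disk structure factor S on a (phi, x = q R_e) grid.

    Built from Monte Carlo runs at unit effective radius, so the x axis
    is dimensionless and one table serves any physical radius.  Smooth
    (cubic where the grid allows) interpolation between nodes; queries
    outside the grid raise rather than extrapolate.
    """

    phi_grid: np.ndarray
    x_grid: np.ndarray
    s_values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phi_grid = np.asarray(self.phi_grid, dtype=float)
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.s_values = np.asarray(self.s_values, dtype=float)
        if self.s_values.shape != (self.phi_grid.size, self.x_grid.size):
            raise ValueError("s_values shape must be (n_phi, n_x)")
        if np.any(self.s_values <= 0):
            raise ValueError("structure factor values must be positive")
        self._build_interpolator()

    def _build_interpolator(self):
        nphi = self.phi_grid.size
        kx = min(3, nphi - 1)
        if nphi >= 2:
            self._spline = RectBivariateSpline(
                self.phi_grid, self.x_grid, self.s_values, kx=kx, ky=3, s=0
            )
            self._single = None
        else:
            self._spline = None
            self._single = CubicSpline(self.x_grid, self.s_values[0])

    def __call__(self, phi: float, x):
        """Evaluate S(phi, x); raises out-of-range on any query off the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x < self.x_grid[0] - 1e-9) or np.any(x > self.x_grid[-1] + 1e-9):
            raise ValueError(
                f"x = qR_e outside table range [{self.x_grid[0]:.3g}, "
                f"{self.x_grid[-1]:.3g}]"
            )
        if self._single is not None:
            if abs(phi - self.phi_grid[0]) > 1e-9:
                raise ValueError(
                    f"single-phi table only covers phi = {self.phi_grid[0]:.4g}"
                )
            return self._single(np.clip(x, self.x_grid[0], self.x_grid[-1]))
        if phi < self.phi_grid[0] - 1e-9 or phi > self.phi_grid[-1] + 1e-9:
            raise ValueError(
                f"phi outside table range [{self.phi_grid[0]:.3g}, "
                f"{self.phi_grid[-1]:.3g}]"
            )
        return self._spline(
            np.clip(phi, self.phi_grid[0], self.phi_grid[-1]),
            np.clip(x, self.x_grid[0], self.x_grid[-1]),
        )[0]

    def save(self, path) -> None:
        payload = {
            "phi_grid": self.phi_grid.tolist(),
            "x_grid": self.x_grid.tolist(),
            "s_values": self.s_values.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def load(cls, path) -> "StructureFactorTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            phi_grid=np.asarray(payload["phi_grid"]),
            x_grid=np.asarray(payload["x_grid"]),
            s_values=np.asarray(payload["s_values"]),
            metadata=payload.get("metadata", {}),
        )


def build_structure_factor_table(
    phi_grid: Sequence[float],
    x_grid: Sequence[float],
    n_disks: int = 2000,
    n_samples: int = 30,
    seed: int = 0,
    settings: Optional[MCSettings] = None,
    bin_width: float = 0.05,
) -> StructureFactorTable:
    """Run one Monte Carlo simulation per phi and tabulate S(phi, x).

    Simulations use unit effective radius, so ``x_grid`` doubles as the
    q grid.  phi = 0 rows are filled with the exact ideal-gas value 1.
    """
    settings = settings or MCSettings()
    phi_grid = np.asarray(sorted(phi_grid), dtype=float)
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(phi_grid < 0) or np.any(phi_grid > 0.55):
        raise ValueError("phi grid must lie within [0, 0.55]")
    if x_grid[0] < 0.2 or x_grid[-1] > 20.0:
        raise ValueError("x = qR_e grid must lie within [0.2, 20]")
    s_values = np.ones((phi_grid.size, x_grid.size))
    for i, phi in enumerate(phi_grid):
        if phi == 0.0:
            continue
        cfg = generate_configuration(
            n_disks, phi, radius_eff=1.0, seed=_derive_seed(seed, 7000 + i),
            settings=settings,
        )
        rdf = radial_distribution(
            cfg, bin_width=bin_width, n_samples=n_samples, settings=settings
        )
        s_vals, _ = structure_factor_from_rdf(rdf, x_grid)
        s_values[i] = np.maximum(s_vals, 1e-6)
    meta = {
        "n_disks": n_disks,
        "n_samples": n_samples,
        "equil_sweeps": settings.equil_sweeps,
        "seed": seed,
        "bin_width": bin_width,
    }
    return StructureFactorTable(phi_grid, x_grid, s_values, metadata=meta)


def proximity_fractions(
    config: DiskConfiguration,
    radius: Optional[float] = None,
    distances: Sequence[float] = (6.0, 10.0),
    grid_spacing: float = 1.0,
) -> ProximityResult:
    """Fraction of matrix area within given distances of a disk surface.

    A square lattice of spacing ``grid_spacing`` is laid over the box.
    A lattice point belongs to the matrix if it lies outside every
    physical disk; for each distance d the cumulative fraction of matrix
    points whose distance to the nearest disk surface is <= d is
    returned.
    """
    radius = config.radius_phys if radius is None else radius
    distances = np.asarray(sorted(distances), dtype=float)
    if np.any(distances <= 0):
        raise ValueError("shell distances must be positive")
    if grid_spacing > 1.0 + 1e-12:
        raise ValueError("grid spacing must be <= 1 Å")
    L = config.box_side
    n_lat = max(2, int(round(L / grid_spacing)))
    cap = float(distances[-1]) * 1.001
    d_surf = _mc.lattice_surface_distances_celled(
        config.centers, L, n_lat, radius, cap
    )
    matrix = d_surf[d_surf >= 0.0]
    if matrix.size == 0:
        raise ValueError("no matrix lattice points: packing too dense for this radius")
    fracs = np.array([(matrix <= d).mean() for d in distances])
    return ProximityResult(
        shell_distances=distances,
        matrix_fraction_within=fracs,
        grid_spacing=L / n_lat,
        phi_phys=config.phi_phys,
        n_matrix_points=int(matrix.size),
    )
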