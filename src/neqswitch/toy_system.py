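"""Toy low/high-level potential surfaces with an exact free-energy oracle.

The systems studied here stand in for a pair of levels of theory (a cheap
molecular-mechanics-like surface and an expensive quantum-like surface) whose
free-energy difference is to be estimated from nonequilibrium switching
simulations.  Each surface is a function of one periodic "dihedral" coordinate
chi (degrees) plus an optional set of auxiliary harmonic bath coordinates, so
the partition function -- and hence the exact Delta A between any two surfaces
-- is available by quadrature.  That exact value plays the role that a
well-converged bidirectional (Crooks) estimate plays for real molecules: an
independent reference against which the one-sided estimators can be judged.

Units: kcal/mol for energies, degrees for chi, fs for time, K for temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872041

__all__ = [
    "KB",
    "PotentialSurface",
    "MixedHamiltonian",
    "LangevinParams",
    "Snapshot",
    "Trajectory",
    "RestartPool",
    "energy",
    "gradient",
    "exact_delta_a",
    "chi_marginal",
    "sample_boltzmann",
    "run_langevin",
    "build_restart_pool",
    "scan_surface",
    "wrap_angle",
    "default_low_surface",
    "default_high_surface",
]


def wrap_angle(chi):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    wrapped = np.remainder(np.asarray(chi, dtype=float) + 180.0, 360.0) - 180.0
    # remainder maps 180 -> -180; fold back so the interval is half-open at -180
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(chi) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class PotentialSurface:
    """One level of theory: cosine dihedral terms + harmonic bath.

    Parameters
    ----------
    dihedral_terms : sequence of (amplitude, multiplicity, phase)
        Cosine series on the periodic coordinate chi; each term contributes
        ``A * (1 + cos(n*chi - phase))`` with A in kcal/mol, n a positive
        integer and the phase in degrees.
    bath_stiffness : sequence of float
        Force constants of the auxiliary harmonic coordinates,
        kcal/(mol deg^2) (or any consistent squared-coordinate unit).
    offset : float
        Constant energy shift, kcal/mol.  Plays the role of the absolute
        energy gap between levels of theory.
    coupling : sequence of float
        Optional bilinear chi-bath couplings c_i (one per bath coordinate),
        contributing ``c_i * chi * q_i``.  Note that a nonzero coupling
        breaks strict 360-degree periodicity; the quadrature oracle then
        treats chi as living on the (-180, 180] box.
    """

    dihedral_terms: tuple = ()
    bath_stiffness: tuple = ()
    offset: float = 0.0
    coupling: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "dihedral_terms",
                           tuple((float(a), int(n), float(p)) for a, n, p in self.dihedral_terms))
        object.__setattr__(self, "bath_stiffness",
                           tuple(float(k) for k in self.bath_stiffness))
        object.__setattr__(self, "coupling", tuple(float(c) for c in self.coupling))
        if self.coupling and len(self.coupling) != len(self.bath_stiffness):
            raise ValueError(
                f"coupling has {len(self.coupling)} entries but bath has "
                f"{len(self.bath_stiffness)} coordinates")
        for k in self.bath_stiffness:
            if k <= 0:
                raise ValueError(f"bath stiffness must be positive, got {k}")

    @property
    def ndim(self) -> int:
        """Number of coordinates: chi plus the bath."""
        return 1 + len(self.bath_stiffness)


def _check_dims(ndim_expected: int, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-1] != ndim_expected:
        raise ValueError(
            f"coordinate vector has dimensionality {coords.shape[-1]}, "
            f"surface expects {ndim_expected}")
    return coords


def energy(surface: "PotentialSurface | MixedHamiltonian", coords) -> "float | np.ndarray":
    """Potential energy in kcal/mol.

    ``coords`` may be a single coordinate vector of length ``surface.ndim``
    or an array of shape ``(..., ndim)``; the leading axes are broadcast.
    """
    if isinstance(surface, MixedHamiltonian):
        return surface.energy(coords)
    coords = _check_dims(surface.ndim, coords)
    chi = coords[..., 0]
    u = np.full(chi.shape, surface.offset, dtype=float)
    for a, n, phase in surface.dihedral_terms:
        u = u + a * (1.0 + np.cos(np.deg2rad(n * chi - phase)))
    for i, k in enumerate(surface.bath_stiffness):
        q = coords[..., 1 + i]
        u = u + 0.5 * k * q * q
        if surface.coupling:
            u = u + surface.coupling[i] * chi * q
    if u.ndim == 0:
        return float(u)
    return u


def gradient(surface: "PotentialSurface | MixedHamiltonian", coords) -> np.ndarray:
    """Gradient of the potential, kcal/(mol deg); same leading shape as coords."""
    if isinstance(surface, MixedHamiltonian):
        return surface.gradient(coords)
    coords = _check_dims(surface.ndim, coords)
    chi = coords[..., 0]
    g = np.zeros_like(coords)
    dchi = np.zeros(chi.shape, dtype=float)
    for a, n, phase in surface.dihedral_terms:
        dchi = dchi - a * n * np.sin(np.deg2rad(n * chi - phase)) * (math.pi / 180.0)
    for i, k in enumerate(surface.bath_stiffness):
        q = coords[..., 1 + i]
        g[..., 1 + i] = k * q
        if surface.coupling:
            c = surface.coupling[i]
            g[..., 1 + i] += c * chi
            dchi = dchi + c * q
    g[..., 0] = dchi
    return g


@dataclass(frozen=True)
class MixedHamiltonian:
    """Linear mix of two surfaces: U(lam, x) = (1-lam) U_low(x) + lam U_high(x)."""

    low: PotentialSurface
    high: PotentialSurface
    lam: float = 0.0

    def __post_init__(self):
        if self.low.ndim != self.high.ndim:
            raise ValueError(
                f"low surface has {self.low.ndim} coordinates, high has {self.high.ndim}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")

    @property
    def ndim(self) -> int:
        return self.low.ndim

    def at(self, lam: float) -> "MixedHamiltonian":
        """A copy of this Hamiltonian frozen at a new coupling parameter."""
        return replace(self, lam=lam)

    def energy(self, coords, lam: "float | None" = None):
        if lam is None:
            lam = self.lam
        return (1.0 - lam) * energy(self.low, coords) + lam * energy(self.high, coords)

    def gradient(self, coords, lam: "float | None" = None):
        if lam is None:
            lam = self.lam
        return (1.0 - lam) * gradient(self.low, coords) + lam * gradient(self.high, coords)


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the Langevin thermostat and integrator.

    friction is in ps^-1 (as customarily reported), timestep in fs, mass in
    kcal fs^2 / (mol deg^2) -- an effective inertia for the reduced
    coordinates.  The default mass of 1 gives a ~100 fs oscillation period
    in the default high-level well, comfortably resolved at 1 fs steps.
    """

    temperature: float = 300.0
    friction: float = 5.0
    timestep: float = 1.0
    seed: int = 0
    n_steps: int = 1000
    mass: float = 1.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.friction < 0:
            raise ValueError(f"friction must be nonnegative, got {self.friction}")
        if self.timestep <= 0:
            raise ValueError(f"timestep must be positive, got {self.timestep}")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")


@dataclass
class Snapshot:
    """Coordinates and velocities, shape (ndim,) or (n_replicas, ndim)."""

    coords: np.ndarray
    velocities: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coords and velocities must have the same shape")

    def copy(self) -> "Snapshot":
        return Snapshot(self.coords.copy(), self.velocities.copy())


@dataclass
class Trajectory:
    """Stored configurations of a Langevin run plus the final phase-space point."""

    coords: np.ndarray          # (n_stored, ...) as produced by the integrator
    store_stride: int
    timestep: float
    final: Snapshot


def _system_ndim(system) -> int:
    return system.ndim


def run_langevin(system, params: LangevinParams, initial: Snapshot,
                 *, store_stride: int = 1, rng: "np.random.Generator | None" = None) -> Trajectory:
    """Integrate Langevin dynamics with the BAOAB splitting.

    ``system`` is a PotentialSurface or a MixedHamiltonian at fixed lambda.
    ``initial.coords`` may be a single vector or an ensemble ``(m, ndim)``;
    an ensemble is propagated as m independent replicas sharing one noise
    stream.  Given the same seed, initial condition and parameters the
    trajectory is bit-reproducible.

    The BAOAB step (half-kick, half-drift, Ornstein-Uhlenbeck velocity
    refresh, half-drift, half-kick) gives accurate configurational sampling
    at the 1 fs default step; friction=0 reduces it to velocity Verlet.
    """
    ndim = _system_ndim(system)
    x = np.atleast_2d(np.asarray(initial.coords, dtype=float)).copy()
    v = np.atleast_2d(np.asarray(initial.velocities, dtype=float)).copy()
    if x.shape[-1] != ndim:
        raise ValueError(f"initial coords have dimensionality {x.shape[-1]}, "
                         f"system expects {ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("initial coordinates must be finite")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    dt = params.timestep
    m = params.mass
    gamma = params.friction * 1e-3          # ps^-1 -> fs^-1
    kbt = KB * params.temperature
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kbt / m) * math.sqrt(max(0.0, 1.0 - c1 * c1))

    n_stored = params.n_steps // store_stride
    stored = np.empty((n_stored,) + x.shape, dtype=float)
    out_i = 0
    f = -gradient(system, x)
    for step in range(params.n_steps):
        v += (0.5 * dt / m) * f
        x += 0.5 * dt * v
        if gamma > 0.0:
            v *= c1
            v += c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        f = -gradient(system, x)
        v += (0.5 * dt / m) * f
        if (step + 1) % store_stride == 0:
            stored[out_i] = x
            out_i += 1
        if (step + 1) % 256 == 0 or step == params.n_steps - 1:
            with np.errstate(over="ignore", invalid="ignore"):
                u = energy(system, x)
            if np.any(np.abs(u) > 1e8) or not np.all(np.isfinite(x)):
                raise RuntimeError(
                    "potential energy exceeded 1e8 kcal/mol during Langevin "
                    "integration; use a smaller timestep")

    shape_single = np.asarray(initial.coords).ndim == 1
    final = Snapshot(x[0] if shape_single else x, v[0] if shape_single else v)
    coords_out = stored[:, 0, :] if shape_single else stored
    return Trajectory(coords=coords_out, store_stride=store_stride,
                      timestep=dt, final=final)


# ---------------------------------------------------------------------------
# Exact free-energy oracle

def _chi_effective_energy(surface: PotentialSurface, chi: np.ndarray) -> np.ndarray:
    """Potential along chi after analytic minimisation-free Gaussian completion
    of the bath: U_dih(chi) + offset - sum c_i^2 chi^2 / (2 k_i)."""
    u = np.full(np.shape(chi), surface.offset, dtype=float)
    for a, n, phase in surface.dihedral_terms:
        u = u + a * (1.0 + np.cos(np.deg2rad(n * np.asarray(chi) - phase)))
    if surface.coupling:
        for k, c in zip(surface.bath_stiffness, surface.coupling):
            u = u - (c * c) * np.asarray(chi) ** 2 / (2.0 * k)
    return u


def _log_partition(surface: PotentialSurface, temperature: float, n_grid: int) -> float:
    """log of the configurational partition function.

    Bath coordinates are Gaussian (after completing the square against the
    bilinear coupling) and integrate in closed form; the chi marginal is a
    midpoint quadrature on n_grid cells over one period.
    """
    beta = 1.0 / (KB * temperature)
    logz = 0.0
    for k in surface.bath_stiffness:
        logz += 0.5 * math.log(2.0 * math.pi / (beta * k))
    width = 360.0 / n_grid
    chi = -180.0 + width * (np.arange(n_grid) + 0.5)
    u = _chi_effective_energy(surface, chi)
    logz += logsumexp(-beta * u) + math.log(width)
    return logz


def exact_delta_a(low: PotentialSurface, high: PotentialSurface, temperature: float = 300.0,
                  n_grid: int = 720, tol: float = 1e-4, max_refinements: int = 12) -> float:
    """Exact Delta A (high minus low) in kcal/mol by quadrature.

    Doubles the chi-grid resolution until two successive estimates differ by
    less than ``tol`` kcal/mol.  Antisymmetric by construction:
    exact_delta_a(low, high) == -exact_delta_a(high, low) on identical grids.
    """
    if low.ndim != high.ndim:
        raise ValueError("surfaces must share dimensionality")
    kbt = KB * temperature
    prev = None
    n = int(n_grid)
    for _ in range(max_refinements + 1):
        da = -kbt * (_log_partition(high, temperature, n) -
                     _log_partition(low, temperature, n))
        if prev is not None and abs(da - prev) < tol:
            return da
        prev = da
        n *= 2
    raise RuntimeError(
        f"free-energy quadrature did not converge: last two estimates "
        f"{prev:.8f} and {da:.8f} kcal/mol differ by more than {tol}")


def chi_marginal(surface: PotentialSurface, temperature: float, n_grid: int = 1440):
    """Normalised Boltzmann marginal of chi on a midpoint grid.

    Returns (chi_centres, probability_per_cell); the probabilities sum to 1.
    """
    beta = 1.0 / (KB * temperature)
    width = 360.0 / n_grid
    chi = -180.0 + width * (np.arange(n_grid) + 0.5)
    logw = -beta * _chi_effective_energy(surface, chi)
    p = np.exp(logw - logsumexp(logw))
    return chi, p


def sample_boltzmann(surface: PotentialSurface, temperature: float, n: int,
                     rng: np.random.Generator, n_grid: int = 2880) -> np.ndarray:
    """Independent samples of the full coordinate vector from exp(-U/kBT).

    chi is drawn by inverse-CDF on a fine grid (with uniform jitter within a
    cell); each bath coordinate follows its conditional Gaussian
    q | chi ~ N(-c chi / k, kBT / k).
    """
    chi_grid, p = chi_marginal(surface, temperature, n_grid)
    width = 360.0 / n_grid
    idx = rng.choice(n_grid, size=n, p=p)
    chi = chi_grid[idx] + rng.uniform(-0.5, 0.5, size=n) * width
    coords = np.empty((n, surface.ndim))
    coords[:, 0] = chi
    kbt = KB * temperature
    for i, k in enumerate(surface.bath_stiffness):
        c = surface.coupling[i] if surface.coupling else 0.0
        mean = -c * chi / k
        coords[:, 1 + i] = mean + math.sqrt(kbt / k) * rng.standard_normal(n)
    return coords


# ---------------------------------------------------------------------------
# Restart pools

@dataclass
class RestartPool:
    """Starting points for switches: 8 independent blocks of saved snapshots."""

    blocks: list                     # list of lists of Snapshot, simulation order
    save_stride: int
    level: str                       # "low" | "high"

    def __post_init__(self):
        counts = {len(b) for b in self.blocks}
        if len(counts) > 1:
            raise ValueError(f"blocks have unequal snapshot counts: {sorted(counts)}")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def snapshots_per_block(self) -> int:
        return len(self.blocks[0])

    @property
    def size(self) -> int:
        return self.n_blocks * self.snapshots_per_block


def _maxwell_velocities(ndim: int, temperature: float, mass: float,
                        rng: np.random.Generator) -> np.ndarray:
    return math.sqrt(KB * temperature / mass) * rng.standard_normal(ndim)


def build_restart_pool(system, params: LangevinParams, *, level: str,
                       run_length: int, save_stride: int, n_blocks: int = 8,
                       randomize_start: bool = True,
                       start_distribution: str = "uniform",
                       burn_in: int = 0) -> RestartPool:
    """Run ``n_blocks`` independent equilibrium simulations, saving snapshots.

    Each block gets its own RNG stream spawned from ``params.seed``; block b
    starts from a random initial chi (uniform on (-180, 180] when
    ``start_distribution="uniform"``, or drawn from the exact Boltzmann
    marginal when ``"boltzmann"``) with Maxwell-Boltzmann velocities, runs
    ``burn_in`` unsaved equilibration steps, then ``run_length`` production
    steps with a snapshot stored every ``save_stride`` steps.

    Two pool qualities are available.  ``start_distribution="uniform"``
    mirrors randomised starting conformers followed by a short equilibration
    and is the deliberately fragile choice: each block is one sequential
    Langevin run whose starting chi is uniform on (-180, 180], so blocks
    that start in (or pass through) a metastable basin carry it into their
    early snapshots -- this is the under-equilibrated pool used to study
    outlier provenance.  ``"boltzmann"`` is the idealised well-equilibrated
    pool: every snapshot's coordinates are drawn independently from the
    exact Boltzmann distribution (inverse-CDF on the quadrature grid) with
    Maxwell-Boltzmann velocities, then relaxed for ``save_stride`` Langevin
    steps to stay consistent with the integrator's sampled ensemble.  The
    Boltzmann mode is what a dynamically unreachable equilibrium (barriers
    of many kBT) would look like after an unaffordably long simulation.
    """
    if run_length % save_stride != 0:
        raise ValueError(
            f"run_length ({run_length}) must be divisible by save_stride ({save_stride})")
    if start_distribution not in ("uniform", "boltzmann"):
        raise ValueError(f"unknown start_distribution: {start_distribution!r}")
    surface = system if isinstance(system, PotentialSurface) else None
    if start_distribution == "boltzmann" and surface is None:
        raise ValueError("boltzmann starts require a plain PotentialSurface")
    ndim = _system_ndim(system)
    n_save = run_length // save_stride
    seeds = np.random.SeedSequence(params.seed).spawn(n_blocks)
    blocks = []
    for b in range(n_blocks):
        rng = np.random.default_rng(seeds[b])
        if randomize_start and start_distribution == "boltzmann":
            coords = sample_boltzmann(surface, params.temperature, n_save, rng)
            vels = (math.sqrt(KB * params.temperature / params.mass)
                    * rng.standard_normal((n_save, ndim)))
            p_seg = replace(params, n_steps=save_stride)
            final = run_langevin(system, p_seg, Snapshot(coords, vels),
                                 store_stride=save_stride, rng=rng).final
            block = [Snapshot(final.coords[j].copy(), final.velocities[j].copy())
                     for j in range(n_save)]
        else:
            coords = np.zeros(ndim)
            coords[0] = 180.0
            if randomize_start:
                coords[0] = rng.uniform(-180.0, 180.0)
            vel = _maxwell_velocities(ndim, params.temperature, params.mass, rng)
            snap = Snapshot(coords, vel)
            if burn_in > 0:
                p_burn = replace(params, n_steps=burn_in)
                snap = run_langevin(system, p_burn, snap, store_stride=burn_in,
                                    rng=rng).final
            block = []
            p_seg = replace(params, n_steps=save_stride)
            for _ in range(n_save):
                snap = run_langevin(system, p_seg, snap, store_stride=save_stride,
                                    rng=rng).final
                block.append(snap.copy())
        blocks.append(block)
    return RestartPool(blocks=blocks, save_stride=save_stride, level=level)


# ---------------------------------------------------------------------------
# Potential-energy scans

def scan_surface(system, chi_grid=None, *, shift_min: bool = True):
    """Energy along chi with the bath analytically relaxed (minimised).

    Returns a pandas DataFrame with columns ``chi_deg`` and
    ``energy_kcal_mol``; by default energies are shifted so the grid minimum
    is zero, the conventional presentation of torsional scans.
    """
    import pandas as pd

    if chi_grid is None:
        chi_grid = np.linspace(-180.0, 180.0, 361)
    chi_grid = np.asarray(chi_grid, dtype=float)
    if np.ptp(chi_grid) > 360.0:
        raise ValueError("chi grid must span at most one period (360 degrees)")

    def relaxed(surface_or_mix, chi):
        if isinstance(surface_or_mix, MixedHamiltonian):
            lo = relaxed(surface_or_mix.low, chi)
            hi = relaxed(surface_or_mix.high, chi)
            return (1.0 - surface_or_mix.lam) * lo + surface_or_mix.lam * hi
        # harmonic bath with optional bilinear coupling minimises analytically
        return _chi_effective_energy(surface_or_mix, chi)

    u = relaxed(system, chi_grid)
    if shift_min:
        u = u - u.min()
    return pd.DataFrame({"chi_deg": chi_grid, "energy_kcal_mol": u})


# ---------------------------------------------------------------------------
# Default parameterisation

def default_low_surface() -> PotentialSurface:
    """Low level: a single broad trans minimum at chi = +/-180 degrees.

    U = 8 (1 + cos chi); thermal width ~16 degrees at 300 K, and the cis
    region (chi ~ 0) sits ~15 kcal/mol up, so spontaneous visits there
    essentially never occur on desk-scale runs.
    """
    return PotentialSurface(dihedral_terms=((8.0, 1, 0.0),))


def default_high_surface() -> PotentialSurface:
    """High level: bistable, with conformational preferences shifted
    relative to the low level.

    U = 6 (1 + cos(2 chi - 70)) + (1 + cos(chi + 55)): a trans-like global
    minimum at 125 degrees (displaced 55 degrees from the low level's -- the
    two levels disagree about the preferred geometry, which is what makes
    fast switches dissipative and the lowest work values rare) and a
    cis-like local minimum at -55 degrees, 2 kcal/mol up, separated by ~13
    kcal/mol barriers at 35 and -145 degrees that dynamics cannot cross at
    300 K.  The low level's minimum at 180 lies inside the high level's
    trans basin, so ordinary forward switches relax towards 125 degrees; a
    switch that starts near the cis region instead ends trapped there with
    a strongly negative work value.
    """
    return PotentialSurface(dihedral_terms=((6.0, 2, 70.0), (1.0, 1, -55.0)))
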