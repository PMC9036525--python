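"""Nonequilibrium switching between levels of theory.

A "switch" is a short Langevin trajectory during which the Hamiltonian is
driven linearly from one level of theory to the other; the work performed on
the system is accumulated in slow-growth mode, one lambda increment per
dynamics step.  Forward switches go low -> high (lambda 0 -> 1) and start from
an equilibrium pool at the low level; backward switches go high -> low and
start from the high-level pool.  Protocols trade switching length against the
number of switches at a fixed total step budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .toy_system import (
    KB,
    LangevinParams,
    MixedHamiltonian,
    RestartPool,
    Snapshot,
    energy,
    gradient,
    wrap_angle,
)

__all__ = [
    "ProtocolSpec",
    "SwitchRecord",
    "WorkSet",
    "make_protocol",
    "run_switch",
    "run_protocol",
    "subsample_reduced",
]

N_BLOCKS = 8


@dataclass(frozen=True)
class ProtocolSpec:
    """A fixed-budget switching protocol.

    n_switch is the switching length in integrator steps (1 fs each, so also
    in fs at the default timestep); n_replicate the number of switches;
    blocksize the switches per block; stride the restart-file spacing between
    consecutive launches; t_total the cumulative switching time in ns.
    """

    name: str
    n_switch: int
    n_replicate: int
    blocksize: int
    stride: int
    t_total: float

    def __post_init__(self):
        if self.n_replicate != N_BLOCKS * self.blocksize:
            raise ValueError(
                f"n_replicate ({self.n_replicate}) must equal "
                f"{N_BLOCKS} x blocksize ({self.blocksize})")


def make_protocol(name: str, n_switch: int, n_replicate: int, pool_size: int) -> ProtocolSpec:
    """Derive blocksize, launch stride and cumulative time for a protocol.

    ``pool_size`` is the total number of restart snapshots across all 8
    blocks; launches use every (pool_size / n_replicate)-th snapshot.
    """
    if n_replicate % N_BLOCKS != 0:
        raise ValueError(
            f"n_replicate ({n_replicate}) must be divisible by {N_BLOCKS} blocks")
    if pool_size % n_replicate != 0:
        raise ValueError(
            f"pool size ({pool_size}) must be divisible by n_replicate ({n_replicate})")
    blocksize = n_replicate // N_BLOCKS
    stride = pool_size // n_replicate
    t_total = n_switch * n_replicate * 1e-6          # fs -> ns
    return ProtocolSpec(name=name, n_switch=n_switch, n_replicate=n_replicate,
                        blocksize=blocksize, stride=stride, t_total=t_total)


@dataclass
class SwitchRecord:
    """Outcome of one switching trajectory."""

    work: float                      # kcal/mol, in the switch's own direction
    direction: str                   # "forward" | "backward"
    block: int                       # 1..8
    within_index: int                # 1..blocksize, restart-file save order
    global_index: int                # continuous numbering across blocks
    chi_pre: tuple                   # degrees, per tracked dihedral
    chi_post: tuple
    seed: int

    def __post_init__(self):
        self.chi_pre = tuple(float(c) for c in np.atleast_1d(self.chi_pre))
        self.chi_post = tuple(float(c) for c in np.atleast_1d(self.chi_post))


@dataclass
class WorkSet:
    """Direction-tagged collection of switch records for one protocol."""

    records: list
    direction: str
    temperature: float
    protocol: ProtocolSpec
    system: str = "toy"

    def __post_init__(self):
        for r in self.records:
            if r.direction != self.direction:
                raise ValueError(
                    f"record {r.global_index} has direction {r.direction!r}, "
                    f"work set is {self.direction!r}")
        if len(self.records) > self.protocol.n_replicate:
            raise ValueError(
                f"{len(self.records)} records exceed protocol n_replicate "
                f"{self.protocol.n_replicate}")

    @property
    def works(self) -> np.ndarray:
        return np.array([r.work for r in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)


def _lambda_schedule(n_steps: int, direction: str) -> np.ndarray:
    """lambda_k for k = 0..n: linear 0->1 forward, 1->0 backward."""
    lam = np.arange(n_steps + 1, dtype=float) / n_steps
    return lam if direction == "forward" else 1.0 - lam


def _batched_switches(mixed: MixedHamiltonian, coords: np.ndarray, vels: np.ndarray,
                      n_steps: int, direction: str, params: LangevinParams,
                      rng: np.random.Generator):
    """Propagate an ensemble of switches, accumulating slow-growth work.

    At step k the dynamics runs under U(lambda_k, .); the work increment is
    U(lambda_{k+1}, x_k) - U(lambda_k, x_k) evaluated at the configuration
    x_k produced by that step.  For a linear mix every increment equals
    (lambda_{k+1} - lambda_k) * (U_high(x_k) - U_low(x_k)).
    """
    lam = _lambda_schedule(n_steps, direction)
    x = coords.copy()
    v = vels.copy()
    dt = params.timestep
    m = params.mass
    gamma = params.friction * 1e-3
    kbt = KB * params.temperature
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kbt / m) * math.sqrt(max(0.0, 1.0 - c1 * c1))
    work = np.zeros(x.shape[0])
    for k in range(n_steps):
        sys_k = mixed.at(lam[k])
        f = -gradient(sys_k, x)
        v += (0.5 * dt / m) * f
        x += 0.5 * dt * v
        if gamma > 0.0:
            v *= c1
            v += c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v
        v += (0.5 * dt / m) * (-gradient(sys_k, x))
        work += (lam[k + 1] - lam[k]) * (energy(mixed.high, x) - energy(mixed.low, x))
    return work, x, v


def run_switch(mixed: MixedHamiltonian, start: Snapshot, n_steps: int,
               direction: str, params: LangevinParams) -> SwitchRecord:
    """Run a single switching trajectory from an equilibrium snapshot.

    The caller is responsible for drawing ``start`` from the equilibrium
    pool of the direction's origin level (forward: the low level); that
    requirement of the work theorem is documented, not checked.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    rng = np.random.default_rng(params.seed)
    coords = np.atleast_2d(start.coords)
    vels = np.atleast_2d(start.velocities)
    work, x_final, _ = _batched_switches(mixed, coords, vels, n_steps, direction, params, rng)
    return SwitchRecord(
        work=float(work[0]), direction=direction, block=1, within_index=1,
        global_index=1, chi_pre=(wrap_angle(float(coords[0, 0])),),
        chi_post=(wrap_angle(float(x_final[0, 0])),), seed=params.seed)


def run_protocol(pool: RestartPool, protocol: ProtocolSpec, mixed: MixedHamiltonian,
                 direction: str, params: LangevinParams, system: str = "toy") -> WorkSet:
    """Launch a full protocol from a restart pool.

    From each block, switches start at every ``protocol.stride``-th saved
    snapshot, in save order; block / within-block / global indices follow the
    continuous numbering scheme (no reset between blocks).  All switches of
    the protocol are integrated as one batched ensemble driven by a single
    RNG stream seeded with ``params.seed``, which every record's ``seed``
    field echoes.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    if protocol.stride * protocol.n_replicate != pool.size:
        expected = pool.size // protocol.n_replicate
        raise ValueError(
            f"protocol stride {protocol.stride} inconsistent with pool of "
            f"{pool.size} snapshots and n_replicate {protocol.n_replicate}; "
            f"expected stride {expected}")
    if pool.n_blocks != N_BLOCKS:
        raise ValueError(f"pool must have {N_BLOCKS} blocks, got {pool.n_blocks}")

    starts, vels = [], []
    for block in pool.blocks:
        for j in range(protocol.blocksize):
            snap = block[(j + 1) * protocol.stride - 1]
            starts.append(snap.coords)
            vels.append(snap.velocities)
    coords = np.array(starts)
    velocities = np.array(vels)
    rng = np.random.default_rng(params.seed)
    work, x_final, _ = _batched_switches(
        mixed, coords, velocities, protocol.n_switch, direction, params, rng)

    records = []
    for i in range(protocol.n_replicate):
        b = i // protocol.blocksize + 1
        w = i % protocol.blocksize + 1
        records.append(SwitchRecord(
            work=float(work[i]), direction=direction, block=b, within_index=w,
            global_index=(b - 1) * protocol.blocksize + w,
            chi_pre=(wrap_angle(float(coords[i, 0])),),
            chi_post=(wrap_angle(float(x_final[i, 0])),),
            seed=params.seed))
    return WorkSet(records=records, direction=direction,
                   temperature=params.temperature, protocol=protocol, system=system)


def subsample_reduced(workset: WorkSet, keep_per_block: int,
                      mode: str = "stride") -> WorkSet:
    """Reduce a work set to ``keep_per_block`` switches per block.

    The default ``"stride"`` mode keeps every (blocksize/keep_per_block)-th
    record within each block starting from the first (within-block indices
    1, 1+s, 1+2s, ...), preserving original indices; ``"first"`` keeps the
    leading keep_per_block records of each block instead.
    """
    blocksize = workset.protocol.blocksize
    if keep_per_block > blocksize:
        raise ValueError(
            f"keep_per_block ({keep_per_block}) exceeds blocksize ({blocksize})")
    if blocksize % keep_per_block != 0:
        raise ValueError(
            f"blocksize ({blocksize}) not divisible by keep_per_block ({keep_per_block})")
    if mode not in ("stride", "first"):
        raise ValueError(f"unknown subsampling mode: {mode!r}")
    s = blocksize // keep_per_block
    if mode == "stride":
        keep = {1 + s * j for j in range(keep_per_block)}
    else:
        keep = set(range(1, keep_per_block + 1))
    records = [r for r in workset.records if r.within_index in keep]
    proto = workset.protocol
    reduced = ProtocolSpec(
        name=proto.name + "red" if keep_per_block < blocksize else proto.name,
        n_switch=proto.n_switch, n_replicate=N_BLOCKS * keep_per_block,
        blocksize=keep_per_block, stride=proto.stride * s,
        t_total=proto.n_switch * N_BLOCKS * keep_per_block * 1e-6)
    return WorkSet(records=records, direction=workset.direction,
                   temperature=workset.temperature, protocol=reduced,
                   system=workset.system)
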