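"""On-disk formats: work-set TSV files and the YAML run configuration.

Work sets are stored as tab-separated text with a small ``# key<TAB>value``
metadata preamble (direction, temperature, protocol arithmetic, system
label) followed by a header line and one row per switch.  TSV rather than
CSV avoids locale decimal-separator ambiguity; floats are written with
Python's shortest round-trip representation, so write -> read is lossless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .switching import ProtocolSpec, SwitchRecord, WorkSet
from .toy_system import LangevinParams, PotentialSurface

__all__ = [
    "read_workset",
    "write_workset",
    "read_pool",
    "write_pool",
    "RunConfig",
    "PoolConfig",
    "ProtocolConfig",
    "validate_config",
    "load_config",
]

_META_KEYS = ("system", "direction", "temperature", "protocol_name", "n_switch",
              "n_replicate", "blocksize", "stride", "t_total")


def _workset_columns(n_dihedrals: int):
    cols = ["direction", "block", "within_index", "global_index", "work_kcal_mol"]
    for k in range(1, n_dihedrals + 1):
        cols += [f"chi{k}_pre_deg", f"chi{k}_post_deg"]
    cols.append("seed")
    return cols


def write_workset(workset: WorkSet, path) -> None:
    """Serialise a work set to TSV (metadata preamble + one row per switch)."""
    path = Path(path)
    n_dih = len(workset.records[0].chi_pre) if workset.records else 1
    cols = _workset_columns(n_dih)
    p = workset.protocol
    meta = {
        "system": workset.system, "direction": workset.direction,
        "temperature": repr(workset.temperature), "protocol_name": p.name,
        "n_switch": p.n_switch, "n_replicate": p.n_replicate,
        "blocksize": p.blocksize, "stride": p.stride, "t_total": repr(p.t_total),
    }
    with open(path, "w") as fh:
        for key in _META_KEYS:
            fh.write(f"# {key}\t{meta[key]}\n")
        fh.write("\t".join(cols) + "\n")
        for r in workset.records:
            row = [r.direction, str(r.block), str(r.within_index), str(r.global_index),
                   repr(r.work)]
            for k in range(n_dih):
                row += [repr(r.chi_pre[k]), repr(r.chi_post[k])]
            row.append(str(r.seed))
            fh.write("\t".join(row) + "\n")


def read_workset(path) -> WorkSet:
    """Read a work set TSV written by :func:`write_workset`.

    A missing column raises an error naming it; a malformed row raises an
    error carrying its line number.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("\t")
            meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    missing_meta = [k for k in _META_KEYS if k not in meta]
    if missing_meta:
        raise ValueError(f"{path}: missing metadata keys: {missing_meta}")
    header = lines[body_start].rstrip("\n").split("\t")
    n_dih = sum(1 for c in header if c.endswith("_pre_deg"))
    expected = _workset_columns(max(n_dih, 1))
    for col in expected:
        if col not in header:
            raise ValueError(f"{path}: missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    records = []
    for lineno, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        try:
            records.append(SwitchRecord(
                work=float(parts[idx["work_kcal_mol"]]),
                direction=parts[idx["direction"]],
                block=int(parts[idx["block"]]),
                within_index=int(parts[idx["within_index"]]),
                global_index=int(parts[idx["global_index"]]),
                chi_pre=tuple(float(parts[idx[f"chi{k}_pre_deg"]])
                              for k in range(1, n_dih + 1)),
                chi_post=tuple(float(parts[idx[f"chi{k}_post_deg"]])
                               for k in range(1, n_dih + 1)),
                seed=int(parts[idx["seed"]])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    protocol = ProtocolSpec(
        name=meta["protocol_name"], n_switch=int(meta["n_switch"]),
        n_replicate=int(meta["n_replicate"]), blocksize=int(meta["blocksize"]),
        stride=int(meta["stride"]), t_total=float(meta["t_total"]))
    return WorkSet(records=records, direction=meta["direction"],
                   temperature=float(meta["temperature"]), protocol=protocol,
                   system=meta["system"])


def write_pool(pool, path) -> None:
    """Serialise a restart pool: one row per snapshot, coordinates then velocities.

    The first coordinate is the periodic dihedral chi in degrees; the
    remaining ones are the harmonic bath coordinates.
    """
    path = Path(path)
    ndim = pool.blocks[0][0].coords.size
    cols = ["block", "snapshot_index", "chi_deg"]
    cols += [f"q{i}_deg" for i in range(1, ndim)]
    cols += ["v_chi_deg_fs"] + [f"v_q{i}_deg_fs" for i in range(1, ndim)]
    with open(path, "w") as fh:
        fh.write(f"# level\t{pool.level}\n# save_stride\t{pool.save_stride}\n")
        fh.write("\t".join(cols) + "\n")
        for b, block in enumerate(pool.blocks, start=1):
            for j, snap in enumerate(block, start=1):
                vals = [str(b), str(j)]
                vals += [repr(float(x)) for x in snap.coords]
                vals += [repr(float(v)) for v in snap.velocities]
                fh.write("\t".join(vals) + "\n")


def read_pool(path):
    """Read a restart pool TSV written by :func:`write_pool`."""
    from .toy_system import RestartPool, Snapshot

    path = Path(path)
    meta = {}
    rows = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                meta[key.strip()] = value.strip()
            elif header is None:
                header = line.rstrip("\n").split("\t")
            elif line.strip():
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header):
                    raise ValueError(
                        f"{path}:{lineno}: expected {len(header)} fields, "
                        f"got {len(parts)}")
                rows.append(parts)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    ndim = (len(header) - 2) // 2
    blocks: dict = {}
    for parts in rows:
        b = int(parts[0])
        coords = np.array([float(x) for x in parts[2:2 + ndim]])
        vels = np.array([float(x) for x in parts[2 + ndim:2 + 2 * ndim]])
        blocks.setdefault(b, []).append(Snapshot(coords, vels))
    return RestartPool(blocks=[blocks[b] for b in sorted(blocks)],
                       save_stride=int(meta.get("save_stride", 1)),
                       level=meta.get("level", "low"))


# ---------------------------------------------------------------------------
# Run configuration

@dataclass(frozen=True)
class PoolConfig:
    run_length: int = 8000
    save_stride: int = 20
    burn_in: int = 2000              # uniform (sequential) mode only
    randomize_start: bool = True
    start_distribution: str = "boltzmann"


@dataclass(frozen=True)
class ProtocolConfig:
    name: str
    n_switch: int
    n_replicate: int


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full protocol-comparison experiment."""

    low: PotentialSurface
    high: PotentialSurface
    langevin: LangevinParams
    pool_low: PoolConfig
    pool_high: PoolConfig
    protocols: tuple
    seed: int = 1
    temperature: float = 300.0
    outlier_k: float = 3.0
    dihedral_labels: tuple = ("chi1",)
    system: str = "toy"
    output_dir: str = "runs/experiment"
    reduced_from: "str | None" = None
    reduced_keep_per_block: "int | None" = None

    @property
    def pool_size_low(self) -> int:
        return 8 * (self.pool_low.run_length // self.pool_low.save_stride)

    @property
    def pool_size_high(self) -> int:
        return 8 * (self.pool_high.run_length // self.pool_high.save_stride)


_DEFAULT_SURFACES = {
    "low": {"dihedral_terms": [[8.0, 1, 0.0]]},
    "high": {"dihedral_terms": [[6.0, 2, 70.0], [1.0, 1, -55.0]]},
}
# fixed budget of 64 000 switching steps; pool of 8 x 400 snapshots
_DEFAULT_PROTOCOLS = [
    {"name": "NSWI40", "n_switch": 40, "n_replicate": 1600},
    {"name": "NSWI100", "n_switch": 100, "n_replicate": 640},
    {"name": "NSWI200", "n_switch": 200, "n_replicate": 320},
    {"name": "NSWI400", "n_switch": 400, "n_replicate": 160},
]

_TOP_KEYS = {"system", "seed", "temperature", "outlier_k", "output_dir",
             "dihedral_labels", "surfaces", "langevin", "pool", "protocols",
             "reduced"}


def _build_surface(spec: dict, errors: list, where: str) -> PotentialSurface:
    known = {"dihedral_terms", "bath_stiffness", "offset", "coupling"}
    for key in spec:
        if key not in known:
            errors.append(f"{where}: unknown key {key!r}")
    try:
        return PotentialSurface(
            dihedral_terms=tuple(tuple(t) for t in spec.get("dihedral_terms", ())),
            bath_stiffness=tuple(spec.get("bath_stiffness", ())),
            offset=float(spec.get("offset", 0.0)),
            coupling=tuple(spec.get("coupling", ())))
    except (TypeError, ValueError) as exc:
        errors.append(f"{where}: {exc}")
        return PotentialSurface()


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw configuration mapping, reporting all problems at once.

    Unknown keys are rejected; defaults (300 K, friction 5 ps^-1, k = 3, the
    default toy surfaces and the scaled-down fixed-budget protocol grid) fill
    anything omitted.
    """
    errors: list = []
    raw = dict(raw or {})
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"unknown key {key!r}")

    surfaces = raw.get("surfaces", _DEFAULT_SURFACES)
    low = _build_surface(surfaces.get("low", _DEFAULT_SURFACES["low"]), errors, "surfaces.low")
    high = _build_surface(surfaces.get("high", _DEFAULT_SURFACES["high"]), errors, "surfaces.high")
    for key in surfaces:
        if key not in ("low", "high"):
            errors.append(f"surfaces: unknown key {key!r}")

    temperature = float(raw.get("temperature", 300.0))
    lang_raw = dict(raw.get("langevin", {}))
    lang_known = {"friction", "timestep", "mass"}
    for key in lang_raw:
        if key not in lang_known:
            errors.append(f"langevin: unknown key {key!r}")
    try:
        langevin = LangevinParams(
            temperature=temperature,
            friction=float(lang_raw.get("friction", 5.0)),
            timestep=float(lang_raw.get("timestep", 1.0)),
            mass=float(lang_raw.get("mass", 1.0)),
            seed=int(raw.get("seed", 1)))
    except ValueError as exc:
        errors.append(f"langevin: {exc}")
        langevin = LangevinParams()

    pool_raw = dict(raw.get("pool", {}))
    pools = {}
    for level in ("low", "high"):
        spec = dict(pool_raw.get(level, {}))
        known = {f.name for f in dataclasses.fields(PoolConfig)}
        for key in spec:
            if key not in known:
                errors.append(f"pool.{level}: unknown key {key!r}")
        try:
            pools[level] = PoolConfig(**{k: v for k, v in spec.items() if k in known})
            if pools[level].run_length % pools[level].save_stride != 0:
                errors.append(
                    f"pool.{level}: run_length {pools[level].run_length} not divisible "
                    f"by save_stride {pools[level].save_stride}")
            if pools[level].start_distribution not in ("uniform", "boltzmann"):
                errors.append(
                    f"pool.{level}: unknown start_distribution "
                    f"{pools[level].start_distribution!r}")
        except TypeError as exc:
            errors.append(f"pool.{level}: {exc}")
            pools[level] = PoolConfig()
    for key in pool_raw:
        if key not in ("low", "high"):
            errors.append(f"pool: unknown key {key!r}")

    protos = []
    pool_size = 8 * (pools["low"].run_length // max(pools["low"].save_stride, 1))
    for i, spec in enumerate(raw.get("protocols", _DEFAULT_PROTOCOLS)):
        spec = dict(spec)
        for key in spec:
            if key not in ("name", "n_switch", "n_replicate"):
                errors.append(f"protocols[{i}]: unknown key {key!r}")
        try:
            pc = ProtocolConfig(name=str(spec["name"]), n_switch=int(spec["n_switch"]),
                                n_replicate=int(spec["n_replicate"]))
        except KeyError as exc:
            errors.append(f"protocols[{i}]: missing key {exc}")
            continue
        if pc.n_replicate % 8 != 0:
            errors.append(
                f"protocols[{i}] ({pc.name}): n_replicate {pc.n_replicate} "
                f"not divisible by 8")
        elif pool_size % pc.n_replicate != 0:
            errors.append(
                f"protocols[{i}] ({pc.name}): pool of {pool_size} snapshots "
                f"not divisible by n_replicate {pc.n_replicate}")
        protos.append(pc)
    if not protos:
        errors.append("protocols: at least one protocol required")

    reduced_from = reduced_keep = None
    if "reduced" in raw:
        red = dict(raw["reduced"])
        for key in red:
            if key not in ("from", "keep_per_block"):
                errors.append(f"reduced: unknown key {key!r}")
        reduced_from = red.get("from")
        reduced_keep = red.get("keep_per_block")
        if reduced_from is not None and reduced_from not in {p.name for p in protos}:
            errors.append(f"reduced.from: unknown protocol {reduced_from!r}")

    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(
        low=low, high=high, langevin=langevin,
        pool_low=pools["low"], pool_high=pools["high"], protocols=tuple(protos),
        seed=int(raw.get("seed", 1)), temperature=temperature,
        outlier_k=float(raw.get("outlier_k", 3.0)),
        dihedral_labels=tuple(raw.get("dihedral_labels", ("chi1",))),
        system=str(raw.get("system", "toy")),
        output_dir=str(raw.get("output_dir", "runs/experiment")),
        reduced_from=reduced_from,
        reduced_keep_per_block=None if reduced_keep is None else int(reduced_keep))


def load_config(path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
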