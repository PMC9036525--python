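"""Fixed-budget protocol comparison: the end-to-end experiment.

The central design question is whether, at a fixed total number of switching
steps, it is better to run many short switches or fewer longer ones.  A
protocol grid holds the product n_switch x n_replicate constant; for each
protocol the one-sided (Jarzynski) estimate from forward switches is compared
against the bidirectional Crooks/BAR reference -- and, on the toy system,
against the exact quadrature value.  The per-protocol deviation

    delta_delta_a = Delta A_JAR - Delta A_CRO

is summarised across systems by its mean absolute deviation (MAD) and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import build_quasi_time_series, outlier_impact
from .estimators import FreeEnergyEstimate, crooks_bar, jarzynski
from .io import RunConfig, write_workset
from .pca_analysis import feature_matrix, flag_by_dihedral, flag_by_work, loading_report, run_pca
from .switching import make_protocol, run_protocol, subsample_reduced
from .toy_system import MixedHamiltonian, build_restart_pool, exact_delta_a

__all__ = [
    "ComparisonCell",
    "SummaryStats",
    "ExperimentResult",
    "delta_delta_a",
    "summarize",
    "run_experiment",
    "stage_seeds",
]


@dataclass(frozen=True)
class ComparisonCell:
    """One (system, protocol) entry of the comparison grid."""

    system: str
    protocol: str
    delta_a_jar: float
    delta_a_cro: float
    delta_delta_a: float
    jar_uncertainty: float
    cro_uncertainty: float

    def __post_init__(self):
        if abs(self.delta_delta_a - (self.delta_a_jar - self.delta_a_cro)) > 1e-12:
            raise ValueError("delta_delta_a must equal delta_a_jar - delta_a_cro")


@dataclass(frozen=True)
class SummaryStats:
    """MAD and RMSE of delta_delta_a over systems, for one protocol."""

    protocol: str
    mad: float
    rmse: float
    n_systems: int


def delta_delta_a(jar: FreeEnergyEstimate, cro: FreeEnergyEstimate) -> float:
    """Deviation of the one-sided estimate from the bidirectional reference."""
    if jar.temperature != cro.temperature:
        raise ValueError(
            f"temperature mismatch: JAR at {jar.temperature} K, CRO at {cro.temperature} K")
    return jar.value - cro.value


def summarize(cells) -> list:
    """Per-protocol MAD = mean |dda| and RMSE = sqrt(mean dda^2) over systems."""
    cells = list(cells)
    if not cells:
        raise ValueError("no comparison cells to summarise")
    out = []
    for name in dict.fromkeys(c.protocol for c in cells):
        dda = np.array([c.delta_delta_a for c in cells if c.protocol == name])
        out.append(SummaryStats(protocol=name, mad=float(np.mean(np.abs(dda))),
                                rmse=float(np.sqrt(np.mean(dda ** 2))),
                                n_systems=dda.size))
    return out


def stage_seeds(master_seed: int, n: int) -> list:
    """Deterministic per-stage sub-seeds (< 2^31) from one master seed.

    Splitting goes through numpy's SeedSequence so any stage can be re-run
    in isolation from (master_seed, stage index).
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass
class ExperimentResult:
    """Everything the end-to-end run produces."""

    exact: float                     # quadrature Delta A, kcal/mol
    cells: list                      # ComparisonCell per protocol
    summary: list                    # SummaryStats per protocol
    estimates: dict                  # protocol -> {"jar": ..., "cro": ...}
    worksets: dict                   # (protocol, direction) -> WorkSet
    quasi_series: dict               # protocol -> QuasiTimeSeries (forward)
    outlier_impacts: dict            # protocol -> OutlierImpact (forward)
    cro_spread: float                # max pairwise |CRO difference| across protocols
    cro_spread_limit: float          # combined 3-sigma bound for that spread
    pca: "object | None"
    pca_features: "object | None"
    loading_table: "pd.DataFrame | None"
    run_dir: "Path | None"


def _write_outputs(result: ExperimentResult, config: RunConfig, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    for (name, direction), ws in result.worksets.items():
        write_workset(ws, run_dir / f"workset_{name}_{direction}.tsv")
    rows = [{"system": c.system, "protocol": c.protocol,
             "delta_a_jar": c.delta_a_jar, "delta_a_cro": c.delta_a_cro,
             "delta_delta_a": c.delta_delta_a,
             "jar_uncertainty": c.jar_uncertainty,
             "cro_uncertainty": c.cro_uncertainty} for c in result.cells]
    pd.DataFrame(rows).to_csv(run_dir / "cells.tsv", sep="\t", index=False)
    pd.DataFrame([{"protocol": s.protocol, "mad_kcal_mol": s.mad,
                   "rmse_kcal_mol": s.rmse, "n_systems": s.n_systems}
                  for s in result.summary]).to_csv(
        run_dir / "summary.tsv", sep="\t", index=False)
    for name, qts in result.quasi_series.items():
        pd.DataFrame({"global_index": qts.global_indices, "block": qts.blocks,
                      "work_kcal_mol": qts.works,
                      "is_outlier": np.isin(qts.global_indices, qts.outlier_indices)}
                     ).to_csv(run_dir / f"qts_{name}.tsv", sep="\t", index=False)
    with open(run_dir / "config_echo.yaml", "w") as fh:
        import yaml

        fh.write(yaml.safe_dump({
            "seed": config.seed, "temperature": config.temperature,
            "system": config.system, "outlier_k": config.outlier_k,
            "exact_delta_a": float(result.exact),
            "protocols": [{"name": p.name, "n_switch": p.n_switch,
                           "n_replicate": p.n_replicate} for p in config.protocols]}))
    if result.loading_table is not None:
        result.loading_table.to_csv(run_dir / "pca_loadings.tsv", sep="\t", index=False)


def run_experiment(config: RunConfig, run_dir=None, *, make_plots: bool = False,
                   n_bootstrap: int = 200) -> ExperimentResult:
    """Run the full fixed-budget comparison on one toy system.

    Stages: exact oracle -> equilibrium restart pools at both levels ->
    every protocol in both directions -> Jarzynski and Crooks/BAR estimates
    with bootstrap uncertainties -> delta_delta_a grid and MAD/RMSE summary
    -> quasi-time-series and outlier-impact diagnostics -> scaled PCA of the
    longest protocol's forward switches.  All artifacts are written under
    ``run_dir`` (default: ``config.output_dir``) with the configuration and
    seeds echoed; a failure aborts with the stage name while preserving
    whatever was already written.
    """
    seeds = stage_seeds(config.seed, 2 + 2 * len(config.protocols))
    mixed = MixedHamiltonian(config.low, config.high)
    stage = "exact oracle"
    try:
        exact = exact_delta_a(config.low, config.high, config.temperature)

        stage = "equilibrium pools"
        pool_low = build_restart_pool(
            config.low, replace(config.langevin, seed=seeds[0]), level="low",
            run_length=config.pool_low.run_length,
            save_stride=config.pool_low.save_stride,
            randomize_start=config.pool_low.randomize_start,
            start_distribution=config.pool_low.start_distribution,
            burn_in=config.pool_low.burn_in)
        pool_high = build_restart_pool(
            config.high, replace(config.langevin, seed=seeds[1]), level="high",
            run_length=config.pool_high.run_length,
            save_stride=config.pool_high.save_stride,
            randomize_start=config.pool_high.randomize_start,
            start_distribution=config.pool_high.start_distribution,
            burn_in=config.pool_high.burn_in)

        worksets, estimates, cells = {}, {}, []
        quasi, impacts = {}, {}
        for i, pc in enumerate(config.protocols):
            stage = f"protocol {pc.name}"
            proto_f = make_protocol(pc.name, pc.n_switch, pc.n_replicate,
                                    config.pool_size_low)
            proto_b = make_protocol(pc.name, pc.n_switch, pc.n_replicate,
                                    config.pool_size_high)
            ws_f = run_protocol(pool_low, proto_f, mixed, "forward",
                                replace(config.langevin, seed=seeds[2 + 2 * i]),
                                system=config.system)
            ws_b = run_protocol(pool_high, proto_b, mixed, "backward",
                                replace(config.langevin, seed=seeds[3 + 2 * i]),
                                system=config.system)
            worksets[(pc.name, "forward")] = ws_f
            worksets[(pc.name, "backward")] = ws_b
            jar = jarzynski(ws_f.works, config.temperature, n_bootstrap=n_bootstrap)
            cro = crooks_bar(ws_f.works, ws_b.works, config.temperature,
                             n_bootstrap=n_bootstrap)
            estimates[pc.name] = {"jar": jar, "cro": cro}
            dda = delta_delta_a(jar, cro)
            cells.append(ComparisonCell(
                system=config.system, protocol=pc.name, delta_a_jar=jar.value,
                delta_a_cro=cro.value, delta_delta_a=dda,
                jar_uncertainty=jar.uncertainty, cro_uncertainty=cro.uncertainty))
            quasi[pc.name] = build_quasi_time_series(ws_f, k=config.outlier_k)
            impacts[pc.name] = outlier_impact(ws_f, config.temperature,
                                              k=config.outlier_k, reference=cro.value,
                                              n_bootstrap=n_bootstrap)

        if config.reduced_from is not None and config.reduced_keep_per_block:
            stage = f"reduced protocol from {config.reduced_from}"
            base = worksets[(config.reduced_from, "forward")]
            ws_red = subsample_reduced(base, config.reduced_keep_per_block)
            worksets[(ws_red.protocol.name, "forward")] = ws_red
            jar = jarzynski(ws_red.works, config.temperature, n_bootstrap=n_bootstrap)
            cro = estimates[config.reduced_from]["cro"]
            estimates[ws_red.protocol.name] = {"jar": jar, "cro": cro}
            cells.append(ComparisonCell(
                system=config.system, protocol=ws_red.protocol.name,
                delta_a_jar=jar.value, delta_a_cro=cro.value,
                delta_delta_a=jar.value - cro.value,
                jar_uncertainty=jar.uncertainty, cro_uncertainty=cro.uncertainty))

        stage = "summary"
        summary = summarize(cells)
        cro_vals = [estimates[p.name]["cro"] for p in config.protocols]
        spread = max(abs(a.value - b.value) for a in cro_vals for b in cro_vals)
        limit = max(3.0 * np.hypot(a.uncertainty, b.uncertainty)
                    for a in cro_vals for b in cro_vals)

        stage = "pca"
        longest = max(config.protocols, key=lambda p: p.n_switch)
        feats = feature_matrix(worksets[(longest.name, "forward")],
                               dihedral_labels=config.dihedral_labels)
        try:
            pca = run_pca(feats, scaled=True)
        except ValueError:
            # degenerate input (a zero-variance column): covariance PCA still works
            pca = run_pca(feats, scaled=False)
        flag_by_work(feats, pca, k=config.outlier_k)
        table = loading_report(pca, top_components=min(2, pca.loadings.shape[1]))

        result = ExperimentResult(
            exact=exact, cells=cells, summary=summary, estimates=estimates,
            worksets=worksets, quasi_series=quasi, outlier_impacts=impacts,
            cro_spread=float(spread), cro_spread_limit=float(limit),
            pca=pca, pca_features=feats, loading_table=table, run_dir=None)

        if run_dir is None:
            run_dir = config.output_dir
        run_dir = Path(run_dir)
        stage = "write outputs"
        _write_outputs(result, config, run_dir)
        result.run_dir = run_dir
        if make_plots:
            stage = "plots"
            from . import plotting

            for name, qts in quasi.items():
                plotting.plot_quasi_time_series(qts, run_dir / f"qts_{name}.png")
            plotting.plot_pca(pca, feats, run_dir / "pca_scaled.png")
            plotting.plot_delta_vs_length(cells, config, run_dir / "dda_vs_length.png")
        return result
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage: {stage}") from exc
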