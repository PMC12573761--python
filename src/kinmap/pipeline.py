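"""End-to-end driver: simulate -> train -> build map -> rates (-> scan).

A single :class:`RunConfig` (YAML-serializable, unknown keys rejected)
drives all stages; every stochastic stage derives its seed from the
master seed, so a run is fully reproducible.  Stages are cached on a
content hash of their parameters and upstream artifacts: re-running an
unchanged config touches nothing and reproduces bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import features as feat
from .isokann import (ChiModel, IsokannConfig, NeuralRegressor, RBFRegressor,
                      isokann_fit, orient_chi)
from .kinetics import (cluster_weights, free_energy, pathway_rates,
                       rate_matrix, sensitivity_scan)
from .mkm import MKMGraph, build_mkm, enumerate_pathways, partition_by_chi
from .toy_dynamics import (EnsembleData, LangevinParams, four_well_potential,
                           harvest_ensemble, sample_long_trajectory)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config",
           "save_model", "load_model"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    system: Literal["four-well"] = "four-well"
    n_steps: int = 10_000_000
    timestep: float = 0.001
    temperature: float = 300.0
    friction: float = 1.0
    mass: float = 1.0
    initial: tuple[float, float] = (-1.0, 1.0)
    burn_in_fraction: float = 0.0
    n_states: int = 4000
    stride: int = 1000
    n_bursts: int = 10
    burst_steps: int = 10


class TrainConfig(_Strict):
    features: Literal["cartesian", "pairdist", "internal"] = "cartesian"
    regressor: Literal["net", "rbf"] = "net"
    max_iterations: int = 200
    epochs_per_iteration: int = 15
    batch_size: int = 100
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    validation_fraction: float = 0.2
    convergence_tol: float = 1e-3
    orientation_rule: Literal["energy-min", "none"] = "energy-min"


class MkmConfig(_Strict):
    n_intervals: int = 3
    epsilon: Union[float, list[float]] = 1.0
    theta: Union[int, list[int]] = 5
    r_n: float = 0.6
    metric: Literal["euclidean", "rmsd"] = "euclidean"
    min_shared: int = 1
    neighborhood_mode: Literal["members", "mean"] = "members"
    max_paths: int = 1000


class RatesConfig(_Strict):
    beta: float = 1.0  # energies in kT by default
    prefactor: float = 1.0


class ScanConfig(_Strict):
    n_intervals: list[int] = Field(default_factory=lambda: [2, 3, 4, 5, 6])
    epsilons: list[float] = Field(default_factory=lambda: [1.0])
    thetas: list[int] = Field(default_factory=lambda: [5])


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "kinmap-run"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)
    mkm: MkmConfig = Field(default_factory=MkmConfig)
    rates: RatesConfig = Field(default_factory=RatesConfig)
    scan: Optional[ScanConfig] = None
    figures: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def load_config(path: str | Path) -> RunConfig:
    try:
        return RunConfig.from_yaml(path)
    except ValidationError as exc:
        # surface unknown/invalid keys with their location
        raise ValueError(f"invalid run configuration: {exc}") from exc


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seeds: dict = Field(default_factory=dict)
    stage_keys: dict = Field(default_factory=dict)
    outputs: dict = Field(default_factory=dict)  # stage -> {file: sha256}
    cached: dict = Field(default_factory=dict)
    timestamps: dict = Field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls.model_validate_json(Path(path).read_text())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(params, upstream_hashes: Sequence[str]) -> str:
    blob = json.dumps([params, list(upstream_hashes)], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def save_model(path: str | Path, model: ChiModel, config: IsokannConfig,
               report) -> None:
    transform = model.feature_transform
    payload = {
        "regressor": model.regressor,
        "feature_kind": model.feature_kind,
        "orientation_flipped": model.orientation_flipped,
        "config": config,
        "report": report,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    del transform


_TRANSFORMS = {
    "cartesian": None,
    "pairdist": lambda x: np.stack([feat.pairwise_distances(c.reshape(-1, 3))
                                    for c in x]),
    "internal": lambda x: np.stack([feat.internal_coordinates(c.reshape(-1, 3))
                                    for c in x]),
}


def load_model(path: str | Path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    kind = payload["feature_kind"]
    model = ChiModel(
        regressor=payload["regressor"],
        feature_transform=_TRANSFORMS.get(kind),
        feature_kind=kind,
        orientation_flipped=payload["orientation_flipped"],
    )
    return model, payload["config"], payload["report"]


def _derive_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).generate_state(4)
    return {
        "trajectory": int(children[0] % 2**31),
        "bursts": int(children[1] % 2**31),
        "train": int(children[2] % 2**31),
    }


def run_pipeline(config: RunConfig, force: bool = False) -> RunManifest:
    """Execute all configured stages, reusing cached artifacts when the
    configuration and upstream artifacts are unchanged."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = None
    if manifest_path.exists() and not force:
        try:
            previous = RunManifest.load(manifest_path)
        except Exception:
            previous = None
    manifest = RunManifest()
    seeds = _derive_seeds(config.seed)
    manifest.seeds = dict(seeds)

    def finish_stage(stage: str, key: str, files: dict[str, Path]) -> None:
        manifest.stage_keys[stage] = key
        manifest.outputs[stage] = {f.name: _sha256(f) for f in files.values()}
        manifest.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def cached(stage: str, key: str, files: dict[str, Path]) -> bool:
        ok = (previous is not None
              and previous.stage_keys.get(stage) == key
              and all(f.exists() for f in files.values()))
        manifest.cached[stage] = bool(ok)
        return ok

    # ---- simulate -------------------------------------------------------
    sim = config.simulate
    potential = four_well_potential()
    params = LangevinParams(temperature=sim.temperature, mass=sim.mass,
                            friction=sim.friction, timestep=sim.timestep)
    ens_file = out / "ensemble.npz"
    key = _stage_key(sim.model_dump(), [str(seeds["trajectory"]), str(seeds["bursts"])])
    files = {"ensemble": ens_file}
    if not cached("simulate", key, files):
        logger.info("simulate: %d steps of %s", sim.n_steps, sim.system)
        traj = sample_long_trajectory(potential, params, sim.n_steps,
                                      np.asarray(sim.initial), seeds["trajectory"],
                                      burn_in_fraction=sim.burn_in_fraction)
        ensemble = harvest_ensemble(traj, sim.n_states, sim.stride,
                                    sim.n_bursts, sim.burst_steps,
                                    potential, params, seeds["bursts"])
        ensemble.save(ens_file)
        del traj
    ensemble = EnsembleData.load(ens_file)
    finish_stage("simulate", key, files)

    # ---- train ----------------------------------------------------------
    tr = config.train
    model_file = out / "model.pkl"
    chi_file = out / "chi.csv"
    iso_cfg = IsokannConfig(
        max_iterations=tr.max_iterations,
        epochs_per_iteration=tr.epochs_per_iteration,
        batch_size=tr.batch_size,
        learning_rate=tr.learning_rate,
        weight_decay=tr.weight_decay,
        validation_fraction=tr.validation_fraction,
        convergence_tol=tr.convergence_tol,
        seed=seeds["train"],
    )
    key = _stage_key(tr.model_dump(), [manifest.outputs["simulate"]["ensemble.npz"]])
    files = {"model": model_file, "chi": chi_file}
    if not cached("train", key, files):
        logger.info("train: ISOKANN with %s regressor", tr.regressor)
        regressor = NeuralRegressor(weight_decay=tr.weight_decay) \
            if tr.regressor == "net" else RBFRegressor(neighbors=64)
        model, report = isokann_fit(ensemble, regressor, iso_cfg,
                                    feature_transform=_TRANSFORMS[tr.features],
                                    feature_kind=tr.features)
        energies = potential.energy(ensemble.X0) \
            if tr.orientation_rule == "energy-min" else None
        model = orient_chi(model, ensemble, energies=energies,
                           rule=tr.orientation_rule)
        save_model(model_file, model, iso_cfg, report)
        chi = model.predict(ensemble.X0)
        np.savetxt(chi_file, np.column_stack([np.arange(len(chi)), chi]),
                   fmt=("%d", "%.8f"), delimiter=",", header="state,chi",
                   comments="")
        losses = np.column_stack([report.train_loss, report.validation_loss])
        np.savetxt(out / "losses.csv", losses, delimiter=",",
                   header="train_loss,validation_loss", comments="")
    model, _, report = load_model(model_file)
    chi = np.loadtxt(chi_file, delimiter=",", skiprows=1, usecols=1)
    finish_stage("train", key, files)

    # ---- build-mkm ------------------------------------------------------
    mk = config.mkm
    graph_file = out / "graph.json"
    graphml_file = out / "graph.graphml"
    key = _stage_key(mk.model_dump(), [manifest.outputs["train"]["chi.csv"]])
    files = {"graph": graph_file, "graphml": graphml_file}
    if not cached("build-mkm", key, files):
        logger.info("build-mkm: N_I=%d", mk.n_intervals)
        partition = partition_by_chi(chi, mk.n_intervals)
        graph = build_mkm(ensemble.X0, chi, partition,
                          epsilon=mk.epsilon, theta=mk.theta, r_n=mk.r_n,
                          metric=mk.metric, min_shared=mk.min_shared,
                          neighborhood_mode=mk.neighborhood_mode)
        graph.save_json(graph_file)
        graph.save_graphml(graphml_file)
    graph = MKMGraph.load_json(graph_file)
    finish_stage("build-mkm", key, files)

    # ---- rates ----------------------------------------------------------
    rt = config.rates
    nodes_file = out / "nodes.csv"
    paths_file = out / "pathways.csv"
    key = _stage_key(rt.model_dump(), [manifest.outputs["build-mkm"]["graph.json"]])
    files = {"nodes": nodes_file, "pathways": paths_file}
    if not cached("rates", key, files):
        import pandas as pd

        weights = cluster_weights(graph)
        profile = free_energy(weights, beta=rt.beta, graph=graph)
        rows = [{"node": int(i), "interval": graph.nodes[i].interval,
                 "mean_chi": graph.nodes[i].mean_chi,
                 "pi": weights.of(i),
                 "free_energy": float(profile.energy[list(profile.node_ids).index(i)])}
                for i in weights.node_ids]
        pd.DataFrame(rows).to_csv(nodes_file, index=False)
        pathways = enumerate_pathways(graph, max_paths=mk.max_paths)
        prow = []
        for p in pathways:
            fwd, rev = pathway_rates(p, weights, graph, rt.prefactor)
            prow.append({"nodes": "-".join(map(str, p.nodes)),
                         "forward_rate": fwd, "reverse_rate": rev})
        pd.DataFrame(prow, columns=["nodes", "forward_rate", "reverse_rate"]) \
            .to_csv(paths_file, index=False)
    finish_stage("rates", key, files)

    # ---- scan (optional) ------------------------------------------------
    if config.scan is not None:
        sc = config.scan
        scan_file = out / "scan.csv"
        key = _stage_key(sc.model_dump(), [manifest.outputs["train"]["chi.csv"]])
        files = {"scan": scan_file}
        if not cached("scan", key, files):
            logger.info("scan: %d grid points",
                        len(sc.n_intervals) * len(sc.epsilons) * len(sc.thetas))
            table = sensitivity_scan(ensemble.X0, chi, sc.n_intervals,
                                     sc.epsilons, sc.thetas, r_n=mk.r_n,
                                     metric=mk.metric)
            table.to_csv(scan_file, index=False)
        finish_stage("scan", key, files)

    # ---- figures (optional) --------------------------------------------
    if config.figures:
        from .plotting import export_figures

        key = _stage_key({"figures": True},
                         [manifest.outputs["build-mkm"]["graph.json"]])
        expected = {name: out / f"{name}.svg"
                    for name in ("chi_scatter", "mkm", "profiles")}
        if not cached("figures", key, expected):
            weights = cluster_weights(graph)
            pathways = enumerate_pathways(graph, max_paths=mk.max_paths)
            written = export_figures(out, states=ensemble.X0, chi=chi,
                                     graph=graph, weights=weights,
                                     pathways=pathways, beta=rt.beta)
            expected = {p.stem: p for p in written}
        finish_stage("figures", key, expected)

    manifest.save(manifest_path)
    return manifest
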