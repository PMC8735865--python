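"""Experiment orchestration: datasets, agent groups, presets, manifests.

The helpers here tie the environments, agents, training, and analyses into
reproducible experiments.  Scale factors shrink replicate counts and
dataset sizes only — never the sequence length, the architecture sizes, or
the environment statistics, which would change the science rather than the
precision of its estimates.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environments import EnvironmentConfig, generate_batch
from .heuristics import SGDConfig, fit_heuristic, run_heuristic
from .hyperparameters import HEURISTIC_SGD_LEARNING_RATE, load_hyperparameters
from .networks import NetworkParameters, forward_batch, initialize_network
from .optimal import run_optimal_batch
from .training import TrainerConfig, TrainingResult, train_network
from .analyses.performance import (
    PerformanceReport,
    chance_log_likelihood,
    group_performance,
    trace_log_likelihood,
)

__all__ = [
    "AgentSpec",
    "ExperimentConfig",
    "RunManifest",
    "make_training_data",
    "train_group",
    "evaluate_group",
    "preset",
    "PRESET_NAMES",
    "run_experiment",
]

MINIBATCH_SIZE = 20
TRAIN_MINIBATCHES = {"unigram": 160, "bigram": 400}
TEST_SEQUENCES = 1000

# seed offsets separating the independent random streams of one experiment
_TRAIN_DATA_OFFSET = 1
_TEST_DATA_OFFSET = 2
_AGENT_OFFSET = 3


@dataclass(frozen=True)
class AgentSpec:
    kind: str  # "network" | "heuristic"
    arch: str = "gated"  # network architecture, or "<rule>_<scope>" for heuristics
    n_units: int = 11
    replicates: int = 20


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    environment: EnvironmentConfig
    agents: tuple[AgentSpec, ...]
    train_minibatches: int
    test_sequences: int
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    package_version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)  # path -> sha256
    agents: list = field(default_factory=list)
    incomplete: list = field(default_factory=list)


def _env_key(structure: str) -> str:
    return "unigram" if structure == "unigram" else "bigram"


def make_training_data(
    structure: str, n_minibatches: int, seed: int, minibatch_size: int = MINIBATCH_SIZE
) -> np.ndarray:
    cfg = EnvironmentConfig(structure=structure, seed=seed)
    return generate_batch(cfg, n_minibatches * minibatch_size)


def train_group(
    structure: str,
    arch: str,
    n_units: int,
    n_replicates: int,
    train_sequences: np.ndarray,
    base_seed: int,
) -> list[TrainingResult]:
    """Train ``n_replicates`` networks differing only in their random seed.

    The seed changes the parameter initialisation and the shuffling of the
    shared training data.
    """
    hp = load_hyperparameters(_env_key(structure), arch, n_units)
    results = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([base_seed, rep])
        params = initialize_network(arch, n_units, hp.sigma0_x, hp.sigma0_h, hp.mu0_diag, rng)
        results.append(
            train_network(params, train_sequences, TrainerConfig(learning_rate=hp.eta0), rng)
        )
    return results


def evaluate_group(
    param_list: list[NetworkParameters],
    test_sequences: np.ndarray,
    config: EnvironmentConfig,
) -> PerformanceReport:
    """% of optimal log likelihood of each network on a shared test set."""
    opt = run_optimal_batch(test_sequences, config)
    L_optimal = float(np.sum(opt.log_likelihood))
    L_chance = chance_log_likelihood(test_sequences)
    lls = []
    for params in param_list:
        preds, _ = forward_batch(params, test_sequences)
        lls.append(float(np.sum(trace_log_likelihood(preds, test_sequences))))
    return group_performance(np.asarray(lls), L_optimal, L_chance)


PRESET_NAMES = (
    "fig2-performance",
    "fig3-learning-rate",
    "fig4-readout",
    "fig5-perturbation",
    "fig6-bigram",
    "fig7-higher-level",
    "fig8-complexity",
)

_NETWORK_ARCHS = ("gated", "no_gating", "no_lateral", "frozen_recurrence")
_HEURISTICS = ("delta_unigram", "leaky_unigram")
_HEURISTICS_BIGRAM = ("delta_unigram", "leaky_unigram", "delta_bigram", "leaky_bigram")


def preset(name: str, scale: float = 1.0, seed: int = 0) -> ExperimentConfig:
    """Full-scale experiment configuration; ``scale`` shrinks replicates and datasets."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")

    def s(n: int, floor: int = 1) -> int:
        return max(floor, int(round(n * scale)))

    structure = "unigram"
    agents: tuple[AgentSpec, ...]
    if name in ("fig2-performance", "fig3-learning-rate"):
        agents = tuple(
            AgentSpec("network", a, 11, s(20, 2)) for a in _NETWORK_ARCHS
        ) + tuple(AgentSpec("heuristic", h, 0, s(20, 2)) for h in _HEURISTICS)
    elif name in ("fig4-readout", "fig5-perturbation"):
        agents = (AgentSpec("network", "gated", 11, s(20, 2)),)
        if name == "fig5-perturbation":
            agents = tuple(AgentSpec("network", a, 11, s(20, 2)) for a in _NETWORK_ARCHS)
    elif name == "fig6-bigram":
        structure = "bigram_independent"
        agents = tuple(
            AgentSpec("network", a, 11, s(20, 2)) for a in _NETWORK_ARCHS
        ) + tuple(AgentSpec("heuristic", h, 0, s(20, 2)) for h in _HEURISTICS_BIGRAM)
    elif name == "fig7-higher-level":
        structure = "bigram_coupled"
        agents = tuple(AgentSpec("network", a, 11, s(20, 2)) for a in _NETWORK_ARCHS)
    else:  # fig8-complexity
        structure = "unigram"
        agents = tuple(AgentSpec("network", a, 11, s(20, 2)) for a in _NETWORK_ARCHS)

    env = EnvironmentConfig(structure=structure, seed=seed + _TRAIN_DATA_OFFSET)
    return ExperimentConfig(
        name=name,
        environment=env,
        agents=agents,
        train_minibatches=s(TRAIN_MINIBATCHES[_env_key(structure)], 5),
        test_sequences=s(TEST_SEQUENCES, 50),
        seed=seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Generate data, train the roster, evaluate performance, write tables.

    Writes, under ``config.output_dir / config.name``: the dataset manifest
    (YAML), a per-agent performance table (CSV), and the run manifest
    (JSON) listing every output with a content checksum.  Failures of
    individual agents are recorded and do not abort the run.
    """
    out = Path(config.output_dir) / config.name
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    structure = config.environment.structure

    train_seqs = make_training_data(
        structure, config.train_minibatches, config.seed + _TRAIN_DATA_OFFSET
    )
    test_cfg = EnvironmentConfig(structure=structure, seed=config.seed + _TEST_DATA_OFFSET)
    test_seqs = generate_batch(test_cfg, config.test_sequences)

    dataset_manifest = {
        "environment": asdict(config.environment),
        "train_sequences": int(train_seqs.shape[0]),
        "test_sequences": int(test_seqs.shape[0]),
        "test_seed": config.seed + _TEST_DATA_OFFSET,
    }
    ds_path = out / "datasets.yaml"
    ds_path.write_text(yaml.safe_dump(dataset_manifest, sort_keys=True))

    opt = run_optimal_batch(test_seqs, config.environment)
    L_optimal = float(np.sum(opt.log_likelihood))
    L_chance = chance_log_likelihood(test_seqs)

    rows = []
    for spec in config.agents:
        for rep in range(spec.replicates):
            agent_seed = [config.seed + _AGENT_OFFSET, zlib.crc32(spec.arch.encode()) % (2**16), rep]
            rng = np.random.default_rng(agent_seed)
            t0 = time.time()
            try:
                if spec.kind == "network":
                    hp = load_hyperparameters(_env_key(structure), spec.arch, spec.n_units)
                    params = initialize_network(
                        spec.arch, spec.n_units, hp.sigma0_x, hp.sigma0_h, hp.mu0_diag, rng
                    )
                    result = train_network(
                        params, train_seqs, TrainerConfig(learning_rate=hp.eta0), rng
                    )
                    preds, _ = forward_batch(result.params, test_seqs)
                    final_loss = float(result.loss_curve[-1])
                elif spec.kind == "heuristic":
                    rule, scope = spec.arch.split("_")
                    fitted = fit_heuristic(
                        rule, scope, train_seqs,
                        SGDConfig(learning_rate=HEURISTIC_SGD_LEARNING_RATE), rng,
                    )
                    preds = np.stack(
                        [run_heuristic(fitted, x).predictions for x in test_seqs]
                    )
                    final_loss = float("nan")
                else:
                    raise ValueError(f"unknown agent kind {spec.kind!r}")
                L = float(np.sum(trace_log_likelihood(preds, test_seqs)))
                pct = (L - L_chance) / (L_optimal - L_chance) * 100.0
                rows.append(
                    {"kind": spec.kind, "arch": spec.arch, "replicate": rep,
                     "log_likelihood": L, "percent_optimal": pct,
                     "final_train_loss": final_loss, "seconds": time.time() - t0}
                )
                manifest.agents.append(
                    {"arch": spec.arch, "replicate": rep, "seed": agent_seed,
                     "percent_optimal": pct}
                )
            except (FloatingPointError, ValueError) as exc:
                manifest.incomplete.append(
                    {"arch": spec.arch, "replicate": rep, "error": str(exc)}
                )

    outputs = [ds_path]
    if rows:
        perf_path = out / "performance.csv"
        pd.DataFrame(rows).drop(columns=["seconds"]).to_csv(perf_path, index=False)
        outputs.append(perf_path)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.outputs = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {k: v for k, v in manifest.__dict__.items() if k not in ("started", "finished")}
            | {"started": manifest.started, "finished": manifest.finished},
            indent=2,
            default=str,
        )
    )
    return manifest
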