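"""Training driver: alternate play and train phases from a YAML config.

The config has four sections — ``environment``, ``network``, ``training``
and ``play`` — every key of which is optional and defaults to the values
documented on the corresponding dataclasses.  Each run writes one manifest
(JSON) with the full config echo, seeds, per-round metrics, and checkpoint
paths; reruns with the same config and seeds reproduce the metric trail
exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .environment import DesignTarget, NussinovPredictor
from .fixtures import make_fold_derived_targets, random_hairpins
from .qnet import QNetwork, QNetworkConfig
from .structures import read_structures
from .training import (
    AdamOptimizer,
    TrainingConfig,
    play_episodes,
    sync_target,
    train_epoch,
    write_episodes,
)

logger = logging.getLogger(__name__)

_SECTIONS = ("environment", "network", "training", "play")


class ConfigError(ValueError):
    """Raised when the run config fails schema validation."""


def load_config(path: str) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"version"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    cfg = {s: dict(raw.get(s) or {}) for s in _SECTIONS}
    cfg["version"] = raw.get("version", 1)
    play_defaults = {
        "rounds": 30,
        "epsilon": 0.5,
        "epsilon_end": 0.05,  # None keeps epsilon constant across rounds
        "seed": 0,
        "targets": "hairpins",     # hairpins | fold_derived | a structure file path
        "n_targets": 50,
        "target_length": 20,
        "target_seed": 0,
        "use_shape": False,
        "save_episodes": False,
    }
    bad = set(cfg["play"]) - set(play_defaults)
    if bad:
        raise ConfigError(f"unknown play keys: {sorted(bad)}")
    cfg["play"] = {**play_defaults, **cfg["play"]}
    env_defaults = {"min_loop": 3, "noise_sd": 0.0, "seed": 0, "fold_threshold": 0.5}
    bad = set(cfg["environment"]) - set(env_defaults)
    if bad:
        raise ConfigError(f"unknown environment keys: {sorted(bad)}")
    cfg["environment"] = {**env_defaults, **cfg["environment"]}
    try:
        QNetworkConfig(**cfg["network"])
        TrainingConfig(**cfg["training"])
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def _make_targets(play_cfg: dict, min_loop: int) -> list[DesignTarget]:
    kind = play_cfg["targets"]
    n, length, seed = play_cfg["n_targets"], play_cfg["target_length"], play_cfg["target_seed"]
    if kind == "hairpins":
        structures = random_hairpins(n, length, seed=seed)
        return [DesignTarget(s, name=f"hairpin_{i}") for i, s in enumerate(structures)]
    if kind == "fold_derived":
        derived = make_fold_derived_targets(n, length, seed=seed, min_loop=min_loop)
        return [DesignTarget(s, name=f"derived_{i}") for i, (_, s) in enumerate(derived)]
    records = read_structures(kind)
    return [DesignTarget(s, name=name) for name, s in records]


def epsilon_schedule(rounds: int, start: float, end: float | None) -> list[float]:
    """Linear exploration decay across rounds; constant when ``end`` is None.

    Within each play phase epsilon is a single constant; the schedule lives
    here in the driver.
    """
    if end is None or rounds == 1:
        return [start] * rounds
    return [start + (end - start) * r / (rounds - 1) for r in range(rounds)]


def train_curriculum(
    network: QNetwork,
    env,
    targets: list[DesignTarget],
    train_cfg: TrainingConfig,
    rounds: int = 30,
    epsilon_start: float = 0.5,
    epsilon_end: float | None = 0.05,
    play_seed: int = 0,
    use_shape: bool = False,
    fold_threshold: float = 0.5,
) -> list[dict]:
    """Alternate play and train phases in place; returns per-round metrics.

    Each round plays one episode per target at that round's epsilon, runs
    ``train_cfg.train_passes`` gradient passes over the fresh episodes, and
    syncs the target network every ``target_sync_epochs`` rounds.
    """
    frozen = network.copy()
    optimizer = AdamOptimizer(train_cfg.learning_rate, train_cfg.grad_clip)
    history: list[dict] = []
    for rnd, eps in enumerate(epsilon_schedule(rounds, epsilon_start, epsilon_end)):
        episodes, mean_reward = play_episodes(
            network, env, targets, epsilon=eps,
            seed=(play_seed * 100003 + rnd) % (2**31),
            use_shape=use_shape, fold_threshold=fold_threshold,
        )
        loss = float("nan")
        for _ in range(train_cfg.train_passes):
            loss = train_epoch(network, frozen, episodes, train_cfg, optimizer)
        if (rnd + 1) % train_cfg.target_sync_epochs == 0:
            sync_target(network, frozen)
        logger.info(
            "phase=round round=%d epsilon=%.3f mean_reward=%.4f mean_loss=%.4f",
            rnd, eps, mean_reward, loss,
        )
        history.append(
            {"round": rnd, "epsilon": eps, "mean_reward": float(mean_reward),
             "mean_loss": float(loss)}
        )
    return history


def run_train(config_path: str, run_dir: str, resume_from: str | None = None) -> dict:
    """Run the alternating play/train loop; returns the manifest dict."""
    cfg = load_config(config_path)
    out = Path(run_dir)
    out.mkdir(parents=True, exist_ok=True)

    net_cfg = QNetworkConfig(**cfg["network"])
    train_cfg = TrainingConfig(**cfg["training"])
    env = NussinovPredictor(
        min_loop=cfg["environment"]["min_loop"],
        noise_sd=cfg["environment"]["noise_sd"],
        seed=cfg["environment"]["seed"],
    )
    targets = _make_targets(cfg["play"], cfg["environment"]["min_loop"])

    start_round = 0
    if resume_from is not None:
        network = QNetwork.load(resume_from, expected_config=net_cfg)
        prev = json.loads((Path(resume_from).parent / "manifest.json").read_text())
        start_round = len(prev["rounds"])
    else:
        network = QNetwork(net_cfg)
    frozen = network.copy()
    optimizer = AdamOptimizer(train_cfg.learning_rate, train_cfg.grad_clip)

    manifest: dict = {
        "version": "rnaqdesign-1",
        "config": cfg,
        "network": asdict(net_cfg),
        "training": asdict(train_cfg),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_targets": len(targets),
        "rounds": [],
    }
    play_cfg = cfg["play"]
    epsilons = epsilon_schedule(
        start_round + play_cfg["rounds"], play_cfg["epsilon"], play_cfg["epsilon_end"]
    )
    for rnd in range(start_round, start_round + play_cfg["rounds"]):
        episodes, mean_reward = play_episodes(
            network,
            env,
            targets,
            epsilon=epsilons[rnd],
            seed=(play_cfg["seed"] * 100003 + rnd) % (2**31),
            use_shape=play_cfg["use_shape"],
            fold_threshold=cfg["environment"]["fold_threshold"],
        )
        if play_cfg["save_episodes"]:
            write_episodes(str(out / f"episodes_round{rnd:03d}.tsv"), episodes)
        loss = np.nan
        for _ in range(train_cfg.train_passes):
            loss = train_epoch(network, frozen, episodes, train_cfg, optimizer)
        if (rnd + 1) % train_cfg.target_sync_epochs == 0:
            sync_target(network, frozen)
        ckpt = out / f"checkpoint_round{rnd:03d}.npz"
        network.save(str(ckpt))
        logger.info(
            "phase=round round=%d mean_reward=%.4f mean_loss=%.4f", rnd, mean_reward, loss
        )
        manifest["rounds"].append(
            {"round": rnd, "mean_reward": float(mean_reward), "mean_loss": float(loss)}
        )

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["final_checkpoint"] = str(out / f"checkpoint_round{start_round + play_cfg['rounds'] - 1:03d}.npz")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "config_echo.yaml").write_text(yaml.safe_dump(cfg))
    return manifest
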