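"""Plain-text interchange: run configs (YAML), episode traces and summary
tables (delimited text), and parameter checkpoints (array container plus a
JSON manifest)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import AgentConfig


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def agent_config_from_dict(d: dict) -> AgentConfig:
    known = {k: v for k, v in d.items()
             if k in AgentConfig.__dataclass_fields__}
    return AgentConfig(**known)


def write_episode_trace(path, rows) -> None:
    """One row per step: trial id, step, row, col, orientation, action,
    reward, done."""
    df = pd.DataFrame(rows, columns=["trial", "step", "row", "col",
                                     "orientation", "action", "reward",
                                     "done"])
    df.to_csv(path, sep="\t", index=False)


def read_episode_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_checkpoint(path, snapshot: dict, config: AgentConfig,
                    meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             theta=snapshot["theta"], theta_tgt=snapshot["theta_tgt"],
             opt_m=snapshot["opt"]["m"], opt_v=snapshot["opt"]["v"])
    manifest = {"opt_t": int(snapshot["opt"]["t"]),
                "update_count": int(snapshot["update_count"]),
                "config": {k: getattr(config, k)
                           for k in config.__dataclass_fields__},
                "meta": meta or {}}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_rate_tensor(rates_path, labels_path):
    """Reader for externally supplied trials x neurons x time firing-rate
    arrays (``.npy``) with a tab-delimited label sidecar carrying
    ``strategy`` (0-3) and ``decision`` (0/1) columns — the drop-in
    substitute for the synthetic generator's output."""
    rates = np.load(rates_path)
    labels = pd.read_csv(labels_path, sep="\t")
    if rates.ndim != 3:
        raise ValueError("rate tensor must be trials x neurons x time")
    if len(labels) != rates.shape[0]:
        raise ValueError("label sidecar length does not match trials")
    for col in ("strategy", "decision"):
        if col not in labels.columns:
            raise ValueError(f"label sidecar missing column {col!r}")
    return rates, labels


def save_condition_tensor(path, tensor) -> None:
    """Condition tensor + axis labels as an array container (.npz) with a
    JSON sidecar naming the axes."""
    from .demixing import STRATEGY_LEVELS, DECISION_LEVELS
    path = Path(path)
    np.savez(path.with_suffix(".npz"), data=tensor.data,
             counts=tensor.counts, missing=tensor.missing)
    path.with_suffix(".json").write_text(json.dumps({
        "axes": ["unit", "strategy", "decision", "time_bin"],
        "strategy_levels": list(STRATEGY_LEVELS),
        "decision_levels": list(DECISION_LEVELS)}, indent=1))


def load_condition_tensor(path):
    from .demixing import ConditionTensor
    arrs = np.load(Path(path).with_suffix(".npz"))
    return ConditionTensor(data=arrs["data"], counts=arrs["counts"],
                           missing=arrs["missing"])


def read_trajectory_table(path) -> list:
    """Reader for externally supplied discretized trajectories (columns:
    trial, step, row, col), returning the episode dicts the behaviour
    profiles consume."""
    df = pd.read_csv(path, sep="\t")
    episodes = []
    for _, grp in df.groupby("trial"):
        grp = grp.sort_values("step")
        episodes.append({"positions": [(int(r), int(c)) for r, c in
                                       zip(grp["row"], grp["col"])]})
    return episodes


def load_checkpoint(path):
    path = Path(path)
    arrs = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    snapshot = {"theta": arrs["theta"], "theta_tgt": arrs["theta_tgt"],
                "opt": {"m": arrs["opt_m"], "v": arrs["opt_v"],
                        "t": manifest["opt_t"]},
                "update_count": manifest["update_count"]}
    return snapshot, agent_config_from_dict(manifest["config"]), manifest
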