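"""Persistence of experiment results: HDF5 container plus tidy CSV sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import ExperimentConfig, validate_config
from .experiments import ResultsBundle

__all__ = ["save_results", "load_results", "save_edge_list", "load_edge_list"]


def save_edge_list(path, pre, post, weight, delay_ms=1.0) -> None:
    """Write a weight matrix block as an edge-list CSV (pre, post, weight, delay)."""
    n = len(pre)
    pd.DataFrame(
        {
            "pre": np.asarray(pre, np.int64),
            "post": np.asarray(post, np.int64),
            "weight": np.asarray(weight, float),
            "delay_ms": np.broadcast_to(np.asarray(delay_ms, float), (n,)),
        }
    ).to_csv(path, index=False)


def load_edge_list(path) -> pd.DataFrame:
    """Read an edge-list CSV written by :func:`save_edge_list`."""
    df = pd.read_csv(path)
    missing = {"pre", "post", "weight", "delay_ms"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list is missing columns: {sorted(missing)}")
    return df


def save_results(bundle: ResultsBundle, outdir) -> Path:
    """Write a ResultsBundle to ``outdir`` (HDF5 + CSVs); returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        json_to_yaml(bundle.config.model_dump())
    )
    with h5py.File(outdir / "results.h5", "w") as h5:
        h5.attrs["task"] = bundle.task
        h5.attrs["config_json"] = json.dumps(bundle.config.model_dump())
        if bundle.outcomes is not None:
            h5.create_dataset("outcomes", data=np.asarray(bundle.outcomes, float))
        if bundle.accuracies:
            grp = h5.create_group("accuracies")
            for gate, (pre, post) in bundle.accuracies.items():
                grp.create_dataset(gate, data=np.array([pre, post]))
        if bundle.spike_stats:
            grp = h5.create_group("spike_stats")
            for k, v in bundle.spike_stats.items():
                grp.attrs[k] = float(v)
        wgrp = h5.create_group("weights")
        for k, v in bundle.weights.items():
            wgrp.create_dataset(k, data=np.asarray(v))
    if bundle.outcomes is not None:
        pd.DataFrame({"trial": np.arange(len(bundle.outcomes)),
                      "outcome": bundle.outcomes}).to_csv(
            outdir / "outcomes.csv", index=False
        )
    if bundle.accuracies:
        rows = [
            {"gate": g, "pre": pre, "post": post}
            for g, (pre, post) in bundle.accuracies.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "accuracies.csv", index=False)
    return outdir


def load_results(outdir) -> ResultsBundle:
    """Read a ResultsBundle previously written by :func:`save_results`."""
    outdir = Path(outdir)
    with h5py.File(outdir / "results.h5", "r") as h5:
        cfg = ExperimentConfig(**json.loads(h5.attrs["config_json"]))
        bundle = ResultsBundle(config=cfg, task=str(h5.attrs["task"]))
        if "outcomes" in h5:
            bundle.outcomes = h5["outcomes"][...]
        if "accuracies" in h5:
            bundle.accuracies = {
                g: tuple(h5["accuracies"][g][...]) for g in h5["accuracies"]
            }
        if "spike_stats" in h5:
            bundle.spike_stats = dict(h5["spike_stats"].attrs)
        bundle.weights = {k: h5["weights"][k][...] for k in h5.get("weights", {})}
    return bundle


def json_to_yaml(data: dict) -> str:
    import yaml

    return yaml.safe_dump(data, sort_keys=False)
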