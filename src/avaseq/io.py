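"""Delimited-text and JSON interchange for all pipeline artifacts.

Spike tables are two-column delimited text (neuron_id, time_s); trajectories
are (time_s, x_m, y_m).  Models (VLMC, AIM, transition chains) round-trip
through JSON exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AIMModel, ConditionalLogLikMatrix, EnrichmentResult
from .parsing import AvalancheSet, BurstSequence, SpikeEnsemble
from .run_optimal import TransitionChain
from .vlmc import VLMCModel


def write_spike_table(ensemble: SpikeEnsemble, path: str | Path, sep: str = "\t") -> None:
    rows = []
    for nid in sorted(ensemble.spike_times):
        for t in ensemble.spike_times[nid]:
            rows.append((nid, t))
    df = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    df.to_csv(path, sep=sep, index=False, float_format="%.9f")


def read_spike_table(path: str | Path, sep: str | None = None, epoch: str = "POST") -> SpikeEnsemble:
    """Read a delimited (neuron_id, time_s) table; header detected, rows validated."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep or r"\s+|,|\t", engine="python", header=None,
                     comment="#")
    # header detection: first row non-numeric
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    try:
        ids = df.iloc[:, 0].astype(int).to_numpy()
        times = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        bad = df[pd.to_numeric(df.iloc[:, 1], errors="coerce").isna()].index
        lines = ", ".join(str(i + 1) for i in bad[:5])
        raise ValueError(f"{path}: malformed rows at lines {lines}") from exc
    spikes: dict[int, list[float]] = {}
    for nid, t in zip(ids, times):
        spikes.setdefault(int(nid), []).append(float(t))
    out = {}
    for nid, ts in spikes.items():
        arr = np.array(ts)
        if np.any(np.diff(arr) < 0):
            warnings.warn(f"{path}: unsorted times for neuron {nid}; sorting")
            arr = np.sort(arr)
        out[nid] = arr
    return SpikeEnsemble(out, epoch=epoch)


def write_trajectory(trajectory: np.ndarray, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(trajectory, columns=["time_s", "x_m", "y_m"]).to_csv(
        path, sep=sep, index=False, float_format="%.9f")


def read_trajectory(path: str | Path, sep: str | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep=sep or r"\s+|,|\t", engine="python", header=None,
                     comment="#")
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    return df.iloc[:, :3].astype(float).to_numpy()


def write_burst_sequence(seq: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(" ".join(str(int(s)) for s in seq) + "\n")


def read_burst_sequence(path: str | Path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.array([int(s) for s in text], dtype=np.int64)


def write_word_table(avalanches: AvalancheSet, burst_seq: BurstSequence,
                     path: str | Path) -> None:
    rows = []
    for i, (av, (a, b)) in enumerate(zip(avalanches.avalanches, burst_seq.word_spans)):
        word = " ".join(str(int(s)) for s in burst_seq.symbols[a:b])
        start_s = avalanches.t0 + av.start_bin * avalanches.bin_width_s
        rows.append((i, start_s, av.size, word))
    pd.DataFrame(rows, columns=["index", "start_s", "size", "word"]).to_csv(
        path, sep="\t", index=False)


def write_enrichment_table(results: list[EnrichmentResult], path: str | Path) -> None:
    rows = [
        ("-".join(map(str, r.sequence)), r.likelihood_ratio, r.log2_ratio,
         r.z, r.p_value, r.significant)
        for r in results
    ]
    pd.DataFrame(rows, columns=["sequence", "L", "l", "z", "p", "significant"]).to_csv(
        path, sep="\t", index=False)


def write_loglik_matrix(R: ConditionalLogLikMatrix, path: str | Path) -> None:
    df = pd.DataFrame(R.values, index=R.context_labels(),
                      columns=[str(j) for j in range(R.alphabet_size)])
    df.to_csv(path, sep="\t", index_label="context")


def write_network(G: nx.DiGraph, edge_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    rows = [(u, v, d.get("weight", 1.0), d.get("run_order", False))
            for u, v, d in G.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "weight", "run_order"]).to_csv(
        edge_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)


_MODEL_TYPES = {"vlmc": VLMCModel, "aim": AIMModel, "chain": TransitionChain}


def serialize_model(model, path: str | Path) -> None:
    for tag, cls in _MODEL_TYPES.items():
        if isinstance(model, cls):
            payload = {"type": tag, "model": model.to_dict()}
            Path(path).write_text(json.dumps(payload, indent=1))
            return
    raise TypeError(f"cannot serialize {type(model).__name__}")


def deserialize_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    cls = _MODEL_TYPES[payload["type"]]
    return cls.from_dict(payload["model"])
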