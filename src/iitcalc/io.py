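"""JSON and CSV interchange for networks, repertoires and reports.

Network JSON schema::

    {"labels": [...],
     "cm": [[0/1, ...], ...],            # cm[i][j] = 1 iff i inputs to j
     "gates": [{"kind": "...", "weights": [...], "threshold": x,
                "table": [...]}, ...],
     "state": [0/1, ...]}                # optional current state

TPM CSV files are state-by-node: one column per node (header row of labels),
one row per past network state in little-endian order, entries are the
probability of the column's node being ON at the next step.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    STATE_ORDER,
    GateSpec,
    Network,
    NetworkError,
    all_states,
    build_network,
)
from .repertoires import Repertoire


def network_to_dict(net: Network, state=None) -> dict:
    gates = []
    for g in net.gates:
        entry: dict = {"kind": g.kind}
        if g.weights is not None:
            entry["weights"] = list(g.weights)
        if g.threshold is not None:
            entry["threshold"] = g.threshold
        if g.table is not None:
            entry["table"] = list(g.table)
        gates.append(entry)
    out = {
        "state_ordering": STATE_ORDER,
        "labels": list(net.labels),
        "cm": net.cm.astype(int).tolist(),
        "gates": gates,
    }
    if state is not None:
        out["state"] = [int(v) for v in state]
    return out


def network_from_dict(data: dict) -> tuple[Network, tuple[int, ...] | None]:
    gates = []
    for entry in data["gates"]:
        gates.append(
            GateSpec(
                kind=entry["kind"],
                weights=tuple(entry["weights"]) if "weights" in entry else None,
                threshold=entry.get("threshold"),
                table=tuple(entry["table"]) if "table" in entry else None,
            )
        )
    net = build_network(data["labels"], data["cm"], gates)
    state = tuple(int(v) for v in data["state"]) if "state" in data else None
    return net, state


def save_network(net: Network, path, state=None) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net, state), indent=2))


def load_network(path) -> tuple[Network, tuple[int, ...] | None]:
    return network_from_dict(json.loads(Path(path).read_text()))


def tpm_to_csv(net: Network, path) -> None:
    """Export the state-by-node TPM (rows in little-endian state order)."""
    pd.DataFrame(net.node_tpm, columns=list(net.labels)).to_csv(path, index=False)


def tpm_from_csv(path) -> Network:
    """Import a state-by-node TPM as a network of TABLE gates.

    Connectivity is inferred by functional dependence: node i is an input of
    node j iff flipping bit i changes node j's ON-probability for some state.
    """
    df = pd.read_csv(path)
    labels = [str(c) for c in df.columns]
    n = len(labels)
    tpm = df.to_numpy(dtype=float)
    if tpm.shape != (1 << n, n):
        raise NetworkError(
            f"TPM shape {tpm.shape} does not match {n} nodes ({1 << n} states)"
        )
    states = all_states(n)
    cm = np.zeros((n, n), dtype=int)
    for j in range(n):
        col = tpm[:, j]
        for i in range(n):
            flipped = np.arange(1 << n) ^ (1 << i)
            if not np.allclose(col, col[flipped]):
                cm[i, j] = 1
    gates = []
    for j in range(n):
        inputs = np.flatnonzero(cm[:, j])
        if len(inputs) == 0:
            table = (float(tpm[0, j]),)
        else:
            # read the table off the rows where non-input nodes are zero
            rows = states[:, [i for i in range(n) if i not in inputs]].sum(axis=1) == 0
            sub = tpm[rows, j]
            order = np.argsort(states[rows][:, inputs] @ (1 << np.arange(len(inputs))))
            table = tuple(float(v) for v in sub[order])
        gates.append(GateSpec(kind="TABLE", table=table))
    return build_network(labels, cm, gates)


def repertoire_to_dict(rep: Repertoire, labels) -> dict:
    """Repertoire as JSON with explicit state labels.

    State keys list the purview nodes' values left-to-right in purview order
    (so "10" over purview (B, C) means B=1, C=0).
    """
    purview_labels = [labels[i] for i in rep.purview]
    out = {
        "purview": purview_labels,
        "direction": rep.direction,
        "state_ordering": STATE_ORDER,
    }
    if rep.is_undefined:
        out["probs"] = None
        return out
    probs = {}
    for s, p in enumerate(rep.probs):
        key = "".join(str((s >> k) & 1) for k in range(len(rep.purview))) or ""
        probs[key] = float(p)
    out["probs"] = probs
    return out
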