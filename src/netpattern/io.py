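"""File formats and packaged fixtures.

Formats (all plain text, node ids 1-based):

* edge-list TSV: columns ``source  target  count`` with ``#`` comment lines;
* adjacency CSV: dense integer matrix, row = target node;
* pattern CSV: columns ``node, value`` (or ``value_1..value_s``);
* coloring CSV: columns ``node, color``;
* dynamics YAML: ``{s: 1|2, Q: [[..]], R: [[..]]}`` with numeric entries or
  sign characters ``+ - 0 ?``;
* simulation config YAML: model parameters, network reference, lambda
  schedule ``[[t, lambda], ...]``, seed, noise amplitude, output grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bifurcation import LocalDynamics
from .network import (
    Coloring,
    NetworkError,
    RegularNetwork,
    adjacency_matrix,
    build_reflective_row,
    build_torus_lattice,
    notch_lattice_stencil,
    validate_network,
)


def read_network(path, fmt: str | None = None) -> RegularNetwork:
    """Read an edge-list TSV or adjacency CSV; hard error on non-regular input."""
    path = Path(path)
    if fmt is None:
        fmt = "edgelist" if path.suffix.lower() in (".tsv", ".txt") else "adjacency"
    if fmt == "edgelist":
        entries = []
        n = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise NetworkError(
                        f"{path}:{lineno}: expected 3 tab-separated columns"
                    )
                try:
                    s, t, c = (int(p) for p in parts)
                except ValueError as exc:
                    raise NetworkError(f"{path}:{lineno}: {exc}") from exc
                if s < 1 or t < 1 or c < 1:
                    raise NetworkError(
                        f"{path}:{lineno}: ids and counts must be >= 1"
                    )
                entries.append((s - 1, t - 1, c))
                n = max(n, s, t)
        counts = np.zeros((n, n), dtype=int)
        for s, t, c in entries:
            counts[t, s] += c
    elif fmt == "adjacency":
        counts = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    net = RegularNetwork.from_adjacency(counts, strict=False)
    report = validate_network(net)
    if report["has_self_arrows"]:
        raise NetworkError(f"{path}: network has self-arrows")
    if not report["is_regular"]:
        raise NetworkError(
            f"{path}: network is not regular; input-arrow counts per node: "
            f"{report['input_counts']}"
        )
    return RegularNetwork.from_adjacency(counts, strict=True)


def write_network(net: RegularNetwork, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "edgelist" if path.suffix.lower() in (".tsv", ".txt") else "adjacency"
    A = adjacency_matrix(net)
    if fmt == "edgelist":
        lines = ["# source\ttarget\tcount (1-based node ids)"]
        for t in range(net.n_nodes):
            for s in range(net.n_nodes):
                if A[t, s]:
                    lines.append(f"{s + 1}\t{t + 1}\t{A[t, s]}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "adjacency":
        np.savetxt(path, A, fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_pattern(path) -> np.ndarray:
    """Pattern CSV -> array of shape ``(n,)`` or ``(n, s)`` sorted by node id."""
    df = pd.read_csv(path, comment="#")
    df = df.sort_values(df.columns[0])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return values[:, 0] if values.shape[1] == 1 else values


def write_pattern(values, path, columns=None) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    if values.ndim == 1:
        values = values[:, None]
    if columns is None:
        columns = ["value"] if values.shape[1] == 1 else [
            f"value_{i+1}" for i in range(values.shape[1])
        ]
    df = pd.DataFrame(values, columns=columns)
    df.insert(0, "node", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)


def read_coloring(path) -> Coloring:
    df = pd.read_csv(path, comment="#").sort_values("node")
    return Coloring(tuple(int(c) for c in df["color"]))


def write_coloring(coloring: Coloring, path) -> None:
    df = pd.DataFrame(
        {"node": np.arange(1, coloring.n_nodes + 1), "color": coloring.assignment}
    )
    df.to_csv(path, index=False)


def load_dynamics(path) -> LocalDynamics:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    Q, R = cfg["Q"], cfg["R"]
    sign_entries = any(
        isinstance(e, str) for row in list(Q) + list(R) for e in row
    )
    return LocalDynamics(
        np.array(Q, dtype=object if sign_entries else float),
        np.array(R, dtype=object if sign_entries else float),
        sign_only=sign_entries,
    )


def dump_dynamics(dyn: LocalDynamics, path) -> None:
    def mat(M):
        if dyn.sign_only:
            return [[str(e) for e in row] for row in M]
        return [[float(e) for e in row] for row in M]

    with open(path, "w") as fh:
        yaml.safe_dump({"s": dyn.s, "Q": mat(dyn.Q), "R": mat(dyn.R)}, fh)


def network_from_config(cfg) -> RegularNetwork:
    """Build or load a network from a config mapping.

    Accepted forms: ``{file: path}``, ``{constructor: reflective_row, n: 6,
    weight: 1}`` or ``{constructor: torus_lattice, rows: 8, cols: 8,
    stencil: notch}`` (``stencil`` may also be ``{"dr,dc": weight, ...}``).
    """
    if "file" in cfg:
        return read_network(cfg["file"])
    ctor = cfg.get("constructor")
    if ctor == "reflective_row":
        return build_reflective_row(int(cfg["n"]), int(cfg.get("weight", 1)))
    if ctor == "torus_lattice":
        stencil = cfg.get("stencil", "notch")
        if stencil == "notch":
            stencil = notch_lattice_stencil()
        else:
            stencil = {
                tuple(int(x) for x in key.split(",")): int(w)
                for key, w in stencil.items()
            }
        return build_torus_lattice(int(cfg["rows"]), int(cfg["cols"]), stencil)
    raise ValueError(f"cannot build a network from config {cfg!r}")


def checkerboard_vector(rows: int, cols: int) -> np.ndarray:
    r, c = np.divmod(np.arange(rows * cols), cols)
    return ((-1.0) ** (r + c)).astype(float)


def stripe_vector(rows: int, cols: int) -> np.ndarray:
    """Single-axis stripes (columns alternate), an interior-eigenvalue pattern."""
    _, c = np.divmod(np.arange(rows * cols), cols)
    return ((-1.0) ** c).astype(float)


NOTCH_SIGNS = {
    "s": 2,
    "Q": [["-", "-"], ["0", "-"]],
    "R": [["0", "0"], ["+", "0"]],
}


def make_fixtures(outdir) -> dict[str, Path]:
    """Write the packaged example inputs into ``outdir``.

    Emits the 6-cell vulval-precursor row, the 16x16 and 8x8 lateral
    inhibition tori (nearest = 3, diagonal = 1), alternating and checkerboard
    pattern CSVs, a stripe pattern, the lateral-inhibition sign template and
    the default Delta-Notch kinetic parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    vpc = build_reflective_row(6, 1)
    files["vpc6"] = outdir / "vpc6.tsv"
    write_network(vpc, files["vpc6"])

    stencil = notch_lattice_stencil()
    for size in (8, 16):
        net = build_torus_lattice(size, size, stencil)
        files[f"lattice{size}"] = outdir / f"lattice{size}.tsv"
        write_network(net, files[f"lattice{size}"])
        files[f"checkerboard{size}"] = outdir / f"checkerboard{size}.csv"
        write_pattern(checkerboard_vector(size, size), files[f"checkerboard{size}"])
        files[f"stripes{size}"] = outdir / f"stripes{size}.csv"
        write_pattern(stripe_vector(size, size), files[f"stripes{size}"])

    files["alternating6"] = outdir / "alternating6.csv"
    write_pattern(np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]), files["alternating6"])

    files["notch_signs"] = outdir / "notch_signs.yaml"
    with open(files["notch_signs"], "w") as fh:
        yaml.safe_dump(NOTCH_SIGNS, fh)

    files["delta_notch_params"] = outdir / "delta_notch.yaml"
    with open(files["delta_notch_params"], "w") as fh:
        yaml.safe_dump(
            {
                "model": "delta_notch",
                "params": {"h_D": 2, "h_N": 2, "K_D": 0.1, "K_N": 0.1,
                           "gamma_D": 1.0, "gamma_N": 1.0},
                "lambda_schedule": [[0.0, 0.0], [200.0, 2.0], [400.0, 2.0]],
                "noise_amplitude": 1e-3,
                "seed": 0,
            },
            fh,
        )
    return files


def json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, complex):
        return {"re": o.real, "im": o.imag}
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    return str(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=json_default)
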