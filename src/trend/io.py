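"""File formats, run manifests, and fixture generation.

BOLD series travel as CSV (first column ``time`` in seconds, one column per
region) or HDF5 (dataset ``Y``, attributes ``TR`` and ``labels``).  Graphs
and scenarios are YAML/JSON.  Every CLI invocation writes a manifest
recording the command, configuration hashes, seeds, and package version, so
any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .forward import BOLDTimeSeries
from .graph import NetworkGraph

__all__ = [
    "read_bold",
    "write_bold",
    "read_graph",
    "write_graph",
    "read_yaml",
    "RunManifest",
    "make_fixture",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending row/field."""


# -- BOLD series -----------------------------------------------------------

def write_bold(ts: BOLDTimeSeries, path, fmt: str | None = None):
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("Y", data=ts.Y)
            f.attrs["TR"] = ts.tr
            f.attrs["labels"] = [str(x) for x in ts.region_labels]
    elif fmt == "csv":
        df = pd.DataFrame(ts.Y, columns=ts.region_labels)
        df.insert(0, "time", ts.time)
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_bold(path, fmt: str | None = None, tr: float | None = None) -> BOLDTimeSeries:
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "Y" not in f:
                raise FormatError(f"{path}: missing dataset 'Y'")
            Y = f["Y"][()]
            if tr is None:
                if "TR" not in f.attrs:
                    raise FormatError(f"{path}: missing attribute 'TR'")
                tr = float(f.attrs["TR"])
            labels = [
                x.decode() if isinstance(x, bytes) else str(x)
                for x in f.attrs.get("labels", [])
            ] or None
        return BOLDTimeSeries(Y, tr, labels)
    # CSV: first column is time in seconds
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FormatError(f"{path}: first column must be 'time' (seconds)")
    bad = df.isna()
    if bad.any().any():
        row = int(np.where(bad.any(axis=1))[0][0])
        col = bad.columns[bad.iloc[row].values][0]
        raise FormatError(f"{path}: missing/non-numeric cell at row {row}, column {col!r}")
    t = df["time"].to_numpy(float)
    if tr is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer TR from a single row")
        tr = float(np.median(np.diff(t)))
    labels = [c for c in df.columns if c != "time"]
    return BOLDTimeSeries(df[labels].to_numpy(float), tr, labels)


# -- graphs ----------------------------------------------------------------

def write_graph(graph: NetworkGraph, path):
    path = Path(path)
    d = graph.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def read_graph(path) -> NetworkGraph:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return NetworkGraph.from_dict(d)


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# -- manifests -------------------------------------------------------------

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def write(self, out_path):
        self.finished = time.time()
        out_path = Path(out_path)
        from importlib.metadata import PackageNotFoundError, version

        try:
            pkg_version = version("trend-dcm")
        except PackageNotFoundError:
            pkg_version = "unknown"
        payload = {
            "command": self.command,
            "config": self.config,
            "config_hash": _hash_obj(self.config),
            "seeds": self.seeds,
            "inputs": [str(p) for p in self.inputs],
            "outputs": [str(p) for p in self.outputs],
            "package_version": pkg_version,
            "started": self.started,
            "finished": self.finished,
        }
        out_path.write_text(json.dumps(payload, indent=2))
        return out_path


def manifest_path_for(output) -> Path:
    output = Path(output)
    return output.with_suffix(output.suffix + ".manifest.json")


# -- fixtures --------------------------------------------------------------

def make_fixture(name: str, out_dir, seed: int = 0) -> dict:
    """Write a self-contained test fixture (scenario + observations).

    Known names: ``tiny`` (2 regions, 60 s), ``three_region``,
    ``ten_region``.  Produces the scenario YAML, the noiseless observation,
    and a CNR=10 noisy observation.
    """
    from dataclasses import replace

    from .benchmarks import (
        BenchmarkScenario,
        three_region_benchmark,
        ten_region_benchmark,
    )
    from .graph import NetworkGraph
    from .params import ConnectivityParams, NeuronalParams
    from .stimulus import default_block_design

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if name == "tiny":
        a_mask = np.array([[0, 0], [1, 0]], dtype=np.int8)
        c_mask = np.array([[1], [0]], dtype=np.int8)
        graph = NetworkGraph(2, a_mask, c_mask=c_mask)
        A = np.zeros((2, 2))
        A[1, 0] = 0.4
        scenario = BenchmarkScenario(
            name="tiny",
            generator="pdcm",
            n_regions=2,
            graph=graph,
            neuronal=NeuronalParams.default(2),
            conn=ConnectivityParams(A, [], c_mask.astype(float)),
            design=default_block_design(n_driving=1, total_duration=60.0),
            tr=1.0,
        )
    elif name == "three_region":
        scenario = three_region_benchmark()
    elif name == "ten_region":
        scenario = ten_region_benchmark()
    else:
        raise ValueError(f"unknown fixture name {name!r}")

    paths = {}
    scen_path = out_dir / f"{name}_scenario.yaml"
    scen_path.write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))
    paths["scenario"] = scen_path
    clean = scenario.generate()
    clean_path = out_dir / f"{name}_noiseless.csv"
    write_bold(clean, clean_path)
    paths["noiseless"] = clean_path
    noisy = replace(scenario, cnr=10.0).generate(noise_seed=seed)
    noisy_path = out_dir / f"{name}_cnr10.csv"
    write_bold(noisy, noisy_path)
    paths["cnr10"] = noisy_path
    return paths
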