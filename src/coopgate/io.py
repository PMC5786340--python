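"""Configuration, serialization, fixtures and run manifests.

Configs are JSON or TOML files validated against a flat schema; unknown
keys are rejected by name.  Time series go to CSV with a units header row;
summaries and manifests to JSON.  Fixture generators produce the synthetic
datasets used by the analysis-layer tests together with their ground-truth
descriptors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RunConfig", "RunManifest", "load_config", "save_config",
           "write_timeseries", "read_timeseries", "make_fixture",
           "expand_seed"]

_MODELS = ("stochastic", "ionic", "map")
_PROTOCOLS = ("vclamp", "pace", "apclamp", "scan", "iv", "spark")


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one simulation run."""

    model: str = "ionic"
    protocol: str = "pace"
    seed: int = 0
    out_dir: str = "runs"
    output_stride: int = 20
    params: dict = field(default_factory=dict)   # model-parameter overrides
    pcl: float = 300.0
    n_beats: int = 10
    dt: float = 0.01
    holding: float = -80.0
    test_potentials: tuple = (20.0,)
    grid: tuple = (8, 8, 4)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; one of {_MODELS}")
        if self.protocol not in _PROTOCOLS:
            raise ValueError(
                f"unknown protocol {self.protocol!r}; one of {_PROTOCOLS}")
        if self.dt <= 0 or self.pcl <= 0 or self.n_beats < 1:
            raise ValueError("dt, pcl must be > 0 and n_beats >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["test_potentials"] = list(self.test_potentials)
        d["grid"] = list(self.grid)
        return d


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or TOML run config.

    Unknown keys are rejected with their names; defaults fill the rest.
    """
    path = Path(path)
    text = path.read_bytes()
    if path.suffix.lower() == ".toml":
        raw = tomllib.loads(text.decode())
    else:
        raw = json.loads(text)
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "test_potentials" in raw:
        raw["test_potentials"] = tuple(raw["test_potentials"])
    if "grid" in raw:
        raw["grid"] = tuple(raw["grid"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def write_timeseries(trace: dict | pd.DataFrame, path: str | Path,
                     units: dict | None = None) -> None:
    """Write a time series as CSV with a ``# units:`` comment header.

    Column order follows the input mapping; values round-trip at 12
    significant digits.  Empty traces are an error.
    """
    df = pd.DataFrame(trace)
    if df.empty:
        raise ValueError("empty trace")
    path = Path(path)
    with open(path, "w") as fh:
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a run bit-exactly."""

    config: dict
    version: str
    seeds: dict
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        tmp.replace(path)  # atomic


def expand_seed(seed: int, component: str) -> int:
    """Deterministic per-component substream seed from one global seed."""
    h = hashlib.sha256(f"{seed}:{component}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Synthetic datasets with known ground truth for analysis tests.

    Kinds: ``square_ap``, ``triangle_ap``, ``period2_beats``,
    ``boltzmann_iv``, ``n_open_events``.  Returns ``(data, truth)``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "square_ap":
        width = p.get("width", 200.0)
        pcl = p.get("pcl", 300.0)
        n_beats = p.get("n_beats", 3)
        dt = p.get("dt", 0.1)
        t = np.arange(0.0, pcl * n_beats, dt)
        phase = t % pcl
        vm = np.where((phase >= 10.0) & (phase < 10.0 + width), 20.0, -80.0)
        return {"t": t, "vm": vm}, {"apd": width, "pcl": pcl}
    if kind == "triangle_ap":
        apd0 = p.get("duration", 250.0)
        pcl = p.get("pcl", 300.0)
        dt = p.get("dt", 0.1)
        v_rest, v_peak = -80.0, 20.0
        t = np.arange(0.0, pcl * p.get("n_beats", 3), dt)
        phase = (t - 10.0) % pcl
        vm = np.where(phase < apd0,
                      v_peak - (v_peak - v_rest) * phase / apd0, v_rest)
        vm[t < 10.0] = v_rest
        frac = p.get("fraction", 0.9)
        # linear decay crosses the APD_f threshold at f * duration
        return ({"t": t, "vm": vm},
                {"apd": frac * apd0, "pcl": pcl, "fraction": frac})
    if kind == "period2_beats":
        from .alternans import BeatSeries
        n = p.get("n_beats", 20)
        a, b = p.get("apd_long", 200.0), p.get("apd_short", 180.0)
        ca_a, ca_b = p.get("ca_long", 1.0), p.get("ca_short", 0.8)
        apd = np.where(np.arange(n) % 2 == 0, a, b)
        ca = np.where(np.arange(n) % 2 == 0, ca_a, ca_b)
        series = BeatSeries(apd=apd, ca_peak=ca, pcl=p.get("pcl", 300.0))
        return series, {"d_apd": -(a - b), "d_ca": -(ca_a - ca_b)}
    if kind == "boltzmann_iv":
        v_half, k = p.get("v_half", -10.0), p.get("slope", 6.0)
        vs = np.asarray(p.get("test_potentials", np.arange(-60.0, 61.0, 10.0)))
        from .ltcc import LtccParams, single_channel_current
        lp = LtccParams()
        cp_ref = p.get("cp_ref", 0.5)
        act = 1.0 / (1.0 + np.exp(-(vs - v_half) / k))
        drive = np.array([single_channel_current(float(v), cp_ref, lp) for v in vs])
        peaks = act * drive
        return {"test_potentials": vs, "peak_current": peaks}, \
            {"v_half": v_half, "slope": k, "cp_ref": cp_ref}
    if kind == "n_open_events":
        dt = p.get("dt", 0.1)
        n_events = p.get("n_events", 5)
        gap = p.get("gap", 30)         # samples of silence between events
        events = []
        trace = [0] * gap
        for _ in range(n_events):
            length = int(rng.integers(3, 12))
            seg = rng.integers(1, 6, size=length)
            trace.extend(seg.tolist())
            trace.extend([0] * gap)
            events.append({"max": int(seg.max()), "dwell": length * dt})
        return np.asarray(trace), {"events": events, "dt": dt}
    raise ValueError(f"unknown fixture kind {kind!r}")
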