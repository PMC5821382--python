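"""File formats: edge-list topologies, experiment configs, run manifests.

All files are plain text. Species indices are 1-based in every file
(ecological convention, "species 1 … S"); the in-memory representation is
0-based with conversion at this boundary only.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .config import MODELS, CommunityConfig, GrowthRateSpec
from .networks import PREDATION_TAGS, Topology

__all__ = [
    "FormatError",
    "ConfigError",
    "write_topology",
    "read_topology",
    "load_config",
    "write_manifest",
    "read_manifest",
]


class FormatError(ValueError):
    """Malformed topology file."""


class ConfigError(ValueError):
    """Invalid experiment configuration document."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config:\n  - " + "\n  - ".join(self.problems))


def _header_for(tag: str) -> str:
    return "predator,prey" if tag in PREDATION_TAGS else "i,j"


def write_topology(t: Topology, path) -> None:
    """Write a topology as edge-list CSV with metadata comments.

    Header is ``predator,prey`` for trophic topologies and ``i,j``
    otherwise; one row per nonzero entry of ``alpha``, 1-based.
    """
    lines = [f"# S={t.S}", f"# model={t.model_tag}",
             f"# C_target={t.C_target!r}", _header_for(t.model_tag)]
    ii, jj = np.nonzero(t.alpha)
    lines += [f"{i + 1},{j + 1}" for i, j in zip(ii, jj)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> Topology:
    """Read an edge-list CSV written by :func:`write_topology`.

    Self-links and non-integer or out-of-range indices are rejected with a
    diagnostic naming the offending line. ``S`` comes from the ``# S=``
    comment when present, otherwise from the maximum index.
    """
    path = Path(path)
    S = None
    model = "may_directed"
    C_target = 0.5
    edges = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                if key == "S":
                    S = int(val)
                elif key == "model":
                    model = val.strip()
                elif key == "C_target":
                    C_target = float(val)
            continue
        if line.replace(" ", "") in ("predator,prey", "i,j"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two fields, "
                              f"got {raw!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-integer index in {raw!r}") from None
        if i < 1 or j < 1:
            raise FormatError(f"{path}:{lineno}: indices must be >= 1")
        if i == j:
            raise FormatError(
                f"{path}:{lineno}: self-link {i},{j} is not allowed "
                "(intraspecific effects live in theta)")
        edges.append((i - 1, j - 1))
    if S is None:
        if not edges:
            raise FormatError(f"{path}: no '# S=' header and no edges")
        S = 1 + max(max(i, j) for i, j in edges)
    alpha = np.zeros((S, S), dtype=np.int8)
    for lineno, (i, j) in enumerate(edges):
        if i >= S or j >= S:
            raise FormatError(f"{path}: index exceeds declared S={S}")
        alpha[i, j] = 1
    return Topology(S, alpha, model, C_target)


_CONFIG_KEYS = {"model", "S", "C", "sigma", "theta", "delta", "rates",
                "M", "n_reps", "seed"}
_RATE_KEYS = {"kind", "mean", "sd", "low", "high", "values"}


def load_config(path) -> tuple[CommunityConfig, int]:
    """Load and validate a YAML/JSON experiment config.

    Returns ``(config, n_reps)``. ``delta`` may be given as a decimal
    string (recommended: it is compared exactly against 1/2 for regime
    classification) or a number. Defaults: ``M=200`` structural-vector
    trials, ``n_reps=1000`` replicates, ``seed=0``, structural rates.
    All schema violations are reported at once.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(["document must be a mapping"])
    problems = []
    unknown = set(doc) - _CONFIG_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    for key in ("model", "S", "C", "sigma", "theta", "delta"):
        if key not in doc:
            problems.append(f"missing required key: {key}")
    if problems:
        raise ConfigError(problems)

    if doc["model"] not in MODELS:
        problems.append(f"model must be one of {MODELS}, got {doc['model']!r}")
    delta_raw = doc["delta"]
    delta_str = str(delta_raw)
    try:
        delta = float(delta_raw)
    except (TypeError, ValueError):
        problems.append(f"delta is not a number: {delta_raw!r}")
        delta = None
    if delta is not None and not (0.0 <= delta <= 1.0):
        problems.append(f"delta must lie in [0, 1], got {delta_str}")
    S = doc["S"]
    if not isinstance(S, int) or S < 2:
        problems.append(f"S must be an integer >= 2, got {S!r}")
    if not (isinstance(doc["C"], (int, float)) and 0 < doc["C"] < 1):
        problems.append(f"C must lie in (0, 1), got {doc['C']!r}")
    if not (isinstance(doc["sigma"], (int, float)) and doc["sigma"] > 0):
        problems.append(f"sigma must be positive, got {doc['sigma']!r}")
    if not (isinstance(doc["theta"], (int, float)) and doc["theta"] < 0):
        problems.append(f"theta must be negative, got {doc['theta']!r}")

    rates_doc = doc.get("rates", "structural")
    try:
        if isinstance(rates_doc, str):
            rates = GrowthRateSpec(kind=rates_doc)
        elif isinstance(rates_doc, dict):
            bad = set(rates_doc) - _RATE_KEYS
            if bad:
                raise ValueError(f"unknown rates keys: {sorted(bad)}")
            rates = GrowthRateSpec(**rates_doc)
        else:
            raise ValueError(f"rates must be a string or mapping, "
                             f"got {rates_doc!r}")
    except (TypeError, ValueError) as exc:
        problems.append(f"rates: {exc}")
        rates = GrowthRateSpec()

    n_reps = doc.get("n_reps", 1000)
    if not isinstance(n_reps, int) or n_reps < 1:
        problems.append(f"n_reps must be a positive integer, got {n_reps!r}")
    M = doc.get("M", 200)
    if not isinstance(M, int) or M < 1:
        problems.append(f"M must be a positive integer, got {M!r}")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        problems.append(f"seed must be a non-negative integer, got {seed!r}")

    if problems:
        raise ConfigError(problems)
    config = CommunityConfig(S=S, C=float(doc["C"]), delta=delta,
                             theta=float(doc["theta"]),
                             sigma=float(doc["sigma"]), model=doc["model"],
                             rates=rates, M=M, seed=seed,
                             delta_str=delta_str)
    return config, n_reps


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(path, config: CommunityConfig, seed: int,
                   outputs) -> dict:
    """Write a JSON run manifest: config snapshot, seed, version,
    timestamp, and a checksum inventory of the produced files."""
    from . import __version__

    manifest = {
        "tool": "lvfeas",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": int(seed),
        "config": config.to_dict(),
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
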