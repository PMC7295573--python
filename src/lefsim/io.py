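"""Configuration files, serialization, run manifests and test fixtures.

The config format is a flat ``key = value`` text file (``#`` comments).
Documented keys: n_sites, site_size_kb, n_lefs, v, v_diff, k_bind,
k_unbind, k_switch, sidedness, traversal, pushing, barriers
(``site:orientation:p_stall`` comma-separated, orientation ``left``/
``right`` for left-/right-blocking), loading_weights (``uniform`` or a
path to a one-column file), terminal_unload_sites (comma-separated),
scheduler (``gillespie``/``fixed``), dt, t_end, burn_in, seed.
Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np

from .config import Barrier, ConfigurationError, LatticeConfig, LEFParams, derived_scales
from .engine import Trajectory

__all__ = [
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "RunManifest",
    "FixtureSet",
    "make_fixtures",
]

_KEYS = {
    "n_sites", "site_size_kb", "n_lefs", "v", "v_diff", "k_bind", "k_unbind",
    "k_switch", "sidedness", "traversal", "pushing", "barriers",
    "loading_weights", "terminal_unload_sites", "scheduler", "dt", "t_end",
    "burn_in", "seed",
}

_REQUIRED = {"n_sites", "n_lefs", "k_bind", "k_unbind"}

_DEFAULTS = dict(
    site_size_kb=0.5, v=1.0, v_diff=0.0, k_switch=0.0, sidedness=0.0,
    traversal="false", pushing="none", scheduler="gillespie", dt=0.1,
    t_end=0.0, burn_in=0.0, seed=0,
)


def _parse_barriers(text: str) -> list[Barrier]:
    out = []
    for item in text.split(","):
        item = item.strip()
        if not item:
            continue
        site, orientation, p = item.split(":")
        orientation = {"left": "left-blocking", "right": "right-blocking"}.get(
            orientation.strip(), orientation.strip()
        )
        out.append(Barrier(int(site), orientation, float(p)))
    return out


def load_config(path) -> tuple[LatticeConfig, LEFParams, dict]:
    """Parse and validate a flat key-value config file.

    Returns ``(LatticeConfig, LEFParams, options)`` where ``options`` holds
    the scheduler settings (scheduler, dt, t_end, burn_in, seed).
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _KEYS:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            raw[key] = val
    missing = _REQUIRED - raw.keys()
    if missing:
        raise ConfigurationError(f"missing required keys: {sorted(missing)}")
    vals = dict(_DEFAULTS)
    vals.update(raw)
    weights = None
    wspec = vals.get("loading_weights", "uniform")
    if wspec not in ("uniform", None):
        wpath = wspec
        if not os.path.isabs(wpath):
            wpath = os.path.join(os.path.dirname(os.path.abspath(path)), wpath)
        weights = np.loadtxt(wpath)
    unload = []
    if vals.get("terminal_unload_sites"):
        unload = [int(s) for s in str(vals["terminal_unload_sites"]).split(",") if s.strip()]
    config = LatticeConfig(
        n_sites=int(vals["n_sites"]),
        site_size_kb=float(vals["site_size_kb"]),
        loading_weights=weights,
        barriers=_parse_barriers(vals.get("barriers", "")),
        terminal_unload_sites=unload,
    )
    params = LEFParams(
        n_lefs=int(vals["n_lefs"]),
        k_bind=float(vals["k_bind"]),
        k_unbind=float(vals["k_unbind"]),
        v=float(vals["v"]),
        v_diff=float(vals["v_diff"]),
        k_switch=float(vals["k_switch"]),
        sidedness=float(vals["sidedness"]),
        traversal=str(vals["traversal"]).lower() in ("true", "1", "yes"),
        pushing=vals["pushing"],
    )
    options = dict(
        scheduler=vals["scheduler"],
        dt=float(vals["dt"]),
        t_end=float(vals["t_end"]),
        burn_in=float(vals["burn_in"]),
        seed=int(vals["seed"]),
    )
    return config, params, options


def save_config(path, config: LatticeConfig, params: LEFParams,
                options: dict | None = None) -> None:
    """Write a config file that round-trips through :func:`load_config`."""
    options = options or {}
    lines = [
        f"n_sites = {config.n_sites}",
        f"site_size_kb = {config.site_size_kb}",
        f"n_lefs = {params.n_lefs}",
        f"v = {params.v}",
        f"v_diff = {params.v_diff}",
        f"k_bind = {params.k_bind}",
        f"k_unbind = {params.k_unbind}",
        f"k_switch = {params.k_switch}",
        f"sidedness = {params.sidedness}",
        f"traversal = {str(params.traversal).lower()}",
        f"pushing = {params.pushing}",
    ]
    if config.barriers:
        items = ",".join(
            f"{b.site}:{'left' if b.orientation == 'left-blocking' else 'right'}:{b.p_stall}"
            for b in config.barriers
        )
        lines.append(f"barriers = {items}")
    if config.terminal_unload_sites:
        lines.append(
            "terminal_unload_sites = "
            + ",".join(str(s) for s in config.terminal_unload_sites)
        )
    if config.loading_weights is not None:
        wpath = str(path) + ".weights"
        np.savetxt(wpath, np.asarray(config.loading_weights))
        lines.append(f"loading_weights = {os.path.basename(wpath)}")
    for k in ("scheduler", "dt", "t_end", "burn_in", "seed"):
        if k in options:
            lines.append(f"{k} = {options[k]}")
    _atomic_write(path, "\n".join(lines) + "\n")


def _atomic_write(path, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trajectory(traj: Trajectory, path) -> None:
    """Tab-delimited snapshot blocks: time, lef_id, positions, roles, stalls."""
    df = traj.to_dataframe()
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d)
    os.close(fd)
    try:
        df.to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_trajectory(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")


@dataclass
class RunManifest:
    """Provenance record: config hash, seeds and emitted files."""

    config_hash: str
    seeds: list[int]
    outputs: list[str] = field(default_factory=list)
    software_version: str = ""
    metadata: dict = field(default_factory=dict)

    @classmethod
    def for_run(cls, config: LatticeConfig, params: LEFParams, seeds) -> "RunManifest":
        from . import __version__

        ds = derived_scales(config, params)
        blob = json.dumps(
            dict(
                n_sites=config.n_sites, site_size_kb=config.site_size_kb,
                n_lefs=params.n_lefs, v=params.v, v_diff=params.v_diff,
                k_bind=params.k_bind, k_unbind=params.k_unbind,
                k_switch=params.k_switch, sidedness=params.sidedness,
                traversal=params.traversal, pushing=params.pushing,
            ),
            sort_keys=True,
        )
        return cls(
            config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
            seeds=[int(s) for s in seeds],
            software_version=__version__,
            metadata=dict(
                processivity=ds.processivity, separation=ds.separation,
                lam_over_d=ds.lam_over_d,
            ),
        )

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        _atomic_write(path, json.dumps(self.__dict__, indent=2, default=str))


@dataclass
class FixtureSet:
    """Tiny deterministic inputs for unit tests, generated programmatically."""

    nested_snapshot: list  # the worked loop-forest example
    lattice50: LatticeConfig  # 50 sites, one barrier
    lattice50_params: LEFParams
    polymer200: np.ndarray  # (200, 3) random-walk conformation
    planted_dot_map: np.ndarray  # distance-law map with one enriched pixel
    planted_dot: tuple  # (i, j, enrichment)


def make_fixtures(seed: int = 0) -> FixtureSet:
    """Deterministic fixtures; identical seeds give identical objects."""
    rng = np.random.default_rng(seed)
    n = 40
    i0, j0, enrich = 10, 30, 5.0
    idx = np.arange(n)
    base = np.abs(idx[:, None] - idx[None, :]).astype(float)
    base[base < 1] = 1.0
    m = base**-1.5
    m[i0, j0] *= enrich
    m[j0, i0] *= enrich
    steps = rng.normal(size=(199, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    poly = np.zeros((200, 3))
    poly[1:] = np.cumsum(steps, axis=0)
    return FixtureSet(
        nested_snapshot=[(0, 20), (5, 10), (30, 40)],
        lattice50=LatticeConfig(
            n_sites=50, barriers=[Barrier(25, "right-blocking", 1.0)]
        ),
        lattice50_params=LEFParams(n_lefs=3, k_bind=1.0, k_unbind=0.05),
        polymer200=poly,
        planted_dot_map=m,
        planted_dot=(i0, j0, enrich),
    )
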