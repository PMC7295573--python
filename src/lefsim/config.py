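"""Parameter containers for the 1D loop-extrusion model.

Unit conventions
----------------
The engine works in lattice units: positions are 0-based site indices, the
active extrusion speed ``v`` is expressed in sites per unit time, and every
rate (``k_bind``, ``k_unbind``, ``k_switch``, ``v_diff``) shares that time
unit.  Physical units (kb, seconds) only enter through ``site_size_kb`` when
results are reported.

Control parameters of the model are the dimensionless ratios collected in
:class:`DerivedScales`:

* processivity ``lam = q * v / k_unbind`` -- the mean length extruded per
  binding event (``q = 1`` for one-sided LEFs, ``q = 2`` for two-sided),
* mean separation ``d = L / N_b`` between the ``N_b`` bound LEFs,
* and the ratios ``lam / d``, ``v_diff / v``, ``k_switch / k_unbind`` and
  ``k_switch * L / v`` that parameterize the model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Barrier",
    "LatticeConfig",
    "LEFParams",
    "DerivedScales",
    "derived_scales",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised for invalid lattice or kinetic parameter combinations."""


Orientation = Literal["left-blocking", "right-blocking"]


@dataclass(frozen=True)
class Barrier:
    """A directional, partially permeable extrusion barrier (CTCF-like).

    An extruding subunit attempting to step *onto* ``site`` while moving in
    the blocked direction is stalled with probability ``p_stall``; with
    probability ``1 - p_stall`` the subunit ignores this barrier for the rest
    of its current binding event.  ``left-blocking`` barriers block subunits
    moving toward lower site indices, ``right-blocking`` barriers block
    subunits moving toward higher indices.
    """

    site: int
    orientation: Orientation
    p_stall: float = 0.8

    def __post_init__(self) -> None:
        if self.orientation not in ("left-blocking", "right-blocking"):
            raise ConfigurationError(
                f"barrier orientation must be 'left-blocking' or "
                f"'right-blocking', got {self.orientation!r}"
            )
        if not 0.0 <= self.p_stall <= 1.0:
            raise ConfigurationError(f"p_stall must be in [0, 1], got {self.p_stall}")


@dataclass
class LatticeConfig:
    """The 1D chromatin/DNA lattice.

    Parameters
    ----------
    n_sites
        Lattice length ``L`` in sites.
    site_size_kb
        Physical size ``a`` of one site in kb (0.5 kb for mitotic chromatin,
        ~1 kb for bacterial DNA, 2 kb for interphase monomers).
    loading_weights
        Optional per-site relative binding weights (length ``n_sites``; a LEF
        loading at site ``i`` occupies ``(i, i + 1)``, so the weight of the
        last site is ignored).  ``None`` means uniform.
    loading_orientation
        Optional per-site directional-loading flags: ``+1`` forces the active
        subunit of a one-sided LEF loaded there to extrude rightward, ``-1``
        leftward, ``0`` random.
    barriers
        Directional stall sites.
    terminal_unload_sites
        Sites where any arriving LEF subunit triggers immediate unbinding
        (the bacterial *ter* region).  Circular chromosomes are represented
        by a linear lattice whose two ends are the *ter* region.
    """

    n_sites: int
    site_size_kb: float = 0.5
    loading_weights: np.ndarray | Sequence[float] | None = None
    loading_orientation: np.ndarray | Sequence[int] | None = None
    barriers: list[Barrier] = field(default_factory=list)
    terminal_unload_sites: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ConfigurationError(f"n_sites must be >= 4, got {self.n_sites}")
        if self.site_size_kb <= 0:
            raise ConfigurationError("site_size_kb must be > 0")
        if self.loading_weights is not None:
            w = np.asarray(self.loading_weights, dtype=float)
            if w.shape != (self.n_sites,):
                raise ConfigurationError(
                    f"loading_weights must have length n_sites={self.n_sites}"
                )
            if np.any(w < 0) or not np.any(w[: self.n_sites - 1] > 0):
                raise ConfigurationError(
                    "loading_weights must be non-negative with at least one "
                    "positive loadable site"
                )
            self.loading_weights = w
        if self.loading_orientation is not None:
            o = np.asarray(self.loading_orientation, dtype=np.int8)
            if o.shape != (self.n_sites,):
                raise ConfigurationError(
                    f"loading_orientation must have length n_sites={self.n_sites}"
                )
            if not np.all(np.isin(o, (-1, 0, 1))):
                raise ConfigurationError("loading_orientation entries must be -1, 0 or 1")
            self.loading_orientation = o
        for b in self.barriers:
            if not 0 <= b.site < self.n_sites:
                raise ConfigurationError(f"barrier site {b.site} out of range")
        for s in self.terminal_unload_sites:
            if not 0 <= s < self.n_sites:
                raise ConfigurationError(f"terminal unload site {s} out of range")


PushingMode = Literal["none", "weak", "strong"]


@dataclass
class LEFParams:
    """Kinetic parameters and variant flags of the loop-extruding factors.

    ``sidedness`` is the probability that a binding event produces a
    two-sided LEF (both subunits active); ``1 - sidedness`` of events produce
    one-sided LEFs with a random (or directionally loaded) active subunit.
    ``v_diff > 0`` makes the passive subunit of one-sided LEFs diffusive
    (semi-diffusive model) with loop-entropy-biased step rates; ``k_switch``
    exchanges active and anchored roles (switching model).  ``traversal``
    lets LEFs pass freely through each other (Z-loop model);
    ``pushing`` lets an active subunit displace passive subunits ahead of it.
    """

    n_lefs: int
    k_bind: float
    k_unbind: float
    v: float = 1.0
    v_diff: float = 0.0
    k_switch: float = 0.0
    sidedness: float = 0.0
    traversal: bool = False
    pushing: PushingMode = "none"

    def __post_init__(self) -> None:
        if self.n_lefs < 1:
            raise ConfigurationError("n_lefs must be >= 1")
        for name in ("k_bind", "k_unbind", "v", "v_diff", "k_switch"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.sidedness <= 1.0:
            raise ConfigurationError(f"sidedness must be in [0, 1], got {self.sidedness}")
        if self.pushing not in ("none", "weak", "strong"):
            raise ConfigurationError(f"unknown pushing mode {self.pushing!r}")
        if self.traversal and self.pushing != "none":
            raise ConfigurationError("traversal and pushing are mutually exclusive")

    @property
    def q(self) -> float:
        """Mean number of actively translocating subunits per LEF."""
        return 1.0 + self.sidedness


@dataclass(frozen=True)
class DerivedScales:
    """Dimensionless control parameters, recomputed from the raw rates."""

    processivity: float  # lam = q v / k_unbind, sites
    separation: float  # d = L / N_b, sites
    n_bound_mean: float  # N_b = N k_bind / (k_bind + k_unbind)
    lam_over_d: float
    v_diff_over_v: float
    k_switch_over_k_unbind: float
    k_switch_L_over_v: float


def derived_scales(config: LatticeConfig, params: LEFParams) -> DerivedScales:
    """Compute the processivity, mean separation and scaled ratios.

    ``lam = q * v / k_unbind`` with ``q = 1 + sidedness`` and
    ``d = L / N_b`` with ``N_b = N * k_bind / (k_bind + k_unbind)``.
    """
    if params.k_unbind > 0:
        lam = params.q * params.v / params.k_unbind
    else:
        lam = np.inf
    denom = params.k_bind + params.k_unbind
    n_b = params.n_lefs * params.k_bind / denom if denom > 0 else 0.0
    d = config.n_sites / n_b if n_b > 0 else np.inf
    return DerivedScales(
        processivity=lam,
        separation=d,
        n_bound_mean=n_b,
        lam_over_d=lam / d if np.isfinite(d) and d > 0 else 0.0,
        v_diff_over_v=params.v_diff / params.v if params.v > 0 else np.inf,
        k_switch_over_k_unbind=(
            params.k_switch / params.k_unbind if params.k_unbind > 0 else np.inf
        ),
        k_switch_L_over_v=(
            params.k_switch * config.n_sites / params.v if params.v > 0 else np.inf
        ),
    )
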