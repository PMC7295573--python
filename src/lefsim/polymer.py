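"""Coarse-grained 3D polymer dynamics coupled to the 1D LEF engine.

The chromosome is a bead-spring chain of ``L`` monomers of diameter ``b``
(30 nm, ~3 nucleosomes, for mitotic runs).  Consecutive monomers -- and the
two monomers held by each bound LEF -- are joined by harmonic bonds
``U_b(r) = (k/2)(r - b)^2`` with ``k = 2kT/delta^2``, ``delta = 0.1``.
Monomers repel through a soft excluded-volume polynomial that equals
``eps_exc = 1.5 kT`` at contact and vanishes smoothly at ``sigma = 1.05 b``
(constants ``r_m = 6/7``, ``eps_m = 46656/823543``); an optional attraction
of depth ``eps`` acts on ``(sigma, 2b)``.

Integration is BAOAB Langevin dynamics with intermittent velocity rescaling
to temperature ``T``.  Internal units set ``m = b = kT = 1``; the MD step is
expressed on the conventional 80-unit scale of openmm-style polymer runs,
which maps to a dimensionless step ``dt_int`` with ``dt_int * omega_bond
~ 0.18`` (``omega_bond = sqrt(k/m)``), i.e. well inside the stable range.

After each 1D LEF step the chain evolves for 200 (interphase) or 250
(mitosis) MD steps with the LEF-bond list mirroring the 1D state exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .engine import SimState, fixed_step_run

__all__ = [
    "ForceField",
    "PolymerState",
    "init_polymer",
    "bond_energy",
    "excluded_energy",
    "attraction_energy",
    "couple_and_advance",
    "run_coupled",
    "concave_hull_volume",
    "hull_overlap_volume",
    "chromatid_resolution",
]

R_M = 6.0 / 7.0
EPS_M = 46656.0 / 823543.0  # = (6/7)^6 / 7: depth of t^6(t-1) at t = 6/7

# dt = 80 on the openmm-style scale corresponds to this dimensionless BAOAB
# step in units of m = b = kT = 1 (dt_int * omega_bond ~ 0.18)
DT_UNIT = 0.0125 / 80.0


@dataclass
class ForceField:
    """Force-field constants in units of the monomer diameter ``b`` and kT."""

    b: float = 1.0  # monomer diameter (30 nm for mitotic chromatin)
    delta: float = 0.1
    eps_exc: float = 1.5
    eps_att: float = 0.0  # attraction depth; off by default
    kT: float = 1.0
    mass: float = 1.0
    gamma: float = 0.5  # Langevin friction (1/time); overdamped on bond scale

    @property
    def k_spring(self) -> float:
        return 2.0 * self.kT / (self.delta * self.b) ** 2

    @property
    def sigma(self) -> float:
        return 1.05 * self.b


def bond_energy(r: float, ff: ForceField | None = None) -> float:
    """Harmonic bond ``U_b(r) = (k/2)(r-b)^2``; ``U_b(b(1+delta)) = kT``."""
    ff = ff or ForceField()
    return 0.5 * ff.k_spring * (r - ff.b) ** 2


def excluded_energy(r: float, ff: ForceField | None = None) -> float:
    """Soft repulsion: ``eps_exc`` at r=0, smoothly 0 at and beyond sigma.

    ``U(r) = eps_exc * [1 + z^6 (z - 1)/eps_m]`` with ``z = (r/sigma)^2 r_m``;
    the polynomial's minimum ``-eps_m`` at ``z = r_m`` (i.e. ``r = sigma``)
    makes both the energy and the force vanish at the cutoff.
    """
    ff = ff or ForceField()
    r = float(r)
    if r >= ff.sigma:
        return 0.0
    z = (r / ff.sigma) ** 2 * R_M
    return ff.eps_exc * (1.0 + z**6 * (z - 1.0) / EPS_M)


def attraction_energy(r: float, ff: ForceField) -> float:
    """Optional attraction of depth ``eps_att`` on ``(sigma, 2b)``.

    A smooth well ``-eps_att * sin^2(pi (r - sigma)/(2b - sigma))``: zero at
    both edges, depth ``eps_att`` at the center of the shell.
    """
    r = float(r)
    lo, hi = ff.sigma, 2.0 * ff.b
    if not lo < r < hi:
        return 0.0
    return -ff.eps_att * float(np.sin(np.pi * (r - lo) / (hi - lo)) ** 2)


@dataclass
class PolymerState:
    """Positions/velocities of the chain plus the live bond list."""

    positions: np.ndarray  # (L, 3)
    velocities: np.ndarray  # (L, 3)
    ff: ForceField = field(default_factory=ForceField)
    dt: float = 80.0  # openmm-scale step; internal step is dt * DT_UNIT
    extra_bonds: np.ndarray | None = None  # (m, 2) beyond backbone + LEFs

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    def backbone_bonds(self) -> np.ndarray:
        n = self.n_monomers
        out = np.empty((n - 1, 2), dtype=np.int64)
        out[:, 0] = np.arange(n - 1)
        out[:, 1] = np.arange(1, n)
        return out

    def bond_list(self, lef_state: SimState | None = None) -> np.ndarray:
        """Backbone + current LEF bonds (+ any extra bonds, e.g. centromere)."""
        parts = [self.backbone_bonds()]
        if lef_state is not None:
            loops = lef_state.loops()
            if loops:
                parts.append(np.asarray(loops, dtype=np.int64))
        if self.extra_bonds is not None and len(self.extra_bonds):
            parts.append(np.asarray(self.extra_bonds, dtype=np.int64))
        return np.concatenate(parts, axis=0)

    def kinetic_temperature(self) -> float:
        v2 = float(np.mean(np.sum(self.velocities**2, axis=1)))
        return self.ff.mass * v2 / 3.0


def init_polymer(
    n_monomers: int,
    b: float = 1.0,
    seed: int = 0,
    ff: ForceField | None = None,
) -> PolymerState:
    """Random-walk chain with step ``b`` and Maxwellian velocities at T."""
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    ff = ff or ForceField(b=b)
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_monomers - 1, 3))
    steps *= b / np.linalg.norm(steps, axis=1, keepdims=True)
    pos = np.zeros((n_monomers, 3))
    pos[1:] = np.cumsum(steps, axis=0)
    vel = rng.normal(scale=np.sqrt(ff.kT / ff.mass), size=(n_monomers, 3))
    return PolymerState(positions=pos, velocities=vel, ff=ff)


def advance(polymer: PolymerState, bonds: np.ndarray, n_md_steps: int,
            md_seed: int | None = None) -> None:
    """Advance the chain ``n_md_steps`` BAOAB steps with the given bonds."""
    ff = polymer.ff
    if md_seed is not None:
        K.seed_rng(int(md_seed) & 0x7FFFFFFF)
    status = K.langevin_run(
        polymer.positions, polymer.velocities, np.ascontiguousarray(bonds),
        ff.k_spring, ff.b, ff.eps_exc, ff.sigma, R_M, EPS_M,
        ff.kT, ff.mass, ff.gamma, polymer.dt * DT_UNIT, int(n_md_steps),
        10, 0.5 * ff.b, 100,
    )
    if status != 0:
        raise FloatingPointError(
            "polymer coordinates diverged (non-finite); reduce dt"
        )


def couple_and_advance(
    lef_state: SimState,
    polymer: PolymerState,
    n_md_steps: int = 250,
    lef_dt: float = 1.0,
) -> None:
    """One LEF time step followed by ``n_md_steps`` Langevin steps.

    The 1D state advances by one fixed-time-step sweep; the LEF bond list is
    then rebuilt atomically before the MD segment, so the 3D bonds mirror
    the 1D LEF occupancy exactly at every segment boundary.
    """
    if polymer.n_monomers != lef_state.config.n_sites:
        raise ValueError("polymer length must equal the 1D lattice length")
    fixed_step_run(lef_state, lef_dt, lef_state.time + lef_dt,
                   n_samples=1, method="sweep")
    advance(polymer, polymer.bond_list(lef_state), n_md_steps)


def run_coupled(
    lef_state: SimState,
    polymer: PolymerState,
    n_lef_steps: int,
    n_md_steps: int = 250,
    lef_dt: float = 1.0,
    sample_every: int = 0,
):
    """Drive the coupled 1D+3D simulation; optionally collect conformations."""
    confs = []
    for step in range(n_lef_steps):
        couple_and_advance(lef_state, polymer, n_md_steps, lef_dt)
        if sample_every and (step + 1) % sample_every == 0:
            confs.append(polymer.positions.copy())
    return confs


# ---------------------------------------------------------------------------
# 3D observables
# ---------------------------------------------------------------------------

def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumsphere radii of tetrahedra (vectorized)."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]] - a
    c = points[simplices[:, 2]] - a
    d = points[simplices[:, 3]] - a
    b2 = np.sum(b * b, axis=1)
    c2 = np.sum(c * c, axis=1)
    d2 = np.sum(d * d, axis=1)
    M = np.stack([b, c, d], axis=1)  # (n, 3, 3)
    det = np.linalg.det(M)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs = 0.5 * np.stack([b2, c2, d2], axis=1)[:, :, None]
        centers = np.linalg.solve(
            np.where(np.abs(det)[:, None, None] > 1e-12, M,
                     np.eye(3)[None, :, :]),
            rhs,
        )[:, :, 0]
    r = np.linalg.norm(centers, axis=1)
    r[np.abs(det) <= 1e-12] = np.inf
    return r


def _alpha_keep(points: np.ndarray, r_hull: float):
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    radii = _circumradii(points, tri.simplices)
    keep = radii <= r_hull
    return tri, keep


def concave_hull_volume(positions: np.ndarray, r_hull: float) -> float:
    """Volume of the alpha shape of the points with probe radius ``r_hull``.

    Tetrahedra of the Delaunay triangulation whose circumradius exceeds the
    probe radius are discarded; ``r_hull -> inf`` recovers the convex hull.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape[0] < 4:
        raise ValueError("need >= 4 points")
    tri, keep = _alpha_keep(positions, r_hull)
    if not np.any(keep):
        raise ValueError("degenerate geometry: no tetrahedron within probe radius")
    s = tri.simplices[keep]
    a = positions[s[:, 0]]
    v = np.abs(
        np.linalg.det(
            np.stack(
                [positions[s[:, 1]] - a, positions[s[:, 2]] - a,
                 positions[s[:, 3]] - a],
                axis=1,
            )
        )
    ) / 6.0
    return float(v.sum())


def hull_overlap_volume(
    pos1: np.ndarray, pos2: np.ndarray, r_hull: float, voxel: float
) -> float:
    """Overlap volume of two alpha shapes by voxel counting at pitch ``voxel``."""
    tri1, keep1 = _alpha_keep(np.asarray(pos1, float), r_hull)
    tri2, keep2 = _alpha_keep(np.asarray(pos2, float), r_hull)
    lo = np.maximum(pos1.min(axis=0), pos2.min(axis=0))
    hi = np.minimum(pos1.max(axis=0), pos2.max(axis=0))
    if np.any(hi <= lo):
        return 0.0
    axes = [np.arange(lo[c] + voxel / 2, hi[c], voxel) for c in range(3)]
    if any(len(ax) == 0 for ax in axes):
        return 0.0
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def inside(tri, keep, p):
        s = tri.find_simplex(p)
        ok = s >= 0
        ok[ok] = keep[s[ok]]
        return ok

    both = inside(tri1, keep1, pts) & inside(tri2, keep2, pts)
    return float(both.sum()) * voxel**3


def backbone_monomers(n_monomers: int, loops) -> np.ndarray:
    """Monomers outside all loops, plus the loop anchors."""
    inside = np.zeros(n_monomers, dtype=bool)
    for l, r in loops:
        inside[l + 1 : r] = True
        # anchors stay on the backbone
    return np.nonzero(~inside)[0]


def chromatid_resolution(
    pos1: np.ndarray,
    pos2: np.ndarray,
    loops1,
    loops2,
    r_hull: float,
    voxel: float | None = None,
    rb_mode: str = "mean-bond",
) -> dict:
    """Spatial-resolution observables of a sister-chromatid pair.

    ``dR``: symmetrized median over backbone monomers of one chain of the
    minimum distance to the other chain's backbone.  ``R_b`` normalizes
    ``dR``; ``rb_mode='mean-bond'`` uses the mean 3D distance between
    consecutive backbone monomers, ``'path-length'`` the total backbone path
    length.  ``V_o`` is the alpha-shape overlap volume (voxelized).
    """
    from scipy.spatial import cKDTree

    b1 = np.asarray(pos1, float)[backbone_monomers(len(pos1), loops1)]
    b2 = np.asarray(pos2, float)[backbone_monomers(len(pos2), loops2)]
    d12 = cKDTree(b2).query(b1)[0]
    d21 = cKDTree(b1).query(b2)[0]
    dr = 0.5 * (float(np.median(d12)) + float(np.median(d21)))
    seg1 = np.linalg.norm(np.diff(b1, axis=0), axis=1)
    seg2 = np.linalg.norm(np.diff(b2, axis=0), axis=1)
    if rb_mode == "mean-bond":
        rb = 0.5 * (float(seg1.mean()) + float(seg2.mean()))
    elif rb_mode == "path-length":
        rb = 0.5 * (float(seg1.sum()) + float(seg2.sum()))
    else:
        raise ValueError(f"unknown rb_mode {rb_mode!r}")
    out = {"dR": dr, "R_b": rb, "dR_over_Rb": dr / rb if rb > 0 else np.inf}
    if voxel is not None:
        out["V_overlap"] = hull_overlap_volume(pos1, pos2, r_hull, voxel)
    return out


def write_pdb(path, positions, chain_breaks=()) -> None:
    """Minimal PDB: CA pseudo-atoms, one chain per chromatid."""
    positions = np.asarray(positions)
    breaks = set(chain_breaks)
    chain_ids = "ABCDEFGH"
    with open(path, "w") as fh:
        chain = 0
        for i, p in enumerate(positions):
            if i in breaks:
                fh.write("TER\n")
                chain += 1
            fh.write(
                f"ATOM  {i % 99999 + 1:5d}  CA  GLY {chain_ids[chain % 8]}"
                f"{i % 9999 + 1:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


def write_xyz(path, positions, comment: str = "") -> None:
    positions = np.asarray(positions)
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for p in positions:
            fh.write(f"C {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
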