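"""Semi-analytic contact maps from 1D LEF snapshots (Gaussian-chain theory).

For an ideal (Gaussian) chain the contact probability of two loci decays as
``s^{-3/2}`` with their contour separation ``s``.  A LEF bridges the two
anchors of its loop, so loops reshape the effective contour:

* a loop lying wholly between the two loci contributes nothing (its anchors
  coincide),
* two loci inside the same loop of (collapsed) length ``ell`` at collapsed
  separation ``s`` interact at effective separation ``s_eff = s(1 - s/ell)``
  (the Brownian-bridge variance),
* a locus inside a loop at collapsed arc ``t`` from an anchor contributes
  ``t(1 - t/ell)`` toward that anchor point,
* plain linkers contribute their length, and nested loops are collapsed
  innermost-first.

Averaging ``p = max(s_eff, s_floor)^{-3/2}`` over many steady-state
snapshots yields a relative contact map, the method used here for bacterial
chromosomes and as a fast 1D proxy for interphase maps.  It is not
appropriate for strongly compacted (mitotic) chromosomes, where the chain
is far from ideal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .metrics import LoopForest, build_loop_forest

__all__ = [
    "ContactMap",
    "effective_separation",
    "contact_probability",
    "accumulate_map",
    "expected_by_distance",
    "observed_over_expected",
    "sample_walk_contact_exponent",
    "sample_loop_constrained_map",
]

S_FLOOR = 1.0  # sites; caps the s^{-3/2} divergence at contact


@dataclass
class ContactMap:
    """Square matrix of relative contact frequencies with bin coordinates."""

    matrix: np.ndarray
    bin_size_sites: int
    site_size_kb: float
    n_snapshots: int = 0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def bin_size_kb(self) -> float:
        return self.bin_size_sites * self.site_size_kb

    def site_to_bin(self, site: int) -> int:
        return int(site) // self.bin_size_sites

    def normalized(self) -> "ContactMap":
        """Scale so the main diagonal equals 1."""
        d = np.diag(self.matrix).copy()
        d[d == 0] = 1.0
        return ContactMap(self.matrix / np.sqrt(np.outer(d, d)),
                          self.bin_size_sites, self.site_size_kb,
                          self.n_snapshots)

    def write_text(self, path) -> None:
        header = (f"n_bins={self.n_bins}\tbin_size_kb={self.bin_size_kb}"
                  f"\tn_snapshots={self.n_snapshots}")
        np.savetxt(path, self.matrix, header=header, delimiter="\t")

    @classmethod
    def read_text(cls, path) -> "ContactMap":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        fields = dict(kv.split("=") for kv in header.split("\t"))
        m = np.loadtxt(path, delimiter="\t")
        bs_kb = float(fields["bin_size_kb"])
        return cls(m, bin_size_sites=1, site_size_kb=bs_kb,
                   n_snapshots=int(fields.get("n_snapshots", 0)))

    def write_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("matrix", data=self.matrix)
            ds.attrs["bin_size_sites"] = self.bin_size_sites
            ds.attrs["site_size_kb"] = self.site_size_kb
            ds.attrs["n_snapshots"] = self.n_snapshots

    @classmethod
    def read_hdf5(cls, path) -> "ContactMap":
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh["matrix"]
            return cls(ds[...], int(ds.attrs["bin_size_sites"]),
                       float(ds.attrs["site_size_kb"]),
                       int(ds.attrs["n_snapshots"]))

    def render_png(self, path, log: bool = True) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.matrix.copy()
        if log:
            floor = m[m > 0].min() if np.any(m > 0) else 1e-9
            m = np.log10(np.maximum(m, floor))
        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(m, cmap="afmhot_r", origin="upper")
        fig.colorbar(im, ax=ax, label="log10 relative contact frequency"
                     if log else "relative contact frequency")
        ax.set_xlabel(f"bin ({self.bin_size_kb:g} kb)")
        ax.set_ylabel(f"bin ({self.bin_size_kb:g} kb)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def effective_separation(i: int, j: int, forest: LoopForest) -> float:
    """Effective Gaussian contour separation between sites ``i`` and ``j``.

    Computed by collapsing loops innermost-first: whole loops between the
    sites contribute 0, partial loops contribute the Brownian-bridge arc
    ``t(1 - t/ell)``, linkers their plain length.
    """
    if forest.flat:
        raise ValueError(
            "effective separation is undefined for traversal (overlapping-"
            "loop) snapshots: the Gaussian loop decomposition breaks down"
        )
    nl = len(forest.loops)
    l = np.empty(nl, dtype=np.int64)
    r = np.empty(nl, dtype=np.int64)
    order = sorted(range(nl), key=lambda k: forest.loops[k][0])
    for a, k in enumerate(order):
        l[a], r[a] = forest.loops[k]
    parent = np.empty(nl, dtype=np.int64)
    span = np.empty(nl, dtype=np.float64)
    if K._build_forest_arrays(l, r, nl, parent, span) != 0:
        raise ValueError("crossing loop intervals")
    return float(K._s_eff_arrays(l, r, parent, span, nl, int(i), int(j)))


def contact_probability(s_eff: float, s_floor: float = S_FLOOR) -> float:
    """Relative contact probability ``max(s_eff, s_floor)^{-3/2}``."""
    if s_eff < 0:
        raise ValueError("s_eff must be >= 0")
    return float(max(s_eff, s_floor) ** -1.5)


def _snapshot_arrays(snapshots):
    lefts, rights, offsets = [], [], [0]
    for snap in snapshots:
        for l, r in snap:
            lefts.append(l)
            rights.append(r)
        offsets.append(len(lefts))
    return (np.asarray(lefts, dtype=np.int64),
            np.asarray(rights, dtype=np.int64),
            np.asarray(offsets, dtype=np.int64))


def accumulate_map(
    snapshots,
    n_sites: int,
    bin_size_sites: int = 1,
    site_size_kb: float = 1.0,
    s_floor: float = S_FLOOR,
) -> ContactMap:
    """Average the Gaussian-chain contact probabilities over LEF snapshots.

    ``snapshots`` is an iterable of loop lists ``[(left, right), ...]``
    (e.g. ``traj.loops(i)`` for post-burn-in ``i``).  Probabilities are
    evaluated between bin-center sites.  Snapshots with crossing intervals
    (traversal) are skipped, mirroring the Gaussian theory's domain.
    """
    snapshots = list(snapshots)
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    lefts, rights, offsets = _snapshot_arrays(snapshots)
    n_bins = int(np.ceil(n_sites / bin_size_sites))
    bin_sites = np.minimum(
        np.arange(n_bins, dtype=np.int64) * bin_size_sites + bin_size_sites // 2,
        n_sites - 1,
    )
    out = np.zeros((n_bins, n_bins), dtype=np.float64)
    skipped = K.accumulate_gaussian_map(lefts, rights, offsets, bin_sites,
                                        float(s_floor), out)
    used = len(snapshots) - int(skipped)
    if used == 0:
        raise ValueError("all snapshots had crossing loops")
    out /= used
    return ContactMap(out, bin_size_sites, site_size_kb, used)


def expected_by_distance(matrix: np.ndarray) -> np.ndarray:
    """Mean contact frequency at each bin distance (the 'expected' vector)."""
    n = matrix.shape[0]
    exp = np.empty(n)
    for k in range(n):
        exp[k] = np.mean(np.diagonal(matrix, offset=k))
    return exp


def observed_over_expected(matrix: np.ndarray) -> np.ndarray:
    """Divide each diagonal by its mean, removing the distance dependence."""
    n = matrix.shape[0]
    exp = expected_by_distance(matrix)
    exp[exp == 0] = 1.0
    i, j = np.indices((n, n))
    return matrix / exp[np.abs(i - j)]


# ---------------------------------------------------------------------------
# Monte-Carlo oracles: explicit 3D random-walk conformations
# ---------------------------------------------------------------------------

def sample_walk_contact_exponent(
    n_walks: int = 100_000,
    n_steps: int = 200,
    capture_radius: float = 2.0,
    s_min: int = 10,
    s_max: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Contact-frequency decay exponent of a free 3D Gaussian random walk.

    Draws ``n_walks`` unit-step Gaussian walks, measures the probability
    that two loci ``s`` steps apart lie within ``capture_radius``, and fits
    ``log P`` vs ``log s`` over ``[s_min, s_max]``.  The fitted slope is the
    independent check of the ``s^{-3/2}`` law underlying the semi-analytic
    maps.  Returns ``(slope, s_values, P_values)``.
    """
    rng = rng or np.random.default_rng()
    s_vals = np.unique(
        np.round(np.logspace(np.log10(s_min), np.log10(s_max), 12)).astype(int)
    )
    probs = np.empty(len(s_vals))
    chunk = 20_000
    counts = np.zeros(len(s_vals))
    total = np.zeros(len(s_vals))
    done = 0
    while done < n_walks:
        m = min(chunk, n_walks - done)
        steps = rng.normal(size=(m, n_steps, 3)) / np.sqrt(3.0)
        pos = np.cumsum(steps, axis=1)
        for a, s in enumerate(s_vals):
            # all start positions with separation s
            d = pos[:, s:, :] - pos[:, :-s, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            counts[a] += np.count_nonzero(r2 < capture_radius**2)
            total[a] += r2.size
        done += m
    probs = counts / total
    slope = float(np.polyfit(np.log(s_vals), np.log(probs), 1)[0])
    return slope, s_vals, probs


def sample_loop_constrained_map(
    n_sites: int,
    loops,
    n_conformations: int = 20_000,
    capture_radius: float = 2.0,
    bin_size_sites: int = 1,
    rng: np.random.Generator | None = None,
) -> ContactMap:
    """Monte-Carlo contact map with loop anchors constrained to coincide.

    Draws explicit 3D Gaussian conformations in which each (disjoint,
    non-nested) loop is a Brownian bridge returning to its left anchor, and
    counts capture-radius contacts between bin centers.  Serves as the
    sampling oracle for the semi-analytic map on small systems.
    """
    rng = rng or np.random.default_rng()
    loops = sorted((int(l), int(r)) for l, r in loops)
    for (l1, r1), (l2, r2) in zip(loops, loops[1:]):
        if l2 <= r1:
            raise ValueError("oracle supports disjoint, non-nested loops only")
    n_bins = int(np.ceil(n_sites / bin_size_sites))
    bin_sites = np.minimum(
        np.arange(n_bins) * bin_size_sites + bin_size_sites // 2, n_sites - 1
    )
    counts = np.zeros((n_bins, n_bins))
    chunk = 2_000
    done = 0
    while done < n_conformations:
        m = min(chunk, n_conformations - done)
        steps = rng.normal(size=(m, n_sites - 1, 3)) / np.sqrt(3.0)
        pos = np.zeros((m, n_sites, 3))
        pos[:, 1:, :] = np.cumsum(steps, axis=1)
        # turn each loop's interior walk into a bridge, then rigidly shift
        # the downstream chain so the right anchor lands on the left anchor
        for l, r in loops:
            seg = pos[:, l : r + 1, :] - pos[:, l : l + 1, :]
            ell = r - l
            tfrac = (np.arange(ell + 1) / ell)[None, :, None]
            bridge = seg - tfrac * seg[:, -1:, :]
            shift = pos[:, r : r + 1, :] - (bridge[:, -1:, :] + pos[:, l : l + 1, :])
            pos[:, l : r + 1, :] = bridge + pos[:, l : l + 1, :]
            pos[:, r + 1 :, :] -= shift
        sub = pos[:, bin_sites, :]
        d = sub[:, :, None, :] - sub[:, None, :, :]
        r2 = np.einsum("ijkl,ijkl->ijk", d, d)
        counts += np.count_nonzero(r2 < capture_radius**2, axis=0)
        done += m
    return ContactMap(counts / done, bin_size_sites, 1.0, done)
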