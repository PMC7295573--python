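"""Linear-compaction observables from LEF snapshots.

The compacted fraction ``f`` is the fraction of lattice sites lying inside
the union of all extruded loops; the linear fold compaction is
``FC = 1/(1 - f)``.  Gaps are maximal unlooped runs of sites strictly
between two consecutive parent (outermost) loops; the gap statistic
``n_g / n_l`` -- gaps per parent loop -- is the quantity that limits
one-sided extrusion to its ~10-fold compaction plateau, while the
theoretical prediction for freely traversing LEFs is coverage-based
``FC = e^{lambda/d}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory

__all__ = [
    "LoopForest",
    "CompactionSummary",
    "build_loop_forest",
    "compacted_fraction",
    "count_gaps",
    "coverage_sites",
    "steady_state_summary",
]


class CrossingLoopsError(ValueError):
    """Crossing (pseudoknotted) intervals in a non-traversal snapshot."""


@dataclass
class LoopForest:
    """Containment forest of loop intervals ``[left, right]`` (closed, sites).

    Without traversal, loops are pairwise disjoint or strictly nested;
    ``parent_of[i]`` is the index of the smallest enclosing loop (or None),
    ``children[i]`` the inverse map, ``depth[i]`` the nesting depth (0 for
    parent loops).  With traversal, overlapping intervals are kept flat
    (every parent None) and only the coverage union is meaningful.
    """

    loops: list[tuple[int, int]]
    parent_of: list[int | None]
    children: dict[int, list[int]]
    depth: list[int]
    flat: bool = False

    @property
    def parents(self) -> list[tuple[int, int]]:
        """Outermost loops, ordered along the lattice."""
        if self.flat:
            return sorted(self.loops)
        return sorted(
            self.loops[i] for i in range(len(self.loops)) if self.depth[i] == 0
        )

    def collapsed_length(self, i: int) -> int:
        """Contour length of loop i with its direct children collapsed."""
        l, r = self.loops[i]
        out = r - l
        for c in self.children.get(i, []):
            cl, cr = self.loops[c]
            out -= cr - cl
        return out


def build_loop_forest(snapshot, traversal: bool = False) -> LoopForest:
    """Build the nesting forest from a list of ``(left, right)`` intervals.

    Raises :class:`CrossingLoopsError` on crossing intervals unless
    ``traversal`` is set, in which case a flat forest is returned.
    """
    loops = [(int(l), int(r)) for l, r in snapshot]
    for l, r in loops:
        if l >= r:
            raise ValueError(f"invalid loop ({l}, {r}): need left < right")
    if traversal:
        return LoopForest(loops=loops, parent_of=[None] * len(loops),
                          children={}, depth=[0] * len(loops), flat=True)
    order = sorted(range(len(loops)), key=lambda i: (loops[i][0], -loops[i][1]))
    parent = [None] * len(loops)
    depth = [0] * len(loops)
    children: dict[int, list[int]] = {}
    stack: list[int] = []
    for i in order:
        l, r = loops[i]
        while stack and loops[stack[-1]][1] < l:
            stack.pop()
        if stack:
            pl, pr = loops[stack[-1]]
            if r > pr:
                raise CrossingLoopsError(
                    f"loops ({pl},{pr}) and ({l},{r}) cross; "
                    "not a valid non-traversal snapshot"
                )
            parent[i] = stack[-1]
            depth[i] = depth[stack[-1]] + 1
            children.setdefault(stack[-1], []).append(i)
        stack.append(i)
    return LoopForest(loops=loops, parent_of=parent, children=children,
                      depth=depth)


def coverage_sites(forest: LoopForest) -> int:
    """Number of lattice sites inside the union of all loops (closed)."""
    ivs = sorted(forest.loops)
    total = 0
    cur_l = cur_r = None
    for l, r in ivs:
        if cur_r is None:
            cur_l, cur_r = l, r
        elif l <= cur_r + 0:  # overlapping or sharing sites
            cur_r = max(cur_r, r)
        else:
            total += cur_r - cur_l + 1
            cur_l, cur_r = l, r
    if cur_r is not None:
        total += cur_r - cur_l + 1
    return total


def compacted_fraction(forest: LoopForest, n_sites: int,
                       margin: int = 0) -> float:
    """f = (sites inside the union of all loops) / L.

    ``margin > 0`` restricts the count to the interior window
    ``[margin, L - 1 - margin]``: near the open lattice ends loops are
    systematically sparser (no loops can reach in from outside), and the
    interior window removes that finite-size artifact when comparing
    against infinite-lattice coverage laws.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if margin <= 0:
        return coverage_sites(forest) / n_sites
    lo, hi = margin, n_sites - 1 - margin
    if hi <= lo:
        raise ValueError("margin leaves no interior window")
    covered = 0
    cur_l = cur_r = None
    for l, r in sorted(forest.loops):
        l, r = max(l, lo), min(r, hi)
        if l > r:
            continue
        if cur_r is None:
            cur_l, cur_r = l, r
        elif l <= cur_r:
            cur_r = max(cur_r, r)
        else:
            covered += cur_r - cur_l + 1
            cur_l, cur_r = l, r
    if cur_r is not None:
        covered += cur_r - cur_l + 1
    return covered / (hi - lo + 1)


def fold_compaction(f: float, n_sites: int | None = None) -> float:
    """FC = 1/(1-f); a fully covered lattice is capped at FC = L (resolution
    limit of the lattice) when ``n_sites`` is given, else inf."""
    if f >= 1.0:
        return float(n_sites) if n_sites else float("inf")
    return 1.0 / (1.0 - f)


def count_gaps(forest: LoopForest, n_sites: int) -> tuple[int, int]:
    """(n_g, n_l): internal unlooped gaps and parent-loop count.

    A gap is a maximal run of >= 1 unlooped site strictly between two
    consecutive parent loops; the lattice ends before the first and after
    the last parent loop are uncompacted but not counted as gaps.
    """
    parents = forest.parents
    n_l = len(parents)
    n_g = 0
    for (l1, r1), (l2, r2) in zip(parents, parents[1:]):
        if l2 - r1 >= 2:
            n_g += 1
    return n_g, n_l


@dataclass
class CompactionSummary:
    """Time-averaged compaction observables of one or more trajectories."""

    f: float
    fc: float  # mean of per-snapshot FC
    fc_from_mean_f: float  # 1/(1 - mean f)
    n_g: float
    n_l: float
    gaps_per_loop: float
    loop_coverage: float
    coverage_fc: float  # 1/(1 - mean coverage); the traversal observable
    fc_sem: float = float("nan")
    n_snapshots: int = 0
    n_replicates: int = 1
    per_replicate_fc: list = field(default_factory=list)


def _snapshot_stats(traj: Trajectory, i: int, traversal: bool,
                    coverage_margin: int = 0):
    forest = build_loop_forest(traj.loops(i), traversal=traversal)
    f = compacted_fraction(forest, traj.n_sites, margin=coverage_margin)
    if traversal:
        ng, nl = 0, len(forest.loops)
    else:
        ng, nl = count_gaps(forest, traj.n_sites)
    return f, fold_compaction(f, traj.n_sites), ng, nl


def steady_state_summary(
    trajectories: Trajectory | list[Trajectory],
    burn_in: float,
    traversal: bool = False,
    coverage_margin: int = 0,
) -> CompactionSummary:
    """Average f, FC and gap statistics over post-burn-in snapshots.

    ``FC`` is the mean of per-snapshot ``1/(1-f)`` (the transform of the
    averaged ``f`` is also reported); the gap statistic is the ratio of the
    time-averaged gap and parent-loop counts.  With several replicate
    trajectories the per-replicate mean FCs give the standard error.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    rep_fc = []
    all_f: list[float] = []
    all_fc: list[float] = []
    sum_ng = 0.0
    sum_nl = 0.0
    n_snap = 0
    for traj in trajectories:
        mask = traj.times >= burn_in
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            raise ValueError("no snapshots after burn_in")
        fcs = []
        for i in idx:
            f, fc, ng, nl = _snapshot_stats(traj, int(i), traversal,
                                            coverage_margin)
            all_f.append(f)
            fcs.append(fc)
            sum_ng += ng
            sum_nl += nl
        all_fc.extend(fcs)
        rep_fc.append(float(np.mean(fcs)))
        n_snap += len(idx)
    mean_f = float(np.mean(all_f))
    fc_sem = (
        float(np.std(rep_fc, ddof=1) / np.sqrt(len(rep_fc)))
        if len(rep_fc) > 1
        else float("nan")
    )
    return CompactionSummary(
        f=mean_f,
        fc=float(np.mean(all_fc)),
        fc_from_mean_f=fold_compaction(mean_f, trajectories[0].n_sites),
        n_g=sum_ng / n_snap,
        n_l=sum_nl / n_snap,
        gaps_per_loop=sum_ng / sum_nl if sum_nl > 0 else float("nan"),
        loop_coverage=mean_f,
        coverage_fc=fold_compaction(mean_f, trajectories[0].n_sites),
        fc_sem=fc_sem,
        n_snapshots=n_snap,
        n_replicates=len(trajectories),
        per_replicate_fc=rep_fc,
    )
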