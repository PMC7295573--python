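"""Numba kernels for the 1D LEF engine, contact maps and 3D dynamics.

The single-event helpers (`_bind_attempt`, `_do_unbind`, `_try_step`,
`_try_diff`, `_do_switch`) encode the model rules once; both schedulers and
the Python-level single-event API call them, so there is one source of truth
for the dynamics.

Scheduler implementations:

* ``run_gillespie`` -- continuous-time dynamics sampled by uniformization:
  every bound LEF carries a constant total event-rate bound (unbind + two
  step slots + switch + diffusive grow/shrink bounds), waiting times are
  exponential in the global bound rate, and inapplicable or thinned events
  are no-ops.  This is statistically exact for the underlying Markov chain.
* ``run_fixed_step`` -- the discrete-time chain in which every candidate
  event fires independently with probability ``k_i * dt`` per step, executed
  by per-slot geometric waiting times with thinning (identical chain law to
  a literal per-step Bernoulli sweep, but with cost proportional to the
  number of events rather than the number of steps).
* ``run_sweep`` -- the literal per-step Bernoulli sweep over a random
  permutation of LEFs; also provides the deterministic-extruder mode used
  for bacterial chromosomes (active subunits step every ``dt`` with
  probability 1) and the hook for 3D coupling (one call per LEF step).

Event codes returned by the helpers: 0 = no state change (rejected/blocked/
no-op), 1 = moved, 2 = the LEF unbound (terminal unloading), 3 = bound.
"""

from __future__ import annotations

import numpy as np
from numba import njit

E32 = float(np.exp(1.5))
# Constant upper bound for the shrink-rate bias: shrinking is rejected at the
# minimum loop (ell = 1), so the largest attainable rate is at ell = 2, i.e.
# v_diff * e^{3/4}.  Thinning against this bound is exact.
SHRINK_BOUND = float(np.exp(0.75))

CAT_UNBIND = 0
CAT_STEP_L = 1
CAT_STEP_R = 2
CAT_SWITCH = 3
CAT_DIFF_GROW = 4
CAT_DIFF_SHRINK = 5
CAT_BIND = 6
N_CATS = 7


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline='always')
def _draw_load_site(load_cdf, uniform_load, L):
    """Draw a loading site i (the LEF occupies (i, i+1)) from the weights."""
    if uniform_load:
        return np.random.randint(0, L - 1)
    total = load_cdf[L - 2]
    u = np.random.random() * total
    lo = 0
    hi = L - 2
    while lo < hi:
        mid = (lo + hi) // 2
        if load_cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True, inline='always')
def _bind_attempt(
    lef,
    left, right, act_l, act_r, stall_l, stall_r, bound, two_s,
    occ, occ_side, passed,
    load_cdf, uniform_load, orient,
    sidedness, traversal,
):
    """Attempt to bind an unbound LEF at a weighted random pair of sites."""
    L = occ.shape[0]
    i = _draw_load_site(load_cdf, uniform_load, L)
    if traversal == 0 and (occ[i] != 0 or occ[i + 1] != 0):
        return 0  # rejection is a legal outcome; the event is consumed
    left[lef] = i
    right[lef] = i + 1
    bound[lef] = 1
    stall_l[lef] = 0
    stall_r[lef] = 0
    for b in range(passed.shape[2]):
        passed[lef, 0, b] = 0
        passed[lef, 1, b] = 0
    if np.random.random() < sidedness:
        two_s[lef] = 1
        act_l[lef] = 1
        act_r[lef] = 1
    else:
        two_s[lef] = 0
        o = orient[i]
        if o > 0:  # directional loading: extrude rightward, away from the barrier
            act_l[lef] = 0
            act_r[lef] = 1
        elif o < 0:
            act_l[lef] = 1
            act_r[lef] = 0
        elif np.random.random() < 0.5:
            act_l[lef] = 1
            act_r[lef] = 0
        else:
            act_l[lef] = 0
            act_r[lef] = 1
    if traversal == 0:
        occ[i] = lef + 1
        occ_side[i] = 0
        occ[i + 1] = lef + 1
        occ_side[i + 1] = 1
    return 3


@njit(cache=True, inline='always')
def _do_unbind(
    lef,
    left, right, act_l, act_r, stall_l, stall_r, bound, two_s,
    occ, occ_side,
    traversal,
):
    if traversal == 0:
        occ[left[lef]] = 0
        occ[right[lef]] = 0
    left[lef] = -1
    right[lef] = -1
    act_l[lef] = 0
    act_r[lef] = 0
    stall_l[lef] = 0
    stall_r[lef] = 0
    two_s[lef] = 0
    bound[lef] = 0
    return 2


@njit(cache=True, inline='always')
def _barrier_roll(
    lef, side, tgt, dirn,
    stall_l, stall_r,
    stallp_l, stallp_r, bar_id_l, bar_id_r, passed,
):
    """Evaluate a directional barrier at the target site.

    Returns 1 if the subunit stalls (flag set permanently for this binding
    event), 0 if it may proceed.  A 'pass' outcome is remembered per
    (subunit, barrier) so the stall probability is rolled only once per
    binding event.
    """
    if dirn > 0:
        p = stallp_r[tgt]
        bid = bar_id_r[tgt]
    else:
        p = stallp_l[tgt]
        bid = bar_id_l[tgt]
    if bid >= 0 and p > 0.0:
        if passed[lef, side, bid] == 0:
            if np.random.random() < p:
                if side == 0:
                    stall_l[lef] = 1
                else:
                    stall_r[lef] = 1
                return 1
            passed[lef, side, bid] = 1
    return 0


@njit(cache=True, inline='always')
def _try_step(
    lef, side,
    left, right, act_l, act_r, stall_l, stall_r, bound, two_s,
    occ, occ_side,
    stallp_l, stallp_r, bar_id_l, bar_id_r, passed, unload,
    traversal, pushing,
):
    """One active-translocation attempt, away from the partner subunit."""
    if bound[lef] == 0:
        return 0
    if side == 0:
        if act_l[lef] == 0 or stall_l[lef] == 1:
            return 0
        pos = left[lef]
        dirn = -1
    else:
        if act_r[lef] == 0 or stall_r[lef] == 1:
            return 0
        pos = right[lef]
        dirn = 1
    L = occ.shape[0]
    tgt = pos + dirn
    if tgt < 0 or tgt >= L:
        return 0
    if traversal == 0 and occ[tgt] != 0:
        if pushing == 0:
            return 0
        # scan the train of contiguous passive, unstalled subunits ahead
        ntrain = 0
        p = tgt
        while 0 <= p < L and occ[p] != 0:
            olef = occ[p] - 1
            oside = occ_side[p]
            if oside == 0:
                oact = act_l[olef]
                ostall = stall_l[olef]
            else:
                oact = act_r[olef]
                ostall = stall_r[olef]
            if oact == 1 or ostall == 1:
                return 0  # only passive subunits can be displaced
            ntrain += 1
            if pushing == 1 and ntrain > 1:
                return 0  # weak pushing: a single passive subunit only
            p += dirn
        if p < 0 or p >= L:
            return 0
        if unload[p] != 0:
            return 0  # do not push a passive subunit into the unloading region
        if _barrier_roll(lef, side, tgt, dirn, stall_l, stall_r,
                         stallp_l, stallp_r, bar_id_l, bar_id_r, passed) == 1:
            return 0
        # shift the train one site, starting from its far end
        q = p - dirn
        while q != pos:
            olef = occ[q] - 1
            oside = occ_side[q]
            occ[q + dirn] = occ[q]
            occ_side[q + dirn] = occ_side[q]
            occ[q] = 0
            if oside == 0:
                left[olef] = q + dirn
            else:
                right[olef] = q + dirn
            q -= dirn
    else:
        if _barrier_roll(lef, side, tgt, dirn, stall_l, stall_r,
                         stallp_l, stallp_r, bar_id_l, bar_id_r, passed) == 1:
            return 0
    if unload[tgt] != 0:
        return _do_unbind(lef, left, right, act_l, act_r, stall_l, stall_r,
                          bound, two_s, occ, occ_side, traversal)
    if traversal == 0:
        occ[pos] = 0
        occ[tgt] = lef + 1
        occ_side[tgt] = side
    if side == 0:
        left[lef] = tgt
    else:
        right[lef] = tgt
    return 1


@njit(cache=True, inline='always')
def _try_diff(
    lef, grow,
    left, right, act_l, act_r, stall_l, stall_r, bound, two_s,
    occ, occ_side,
    stallp_l, stallp_r, bar_id_l, bar_id_r, passed, unload,
    traversal,
):
    """One diffusive-step attempt of the passive subunit (semi-diffusive model).

    The caller draws attempts at the constant bound rates ``v_diff`` (grow)
    and ``v_diff * e^{3/2}`` (shrink); this helper thins them down to the
    loop-size-dependent rates ``v_diff * exp(-+ (3/2) / ell)``, evaluated at
    the current loop size, so the rates track every loop-size change.
    """
    if bound[lef] == 0 or two_s[lef] == 1:
        return 0
    side = 0 if act_l[lef] == 0 else 1  # the passive (diffusive) side
    if (stall_l[lef] if side == 0 else stall_r[lef]) == 1:
        return 0
    ell = right[lef] - left[lef]
    if grow:
        accept = np.exp(-1.5 / ell)
        dirn = -1 if side == 0 else 1
    else:
        if ell <= 1:
            return 0  # hard floor: minimum loop is two adjacent sites
        accept = np.exp(1.5 / ell - 0.75)  # actual / bound (<= 1 for ell >= 2)
        dirn = 1 if side == 0 else -1
    if np.random.random() >= accept:
        return 0
    pos = left[lef] if side == 0 else right[lef]
    L = occ.shape[0]
    tgt = pos + dirn
    if tgt < 0 or tgt >= L:
        return 0
    if traversal == 0 and occ[tgt] != 0:
        return 0  # diffusive subunits obey the same blocking rule
    if _barrier_roll(lef, side, tgt, dirn, stall_l, stall_r,
                     stallp_l, stallp_r, bar_id_l, bar_id_r, passed) == 1:
        return 0
    if unload[tgt] != 0:
        return _do_unbind(lef, left, right, act_l, act_r, stall_l, stall_r,
                          bound, two_s, occ, occ_side, traversal)
    if traversal == 0:
        occ[pos] = 0
        occ[tgt] = lef + 1
        occ_side[tgt] = side
    if side == 0:
        left[lef] = tgt
    else:
        right[lef] = tgt
    return 1


@njit(cache=True, inline='always')
def _do_switch(lef, act_l, act_r, bound, two_s):
    """Exchange active and anchored roles; stall flags stay with positions."""
    if bound[lef] == 0 or two_s[lef] == 1:
        return 0
    tmp = act_l[lef]
    act_l[lef] = act_r[lef]
    act_r[lef] = tmp
    return 1


@njit(cache=True, inline='always')
def _record(si, left, right, act_l, act_r, stall_l, stall_r, bound,
            out_left, out_right, out_actl, out_actr, out_stl, out_str, out_bound):
    N = left.shape[0]
    for i in range(N):
        out_left[si, i] = left[i]
        out_right[si, i] = right[i]
        out_actl[si, i] = act_l[i]
        out_actr[si, i] = act_r[i]
        out_stl[si, i] = stall_l[i]
        out_str[si, i] = stall_r[i]
        out_bound[si, i] = bound[i]


# ---------------------------------------------------------------------------
# event-driven scheduler (next-reaction style with dormant blocked slots)
# ---------------------------------------------------------------------------

@njit(cache=True, inline='always')
def _geom_skip(loginv):
    """Bernoulli trials up to and including the first success (p < 1)."""
    return 1 + int(np.log(np.random.random()) * loginv)


@njit(cache=True, inline='always')
def _heap_push(keys, slots, n, key, slot):
    i = n
    keys[i] = key
    slots[i] = slot
    while i > 0:
        par = (i - 1) // 2
        if keys[par] <= keys[i]:
            break
        keys[par], keys[i] = keys[i], keys[par]
        slots[par], slots[i] = slots[i], slots[par]
        i = par
    return n + 1


@njit(cache=True, inline='always')
def _heap_pop(keys, slots, n):
    n -= 1
    keys[0] = keys[n]
    slots[0] = slots[n]
    i = 0
    while True:
        c1 = 2 * i + 1
        c2 = c1 + 1
        if c1 >= n:
            break
        c = c1
        if c2 < n and keys[c2] < keys[c1]:
            c = c2
        if keys[i] <= keys[c]:
            break
        keys[i], keys[c] = keys[c], keys[i]
        slots[i], slots[c] = slots[c], slots[i]
        i = c
    return n


@njit(cache=True, fastmath=True)
def run_events(
    left, right, act_l, act_r, stall_l, stall_r, bound, two_s,
    occ, occ_side,
    stallp_l, stallp_r, bar_id_l, bar_id_r, passed, unload,
    load_cdf, uniform_load, orient,
    v, v_diff, k_bind, k_unbind, k_switch, sidedness, traversal, pushing,
    exponential, dt, t0, t_end, sample_times,
    out_left, out_right, out_actl, out_actr, out_stl, out_str, out_bound,
):
    """Event-by-event run of the LEF dynamics; returns (t_end, n_events).

    Every (LEF, event-category) slot carries its own waiting-time stream:
    exponential in the event rate (``exponential=1``: the continuous-time
    Gillespie chain) or geometric in ``rate * dt`` (``exponential=0``: the
    fixed-time-step chain, with a random fractional tiebreak so same-step
    events execute in uniformly random order).  After an event, newly
    permissible events are (re)scheduled: step slots whose move is
    impossible (blocked, stalled, at a lattice edge, or unbound) go dormant
    and are woken when a neighbouring site is vacated, when the LEF binds,
    or when its subunit roles switch -- so the cost is proportional to the
    number of executed transitions, not to elapsed time.  Diffusive slots
    stay scheduled at their constant bound rates and are thinned against
    the current loop size inside the move attempt (exact).
    """
    N = left.shape[0]
    single_step = sidedness == 0.0
    rate = np.zeros(N_CATS, np.float64)
    rate[CAT_UNBIND] = k_unbind
    rate[CAT_STEP_L] = v
    rate[CAT_STEP_R] = 0.0 if single_step else v
    rate[CAT_SWITCH] = k_switch
    rate[CAT_DIFF_GROW] = v_diff
    rate[CAT_DIFF_SHRINK] = v_diff * SHRINK_BOUND
    rate[CAT_BIND] = k_bind
    # geometric-mode reciprocal logs (one log per draw)
    loginv = np.zeros(N_CATS, np.float64)
    certain = np.zeros(N_CATS, np.uint8)
    for cat in range(N_CATS):
        p = rate[cat] * dt
        if 0.0 < p < 1.0:
            loginv[cat] = 1.0 / np.log1p(-p)
        elif p >= 1.0:
            certain[cat] = 1
    can_sleep = traversal == 0 and pushing == 0
    cap = N * N_CATS + 1
    keys = np.empty(cap, np.float64)
    slots = np.empty(cap, np.int64)
    in_heap = np.zeros(N * N_CATS, np.uint8)
    hn = 0
    t = t0
    base_step = int(t0 / dt + 1e-9)
    for lef in range(N):
        for cat in range(N_CATS):
            if rate[cat] <= 0.0:
                continue
            if exponential == 1:
                key = t - np.log(np.random.random()) / rate[cat]
            elif certain[cat] == 1:
                key = (base_step + 1 + np.random.random()) * dt
            else:
                key = (base_step + _geom_skip(loginv[cat])
                       + np.random.random()) * dt
            slot = lef * N_CATS + cat
            in_heap[slot] = 1
            hn = _heap_push(keys, slots, hn, key, slot)
    si = 0
    ns = sample_times.shape[0]
    n_events = 0
    while hn > 0:
        key = keys[0]
        while si < ns and sample_times[si] <= key:
            _record(si, left, right, act_l, act_r, stall_l, stall_r, bound,
                    out_left, out_right, out_actl, out_actr, out_stl, out_str,
                    out_bound)
            si += 1
        if key >= t_end:
            break
        slot = slots[0]
        hn = _heap_pop(keys, slots, hn)
        in_heap[slot] = 0
        lef = slot // N_CATS
        cat = slot % N_CATS
        t = key
        now_step = int(key / dt + 1e-9)
        n_events += 1
        ol = left[lef]
        orr = right[lef]
        code = 0
        if cat == CAT_BIND:
            if bound[lef] == 0:
                code = _bind_attempt(
                    lef, left, right, act_l, act_r, stall_l, stall_r, bound,
                    two_s, occ, occ_side, passed, load_cdf, uniform_load,
                    orient, sidedness, traversal)
        elif bound[lef] == 1:
            if cat == CAT_UNBIND:
                code = _do_unbind(lef, left, right, act_l, act_r, stall_l,
                                  stall_r, bound, two_s, occ, occ_side,
                                  traversal)
            elif cat == CAT_STEP_L or cat == CAT_STEP_R:
                side = 1 if cat == CAT_STEP_R else 0
                if single_step and act_l[lef] == 0:
                    side = 1
                code = _try_step(lef, side, left, right, act_l, act_r,
                                 stall_l, stall_r, bound, two_s, occ,
                                 occ_side, stallp_l, stallp_r, bar_id_l,
                                 bar_id_r, passed, unload, traversal, pushing)
            elif cat == CAT_SWITCH:
                _do_switch(lef, act_l, act_r, bound, two_s)
                code = 4  # role change: wake this LEF's step slots
            elif cat == CAT_DIFF_GROW:
                code = _try_diff(lef, True, left, right, act_l, act_r,
                                 stall_l, stall_r, bound, two_s, occ,
                                 occ_side, stallp_l, stallp_r, bar_id_l,
                                 bar_id_r, passed, unload, traversal)
            else:
                code = _try_diff(lef, False, left, right, act_l, act_r,
                                 stall_l, stall_r, bound, two_s, occ,
                                 occ_side, stallp_l, stallp_r, bar_id_l,
                                 bar_id_r, passed, unload, traversal)
        # reschedule the popped slot.  Step slots sleep when their move is
        # impossible (code 0) or the LEF unbound (code 2); everything else
        # stays scheduled at its constant (bound) rate.
        is_step = cat == CAT_STEP_L or cat == CAT_STEP_R
        if rate[cat] > 0.0 and not (can_sleep and is_step
                                    and (code == 0 or code == 2)):
            if exponential == 1:
                nk = t - np.log(np.random.random()) / rate[cat]
            elif certain[cat] == 1:
                nk = (now_step + 1 + np.random.random()) * dt
            else:
                nk = (now_step + _geom_skip(loginv[cat])
                      + np.random.random()) * dt
            in_heap[slot] = 1
            hn = _heap_push(keys, slots, hn, nk, slot)
        if can_sleep:
            # wake-up bookkeeping
            if code == 1:
                # a subunit moved: its old site was vacated
                vac = ol if left[lef] != ol else orr
                for tgt in (vac - 1, vac + 1):
                    if 0 <= tgt < occ.shape[0] and occ[tgt] != 0:
                        hn = _wake_steps(occ[tgt] - 1, rate, loginv, certain,
                                         exponential, t, now_step, dt,
                                         in_heap, keys, slots, hn,
                                         single_step)
            elif code == 2:
                # unbound: both sites vacated
                for vac in (ol, orr):
                    for tgt in (vac - 1, vac + 1):
                        if (0 <= tgt < occ.shape[0] and occ[tgt] != 0
                                and occ[tgt] - 1 != lef):
                            hn = _wake_steps(occ[tgt] - 1, rate, loginv,
                                             certain, exponential, t,
                                             now_step, dt, in_heap, keys,
                                             slots, hn, single_step)
            elif code == 3 or code == 4:
                # fresh binding or role switch: this LEF's steps may fire
                hn = _wake_steps(lef, rate, loginv, certain, exponential, t,
                                 now_step, dt, in_heap, keys, slots, hn,
                                 single_step)
    while si < ns:
        _record(si, left, right, act_l, act_r, stall_l, stall_r, bound,
                out_left, out_right, out_actl, out_actr, out_stl, out_str,
                out_bound)
        si += 1
    return t_end, n_events


@njit(cache=True, inline='always')
def _wake_steps(lef, rate, loginv, certain, exponential, t, now_step, dt,
                in_heap, keys, slots, hn, single_step):
    for cat in (CAT_STEP_L, CAT_STEP_R):
        if rate[cat] <= 0.0:
            continue
        slot = lef * N_CATS + cat
        if in_heap[slot] == 1:
            continue
        if exponential == 1:
            nk = t - np.log(np.random.random()) / rate[cat]
        elif certain[cat] == 1:
            nk = (now_step + 1 + np.random.random()) * dt
        else:
            nk = (now_step + _geom_skip(loginv[cat]) + np.random.random()) * dt
        in_heap[slot] = 1
        hn = _heap_push(keys, slots, hn, nk, slot)
    return hn


# ---------------------------------------------------------------------------
# literal per-step sweep (small systems, deterministic extruders, 3D coupling)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_sweep(
    left, right, act_l, act_r, stall_l, stall_r, bound, two_s,
    occ, occ_side,
    stallp_l, stallp_r, bar_id_l, bar_id_r, passed, unload,
    load_cdf, uniform_load, orient,
    v, v_diff, k_bind, k_unbind, k_switch, sidedness, traversal, pushing,
    dt, n_steps, deterministic, sample_steps,
    out_left, out_right, out_actl, out_actr, out_stl, out_str, out_bound,
):
    """Literal fixed-step sweep: each candidate event fires w.p. k_i*dt.

    ``deterministic = 1`` makes active subunits step every dt with
    probability 1 (bacterial deterministic-extruder mode); all other events
    stay stochastic.  LEF order is a fresh random permutation each step and
    the two subunits of a LEF are attempted in random order.
    """
    N = left.shape[0]
    p_u = k_unbind * dt
    p_b = k_bind * dt
    p_s = k_switch * dt
    p_v = v * dt
    pmax_diff = v_diff * SHRINK_BOUND * dt
    nsub = 1
    if pmax_diff > 0.1:
        nsub = int(np.ceil(pmax_diff / 0.1))
    perm = np.arange(N)
    si = 0
    ns = sample_steps.shape[0]
    for step in range(1, n_steps + 1):
        for i in range(N - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            perm[i], perm[j] = perm[j], perm[i]
        for ii in range(N):
            lef = perm[ii]
            if bound[lef] == 0:
                if p_b >= 1.0 or np.random.random() < p_b:
                    _bind_attempt(
                        lef, left, right, act_l, act_r, stall_l, stall_r,
                        bound, two_s, occ, occ_side, passed, load_cdf,
                        uniform_load, orient, sidedness, traversal)
                continue
            if np.random.random() < p_u:
                _do_unbind(lef, left, right, act_l, act_r, stall_l, stall_r,
                           bound, two_s, occ, occ_side, traversal)
                continue
            if p_s > 0.0 and two_s[lef] == 0 and np.random.random() < p_s:
                _do_switch(lef, act_l, act_r, bound, two_s)
            first = 0 if np.random.random() < 0.5 else 1
            for k in range(2):
                side = first if k == 0 else 1 - first
                if bound[lef] == 0:
                    break
                if deterministic == 1 or np.random.random() < p_v:
                    _try_step(lef, side, left, right, act_l, act_r, stall_l,
                              stall_r, bound, two_s, occ, occ_side,
                              stallp_l, stallp_r, bar_id_l, bar_id_r,
                              passed, unload, traversal, pushing)
            if v_diff > 0.0 and bound[lef] == 1 and two_s[lef] == 0:
                pg = v_diff * dt / nsub
                psh = v_diff * SHRINK_BOUND * dt / nsub
                for s in range(nsub):
                    if bound[lef] == 0:
                        break
                    if np.random.random() < pg:
                        _try_diff(lef, True, left, right, act_l, act_r,
                                  stall_l, stall_r, bound, two_s, occ,
                                  occ_side, stallp_l, stallp_r, bar_id_l,
                                  bar_id_r, passed, unload, traversal)
                    if bound[lef] == 1 and np.random.random() < psh:
                        _try_diff(lef, False, left, right, act_l, act_r,
                                  stall_l, stall_r, bound, two_s, occ,
                                  occ_side, stallp_l, stallp_r, bar_id_l,
                                  bar_id_r, passed, unload, traversal)
        while si < ns and sample_steps[si] <= step:
            _record(si, left, right, act_l, act_r, stall_l, stall_r, bound,
                    out_left, out_right, out_actl, out_actr, out_stl, out_str,
                    out_bound)
            si += 1
    while si < ns:
        _record(si, left, right, act_l, act_r, stall_l, stall_r, bound,
                out_left, out_right, out_actl, out_actr, out_stl, out_str,
                out_bound)
        si += 1
    return n_steps


# ---------------------------------------------------------------------------
# Gaussian-chain contact maps: effective separations with loop bridging
# ---------------------------------------------------------------------------

@njit(cache=True, inline='always')
def _colldist(l, r, parent, nl, ctx, a, b):
    """Contour distance a->b in context ``ctx``, direct child loops collapsed."""
    d = float(b - a)
    for k in range(nl):
        if parent[k] == ctx and l[k] >= a and r[k] <= b:
            d -= r[k] - l[k]
    return d


@njit(cache=True)
def _s_eff_arrays(l, r, parent, span, nl, x, y):
    """Effective Gaussian contour separation between sites x < y.

    Loops wholly between x and y contribute zero (their anchors are bridged);
    a site inside a loop of collapsed length ell at collapsed arc t from an
    anchor contributes t*(1 - t/ell) (Brownian-bridge variance); unlooped
    linkers contribute their plain length; contributions add along the path.
    """
    if x == y:
        return 0.0
    if x > y:
        x, y = y, x
    # innermost loop strictly containing each endpoint
    inx = -1
    iny = -1
    for k in range(nl):
        if l[k] < x < r[k]:
            if inx == -1 or (l[k] >= l[inx] and r[k] <= r[inx]):
                inx = k
        if l[k] < y < r[k]:
            if iny == -1 or (l[k] >= l[iny] and r[k] <= r[iny]):
                iny = k
    s = 0.0
    # climb x out of loops that do not strictly contain y (strictness makes a
    # shared anchor site resolve to the loop's collapsed anchor point)
    px = x
    cx = inx
    while cx != -1 and not (l[cx] < y < r[cx]):
        ell = span[cx]
        if ell > 0.0:
            t = _colldist(l, r, parent, nl, cx, l[cx], px)
            s += t * (1.0 - t / ell)
        px = l[cx]
        cx = parent[cx]
    py = y
    cy = iny
    while cy != -1 and not (l[cy] < x < r[cy]):
        ell = span[cy]
        if ell > 0.0:
            t = _colldist(l, r, parent, nl, cy, l[cy], py)
            s += t * (1.0 - t / ell)
        py = l[cy]
        cy = parent[cy]
    # common context: cx == cy (deepest loop containing both, or the root)
    a = px if px <= py else py
    b = py if px <= py else px
    smid = _colldist(l, r, parent, nl, cx, a, b)
    if cx == -1:
        s += smid
    else:
        ell = span[cx]
        if ell > 0.0:
            s += smid * (1.0 - smid / ell)
    return s


@njit(cache=True)
def _build_forest_arrays(l, r, nl, parent, span):
    """Parent pointers and collapsed spans for loops sorted by left anchor.

    Returns 0 on success, -1 if intervals cross (pseudoknot)."""
    stack = np.empty(nl, np.int64)
    top = -1
    for k in range(nl):
        while top >= 0 and r[stack[top]] < l[k]:
            top -= 1
        if top >= 0:
            if r[k] > r[stack[top]]:
                return -1  # crossing intervals
            parent[k] = stack[top]
        else:
            parent[k] = -1
        top += 1
        stack[top] = k
    for k in range(nl):
        span[k] = float(r[k] - l[k])
    for k in range(nl):
        if parent[k] >= 0:
            span[parent[k]] -= r[k] - l[k]
    return 0


@njit(cache=True, fastmath=True)
def accumulate_gaussian_map(lefts, rights, offsets, bin_sites, s_floor, out):
    """Accumulate relative Gaussian-chain contact probabilities over snapshots.

    ``lefts``/``rights`` hold the bound-loop anchors of all snapshots
    back-to-back; ``offsets[s]:offsets[s+1]`` delimits snapshot ``s``.
    ``out`` (n_bins x n_bins) accumulates p = max(s_eff, s_floor)^{-3/2}
    evaluated between the representative sites of each bin pair.
    Returns the number of snapshots skipped due to crossing intervals.
    """
    nbins = bin_sites.shape[0]
    nsnap = offsets.shape[0] - 1
    max_l = 0
    for s in range(nsnap):
        nl = offsets[s + 1] - offsets[s]
        if nl > max_l:
            max_l = nl
    l = np.empty(max_l, np.int64)
    r = np.empty(max_l, np.int64)
    parent = np.empty(max_l, np.int64)
    span = np.empty(max_l, np.float64)
    order = np.empty(max_l, np.int64)
    skipped = 0
    for s in range(nsnap):
        a = offsets[s]
        nl = offsets[s + 1] - a
        for k in range(nl):
            l[k] = lefts[a + k]
            r[k] = rights[a + k]
        # insertion sort by left anchor (snapshots are small)
        for k in range(1, nl):
            lk = l[k]
            rk = r[k]
            j = k - 1
            while j >= 0 and l[j] > lk:
                l[j + 1] = l[j]
                r[j + 1] = r[j]
                j -= 1
            l[j + 1] = lk
            r[j + 1] = rk
        if _build_forest_arrays(l, r, nl, parent, span) != 0:
            skipped += 1
            continue
        for i in range(nbins):
            x = bin_sites[i]
            out[i, i] += 1.0
            for j in range(i + 1, nbins):
                se = _s_eff_arrays(l, r, parent, span, nl, x, bin_sites[j])
                if se < s_floor:
                    se = s_floor
                p = se ** -1.5
                out[i, j] += p
                out[j, i] += p
    return skipped


# ---------------------------------------------------------------------------
# coarse-grained 3D Langevin dynamics (BAOAB + intermittent velocity rescaling)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _pair_forces(pos, pairs, npairs, forces, eps_exc, sigma, r_m, eps_m):
    """Soft excluded-volume repulsion on listed pairs (zero beyond sigma)."""
    sig2 = sigma * sigma
    for idx in range(npairs):
        i = pairs[idx, 0]
        j = pairs[idx, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= sig2 or r2 <= 1e-12:
            continue
        z = (r2 / sig2) * r_m  # z = (r/sigma)^2 * r_m
        z5 = z * z * z * z * z
        # U = eps_exc * (1 + z^6 (z - 1) / eps_m); dU/d(r^2) = eps_exc/eps_m (7z^6-6z^5) r_m/sig2
        du_dr2 = (eps_exc / eps_m) * (7.0 * z - 6.0) * z5 * (r_m / sig2)
        f = -2.0 * du_dr2  # force = -dU/dr * rhat = -2 dU/dr2 * dr_vec
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz


@njit(cache=True, fastmath=True)
def _bond_forces(pos, bonds, forces, kspring, b0):
    for idx in range(bonds.shape[0]):
        i = bonds[idx, 0]
        j = bonds[idx, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        rr = np.sqrt(dx * dx + dy * dy + dz * dz)
        if rr <= 1e-12:
            continue
        f = -kspring * (rr - b0) / rr
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz


@njit(cache=True)
def _build_pairs(pos, cutoff, pairs):
    """Naive O(n^2) neighbour list (desk-scale chains); returns pair count."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    cnt = 0
    cap = pairs.shape[0]
    for i in range(n):
        for j in range(i + 2, n):  # backbone neighbours handled by bonds
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx * dx + dy * dy + dz * dz < c2:
                if cnt < cap:
                    pairs[cnt, 0] = i
                    pairs[cnt, 1] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def langevin_run(
    pos, vel, bonds,
    kspring, b0, eps_exc, sigma, r_m, eps_m,
    kT, mass, gamma, dt, n_steps,
    rebuild_every, skin, rescale_every,
):
    """BAOAB Langevin integration with intermittent velocity rescaling.

    ``bonds`` holds both backbone and live LEF bonds (harmonic, rest length
    b0).  The neighbour list for the excluded-volume term is rebuilt every
    ``rebuild_every`` steps with a safety ``skin``.  Returns 0 on success,
    -1 on numerical divergence.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3), np.float64)
    cap = 40 * n + 64
    pairs = np.empty((cap, 2), np.int64)
    npairs = _build_pairs(pos, sigma + skin, pairs)
    if npairs > cap:
        npairs = cap
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass)
    half = 0.5 * dt
    for step in range(n_steps):
        if step > 0 and step % rebuild_every == 0:
            npairs = _build_pairs(pos, sigma + skin, pairs)
            if npairs > cap:
                npairs = cap
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        _bond_forces(pos, bonds, forces, kspring, b0)
        _pair_forces(pos, pairs, npairs, forces, eps_exc, sigma, r_m, eps_m)
        for i in range(n):
            for c in range(3):
                vel[i, c] += half * forces[i, c] / mass
                pos[i, c] += half * vel[i, c]
        for i in range(n):
            for c in range(3):
                vel[i, c] = c1 * vel[i, c] + c2 * np.random.normal()
        for i in range(n):
            for c in range(3):
                pos[i, c] += half * vel[i, c]
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        _bond_forces(pos, bonds, forces, kspring, b0)
        _pair_forces(pos, pairs, npairs, forces, eps_exc, sigma, r_m, eps_m)
        for i in range(n):
            for c in range(3):
                vel[i, c] += half * forces[i, c] / mass
        if rescale_every > 0 and (step + 1) % rescale_every == 0:
            ke = 0.0
            for i in range(n):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            ke *= 0.5 * mass
            target = 1.5 * n * kT
            if ke > 0.0:
                sc = np.sqrt(target / ke)
                for i in range(n):
                    vel[i, 0] *= sc
                    vel[i, 1] *= sc
                    vel[i, 2] *= sc
    for i in range(n):
        for c in range(3):
            if not np.isfinite(pos[i, c]):
                return -1
    return 0
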