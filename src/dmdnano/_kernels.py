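"""Numba kernels for the event-driven dynamics engine.

State layout (flat numpy arrays, see ``engine.py`` for construction):

* positions are stored asynchronously: ``pos[i]`` is bead i's position at
  its local timestamp ``ptime[i]``; the position at global time t is
  ``pos[i] + vel[i] * (t - ptime[i])``.
* each bead keeps its two earliest known pair events (``ev_*`` best and
  ``e2_*`` runner-up), its next cell-boundary crossing (``cc_*``) and its
  next thermostat reassignment (``th_t``).  The global next event is an
  O(N) argmin over those slots.
* pair events store a snapshot of the partner's collision counter; a
  mismatch at pop time means the record is stale.  A stale best is repaired
  cheaply by re-deriving just that pair and merging with the runner-up;
  a full recomputation (scan of the cell neighborhood) happens only on
  velocity changes, cell crossings, or when both slots are stale.
  Correctness relies on (a) every velocity change triggering a full
  recomputation of the changed bead, so the earliest event of any pair
  always lives on its most recently updated member, and (b) all pair events
  discarded by the two-slot truncation being no earlier than the stored
  runner-up, which merging preserves.
* the box is periodic (minimum image); the scanned cell neighborhood covers
  the largest interaction distance, so any pair must enter each other's
  neighborhoods (triggering recomputation at the crossing) before it can
  interact.

Event type codes (``ev_ty``):
  k >= 0   boundary k of the class-pair step potential (0 = hard core)
  -2       hydrogen-bond reaction boundary
  -3 / -4  bond lower / upper wall
  -6 / -7  recovery pushes (push outward / pull inward); these fire only if
           a pair is found on the wrong side of a hard boundary and are
           never triggered in normal operation
"""

import math

import numpy as np
from numba import njit

# fastmath without 'ninf'/'nnan': empty calendar slots and completeness
# bounds are represented as +inf and must compare correctly
_FM = {'contract', 'arcp', 'reassoc', 'nsz'}

TOL2 = 1e-12   # |r^2 - d^2| below this counts as "at the boundary"
DTOL = 1e-5    # execution-time boundary mismatch tolerance (A)
HBMAX = 8

# iparams indices
(IP_NC, IP_M, IP_SEED, IP_MAXEV, IP_HBON, IP_K, IP_DEBUG,
 IP_W1, IP_W2) = range(9)
# fparams indices
(FP_L, FP_W, FP_KT, FP_NU, FP_TEND, FP_FDT, FP_HBR2, FP_HBEPS,
 FP_RESCDT) = range(9)


@njit(cache=True, fastmath=_FM, inline="always")
def _mi(dx, L):
    if dx > 0.5 * L:
        return dx - L
    elif dx < -0.5 * L:
        return dx + L
    return dx


@njit(cache=True, fastmath=_FM, inline="always")
def _cross_time(r2, b, v2, d2):
    """Time until |r + v t|^2 = d2, or -1.0 if unreachable / at boundary."""
    diff = r2 - d2
    if diff > TOL2:            # boundary inside: inward crossing
        if b >= 0.0:
            return -1.0
        disc = b * b - v2 * diff
        if disc <= 0.0:
            return -1.0
        return (-b - math.sqrt(disc)) / v2
    elif diff < -TOL2:         # boundary outside: outward crossing
        disc = b * b - v2 * diff
        return (-b + math.sqrt(disc)) / v2
    else:                      # at the boundary: outward return after
        if b < 0.0:            # the inward excursion turns around
            return -2.0 * b / v2
        return -1.0


@njit(cache=True, fastmath=_FM, inline="always")
def _earliest(r2, b, v2, d2arr, n):
    """Earliest crossing among sorted squared boundaries; (dt, index).

    Only the nearest inner and nearest outer boundary can host the first
    crossing of a free-flight pair.  A pair sitting exactly at the hard
    core and moving inward reflects immediately; at any other boundary it
    re-crosses that boundary outward at -2 b / v2 if the nearest inner
    boundary is unreachable.
    """
    k_in = -1
    k_at = -1
    k_out = -1
    for k in range(n):
        diff = r2 - d2arr[k]
        if diff > TOL2:
            k_in = k
        elif diff < -TOL2:
            k_out = k
            break
        else:
            k_at = k
    if b < 0.0:
        if k_in >= 0:
            diff = r2 - d2arr[k_in]
            disc = b * b - v2 * diff
            if disc > 0.0:
                return (-b - math.sqrt(disc)) / v2, k_in
        if k_at == 0:
            return 0.0, 0          # at the hard core moving inward: reflect
        if k_at > 0:
            return -2.0 * b / v2, k_at
    if k_out >= 0:
        disc = b * b - v2 * (r2 - d2arr[k_out])
        return (-b + math.sqrt(disc)) / v2, k_out
    return np.inf, -1


@njit(cache=True, fastmath=_FM, inline="always")
def _bond_slot(i, j, bptr, bjarr):
    for e in range(bptr[i], bptr[i + 1]):
        if bjarr[e] == j:
            return e
    return -1


@njit(cache=True, fastmath=_FM, inline="always")
def _hb_reacted(i, j, hbp, hbn):
    for s in range(hbn[i]):
        if hbp[i, s] == j:
            return True
    return False


@njit(cache=True, fastmath=_FM, inline="always")
def _pair_event(i, j, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2, bhi2,
                nb, br2, hbr2, don, acc, don_used, acc_used, hbp, hbn,
                iparams, fparams):
    """Earliest boundary crossing of pair (i, j): (dt, d2, type)."""
    L = fparams[FP_L]
    dti = tnow - ptime[i]
    dtj = tnow - ptime[j]
    dx = _mi(pos[i, 0] + vel[i, 0] * dti - pos[j, 0] - vel[j, 0] * dtj, L)
    dy = _mi(pos[i, 1] + vel[i, 1] * dti - pos[j, 1] - vel[j, 1] * dtj, L)
    dz = _mi(pos[i, 2] + vel[i, 2] * dti - pos[j, 2] - vel[j, 2] * dtj, L)
    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    b = dx * dvx + dy * dvy + dz * dvz
    v2 = dvx * dvx + dvy * dvy + dvz * dvz
    e = _bond_slot(i, j, bptr, bjarr)
    if e >= 0:
        lo2 = blo2[e]
        hi2 = bhi2[e]
        if r2 >= hi2 + TOL2 and b >= 0.0:      # escaped bond: pull back now
            return 0.0, hi2, -7
        if r2 <= lo2 - TOL2 and b <= 0.0:      # inside lower wall: push out
            return 0.0, lo2, -6
        if v2 <= 0.0:
            return np.inf, 0.0, -99
        best = np.inf
        bd2 = 0.0
        bty = -99
        diff = r2 - lo2
        if diff > TOL2:
            if b < 0.0:
                disc = b * b - v2 * diff
                if disc > 0.0:
                    t = (-b - math.sqrt(disc)) / v2
                    if t < best:
                        best = t; bd2 = lo2; bty = -3
        elif diff < -TOL2:                      # inside lo: outward recovery
            t = (-b + math.sqrt(b * b - v2 * diff)) / v2
            if t < best:
                best = t; bd2 = lo2; bty = -3
        elif b < 0.0:                           # at lo moving in: reflect now
            return 0.0, lo2, -3
        diff = r2 - hi2
        if diff < -TOL2:
            t = (-b + math.sqrt(b * b - v2 * diff)) / v2
            if t < best:
                best = t; bd2 = hi2; bty = -4
        elif diff <= TOL2:
            if b > 0.0:                         # at hi moving out: reflect now
                return 0.0, hi2, -4
            elif b < 0.0:                       # future return to hi
                t = -2.0 * b / v2
                if t < best:
                    best = t; bd2 = hi2; bty = -4
        else:                                   # outside hi approaching
            if b < 0.0:
                disc = b * b - v2 * diff
                if disc > 0.0:
                    t = (-b - math.sqrt(disc)) / v2
                    if t < best:
                        best = t; bd2 = hi2; bty = -4
        return best, bd2, bty
    if v2 <= 0.0:
        return np.inf, 0.0, -99
    p = cls[i] * iparams[IP_NC] + cls[j]
    if r2 < br2[p, 0] - TOL2 and b <= 0.0:     # hardcore overlap: push out
        return 0.0, br2[p, 0], -6
    best, kbest = _earliest(r2, b, v2, br2[p], nb[p])
    bd2 = br2[p, kbest] if kbest >= 0 else 0.0
    bty = kbest if kbest >= 0 else -99
    if iparams[IP_HBON] != 0:
        # schedule the reaction boundary only when crossing it can act:
        # pair already bonded, or capacity available for either role
        reacted = _hb_reacted(i, j, hbp, hbn)
        hb_live = reacted
        if not hb_live:
            hb_live = ((don[i] - don_used[i] > 0 and
                        acc[j] - acc_used[j] > 0) or
                       (don[j] - don_used[j] > 0 and
                        acc[i] - acc_used[i] > 0))
        if hb_live:
            d2hb = hbr2[p]
            diff = r2 - d2hb
            t = -1.0
            if diff > TOL2:
                if b < 0.0:
                    disc = b * b - v2 * diff
                    if disc > 0.0:
                        t = (-b - math.sqrt(disc)) / v2
            elif diff < -TOL2:
                t = (-b + math.sqrt(b * b - v2 * diff)) / v2
            else:                               # at the reaction boundary
                if b > 0.0 and reacted:
                    t = 0.0                     # break attempt now
                elif b < 0.0 and not reacted:
                    t = 0.0                     # react now, moving inward
                elif b < 0.0 and reacted:
                    t = -2.0 * b / v2           # future outward return
            if 0.0 <= t < best:
                best = t; bd2 = d2hb; bty = -2
    if bty == -99:
        return np.inf, 0.0, -99
    return best, bd2, bty


@njit(cache=True, fastmath=_FM)
def _recompute(i, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2, bhi2,
               nb, br2, hbr2, don, acc, don_used, acc_used, hbp, hbn,
               iparams, fparams,
               chead, cnext, ccell, cnt,
               ev_t, ev_j, ev_d2, ev_ty, ev_snap,
               e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t):
    """Full calendar rebuild for bead i: best + runner-up pair events."""
    M = iparams[IP_M]
    K = iparams[IP_K]
    L = fparams[FP_L]
    rmaxd = fparams[FP_W] * K          # cells cover the interaction range
    rmax2 = rmaxd * rmaxd
    b1t = np.inf; b1j = -1; b1d = 0.0; b1y = -99
    b2t = np.inf; b2j = -1; b2d = 0.0; b2y = -99
    for e in range(bptr[i], bptr[i + 1]):
        j = bjarr[e]
        dt, d2, ty = _pair_event(i, j, tnow, pos, vel, ptime, cls, bptr,
                                 bjarr, blo2, bhi2, nb, br2, hbr2, don, acc,
                                 don_used, acc_used, hbp, hbn,
                                 iparams, fparams)
        if dt < b1t:
            b2t = b1t; b2j = b1j; b2d = b1d; b2y = b1y
            b1t = dt; b1j = j; b1d = d2; b1y = ty
        elif dt < b2t:
            b2t = dt; b2j = j; b2d = d2; b2y = ty
    dti0 = tnow - ptime[i]
    xi = pos[i, 0] + vel[i, 0] * dti0
    yi = pos[i, 1] + vel[i, 1] * dti0
    zi = pos[i, 2] + vel[i, 2] * dti0
    vxi = vel[i, 0]
    vyi = vel[i, 1]
    vzi = vel[i, 2]
    cx = ccell[i, 0]
    cy = ccell[i, 1]
    cz = ccell[i, 2]
    for ox in range(-K, K + 1):
        ax = (cx + ox) % M
        for oy in range(-K, K + 1):
            ay = (cy + oy) % M
            for oz in range(-K, K + 1):
                az = (cz + oz) % M
                j = chead[(ax * M + ay) * M + az]
                while j >= 0:
                    if j != i and _bond_slot(i, j, bptr, bjarr) < 0:
                        # rigorous prefilter: |d r/d t| <= |v_rel|, so a
                        # pair beyond the interaction range cannot collide
                        # before (r - rmax) / |v_rel|
                        dtj0 = tnow - ptime[j]
                        ddx = _mi(xi - pos[j, 0] - vel[j, 0] * dtj0, L)
                        ddy = _mi(yi - pos[j, 1] - vel[j, 1] * dtj0, L)
                        ddz = _mi(zi - pos[j, 2] - vel[j, 2] * dtj0, L)
                        rr2 = ddx * ddx + ddy * ddy + ddz * ddz
                        skip = False
                        if rr2 > rmax2:
                            dvx0 = vxi - vel[j, 0]
                            dvy0 = vyi - vel[j, 1]
                            dvz0 = vzi - vel[j, 2]
                            vv2 = (dvx0 * dvx0 + dvy0 * dvy0 +
                                   dvz0 * dvz0)
                            if vv2 <= 0.0:
                                skip = True
                            else:
                                tlow = ((math.sqrt(rr2) - rmaxd) /
                                        math.sqrt(vv2))
                                if tlow >= b2t:
                                    skip = True
                        if not skip:
                            dt, d2, ty = _pair_event(
                                i, j, tnow, pos, vel, ptime, cls, bptr,
                                bjarr, blo2, bhi2, nb, br2, hbr2, don,
                                acc, don_used, acc_used, hbp, hbn,
                                iparams, fparams)
                            if dt < b1t:
                                b2t = b1t; b2j = b1j; b2d = b1d; b2y = b1y
                                b1t = dt; b1j = j; b1d = d2; b1y = ty
                            elif dt < b2t:
                                b2t = dt; b2j = j; b2d = d2; b2y = ty
                    j = cnext[j]
    ev_t[i] = tnow + b1t
    ev_j[i] = b1j
    ev_d2[i] = b1d
    ev_ty[i] = b1y
    ev_snap[i] = cnt[b1j] if b1j >= 0 else 0
    e2_t[i] = tnow + b2t
    e2_j[i] = b2j
    e2_d2[i] = b2d
    e2_ty[i] = b2y
    e2_snap[i] = cnt[b2j] if b2j >= 0 else 0
    # events discarded by the two-slot truncation (and prefilter skips) are
    # all later than the runner-up found here; merges must stay below this
    bound_t[i] = tnow + b2t


@njit(cache=True, fastmath=_FM)
def _slot_merge(i, j, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2, bhi2,
                nb, br2, hbr2, don, acc, don_used, acc_used, hbp, hbn,
                iparams, fparams, cnt,
                ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t):
    """Replace bead i's best slot by a fresh (i, j) event merged with the
    stored runner-up.  Returns False (a full rebuild is required) when the
    runner-up is stale too, or when the merged best would exceed the
    completeness bound set at the last full rebuild."""
    j2 = e2_j[i]
    if j2 >= 0 and e2_snap[i] != cnt[j2]:
        return False
    dt, d2, ty = _pair_event(i, j, tnow, pos, vel, ptime, cls, bptr, bjarr,
                             blo2, bhi2, nb, br2, hbr2, don, acc, don_used,
                             acc_used, hbp, hbn, iparams, fparams)
    t_new = tnow + dt
    if min(t_new, e2_t[i]) > bound_t[i]:
        return False
    if t_new <= e2_t[i]:
        ev_t[i] = t_new
        ev_j[i] = j
        ev_d2[i] = d2
        ev_ty[i] = ty
        ev_snap[i] = cnt[j]
    else:
        ev_t[i] = e2_t[i]
        ev_j[i] = j2
        ev_d2[i] = e2_d2[i]
        ev_ty[i] = e2_ty[i]
        ev_snap[i] = e2_snap[i]
        e2_t[i] = t_new
        e2_j[i] = j
        e2_d2[i] = d2
        e2_ty[i] = ty
        e2_snap[i] = cnt[j]
    return True


@njit(cache=True, fastmath=_FM)
def _cc_recompute(i, tnow, pos, vel, ptime, ccell, cc_t, cc_dim, cc_dir,
                  fparams):
    w = fparams[FP_W]
    tbest = np.inf
    dbest = 0
    rbest = 1
    dt0 = tnow - ptime[i]
    for d in range(3):
        v = vel[i, d]
        x = pos[i, d] + v * dt0
        if v > 0.0:
            t = ((ccell[i, d] + 1) * w - x) / v
            r = 1
        elif v < 0.0:
            t = (ccell[i, d] * w - x) / v
            r = -1
        else:
            continue
        if t < 0.0:
            t = 0.0
        if t < tbest:
            tbest = t; dbest = d; rbest = r
    cc_t[i] = tnow + tbest
    cc_dim[i] = dbest
    cc_dir[i] = rbest


@njit(cache=True, fastmath=_FM)
def _cell_remove(i, ccell, chead, cnext, cprev, M):
    c = (ccell[i, 0] * M + ccell[i, 1]) * M + ccell[i, 2]
    p = cprev[i]
    n = cnext[i]
    if p >= 0:
        cnext[p] = n
    else:
        chead[c] = n
    if n >= 0:
        cprev[n] = p


@njit(cache=True, fastmath=_FM)
def _cell_insert(i, ccell, chead, cnext, cprev, M):
    c = (ccell[i, 0] * M + ccell[i, 1]) * M + ccell[i, 2]
    h = chead[c]
    chead[c] = i
    cprev[i] = -1
    cnext[i] = h
    if h >= 0:
        cprev[h] = i


@njit(cache=True, fastmath=_FM)
def _shell_level(p, r2, nb, br2, lvl):
    """Energy level of a nonbonded pair at squared distance r2."""
    m = nb[p]
    if r2 >= br2[p, m - 1]:
        return 0.0
    for k in range(1, m):
        if r2 < br2[p, k]:
            return lvl[p, k - 1]
    return 0.0


@njit(cache=True, fastmath=_FM)
def total_potential(pos, ptime, vel, tnow, cls, scl, bptr, bjarr,
                    nb, br2, lvl, hbp, hbn, iparams, fparams):
    """Reference O(N^2) potential energy (shells + reacted H-bonds)."""
    N = pos.shape[0]
    NC = iparams[IP_NC]
    L = fparams[FP_L]
    pe = 0.0
    for i in range(N):
        dti = tnow - ptime[i]
        xi = pos[i, 0] + vel[i, 0] * dti
        yi = pos[i, 1] + vel[i, 1] * dti
        zi = pos[i, 2] + vel[i, 2] * dti
        for j in range(i + 1, N):
            if _bond_slot(i, j, bptr, bjarr) >= 0:
                continue
            dtj = tnow - ptime[j]
            dx = _mi(xi - pos[j, 0] - vel[j, 0] * dtj, L)
            dy = _mi(yi - pos[j, 1] - vel[j, 1] * dtj, L)
            dz = _mi(zi - pos[j, 2] - vel[j, 2] * dtj, L)
            r2 = dx * dx + dy * dy + dz * dz
            p = cls[i] * NC + cls[j]
            pe += _shell_level(p, r2, nb, br2, lvl) * scl[i] * scl[j]
        for s in range(hbn[i]):
            if hbp[i, s] > i:
                pe -= fparams[FP_HBEPS]
    return pe


@njit(cache=True, fastmath=_FM)
def _hb_add(i, j, i_is_donor, hbp, hbrole, hbn, don_used, acc_used):
    hbp[i, hbn[i]] = j
    hbrole[i, hbn[i]] = 1 if i_is_donor else 0
    hbn[i] += 1
    hbp[j, hbn[j]] = i
    hbrole[j, hbn[j]] = 0 if i_is_donor else 1
    hbn[j] += 1
    if i_is_donor:
        don_used[i] += 1
        acc_used[j] += 1
    else:
        acc_used[i] += 1
        don_used[j] += 1


@njit(cache=True, fastmath=_FM)
def _hb_remove(i, j, hbp, hbrole, hbn, don_used, acc_used):
    for s in range(hbn[i]):
        if hbp[i, s] == j:
            if hbrole[i, s] == 1:
                don_used[i] -= 1
                acc_used[j] -= 1
            else:
                acc_used[i] -= 1
                don_used[j] -= 1
            hbp[i, s] = hbp[i, hbn[i] - 1]
            hbrole[i, s] = hbrole[i, hbn[i] - 1]
            hbn[i] -= 1
            break
    for s in range(hbn[j]):
        if hbp[j, s] == i:
            hbp[j, s] = hbp[j, hbn[j] - 1]
            hbrole[j, s] = hbrole[j, hbn[j] - 1]
            hbn[j] -= 1
            break


@njit(cache=True, fastmath=_FM)
def run_kernel(pos, vel, ptime, mass, cls, scl, is_pep,
               bptr, bjarr, blo2, bhi2, nb, br2, lvl, hbr2,
               don, acc, hbp, hbrole, hbn, don_used, acc_used,
               chead, cnext, cprev, ccell,
               ev_t, ev_j, ev_d2, ev_ty, ev_snap,
               e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t,
               cc_t, cc_dim, cc_dir, th_t, cnt,
               iparams, fparams,
               fpos, fvel, ft, fke, fpe, fhb, diag):
    """Run the event loop until t_end or the physical-event budget.

    Returns (status, n_events, n_frames, pe, t_final, pe_check); status
    0 = reached t_end, 1 = event budget exhausted, 2 = event-time
    regression (internal inconsistency).
    """
    N = pos.shape[0]
    M = iparams[IP_M]
    L = fparams[FP_L]
    kT = fparams[FP_KT]
    nu = fparams[FP_NU]
    t_end = fparams[FP_TEND]
    frame_dt = fparams[FP_FDT]
    hb_eps = fparams[FP_HBEPS]
    max_events = iparams[IP_MAXEV]
    np.random.seed(iparams[IP_SEED])

    for c in range(M * M * M):
        chead[c] = -1
    w = fparams[FP_W]
    for i in range(N):
        for d in range(3):
            cix = int(pos[i, d] / w)
            if cix >= M:
                cix = M - 1
            if cix < 0:
                cix = 0
            ccell[i, d] = cix
        _cell_insert(i, ccell, chead, cnext, cprev, M)

    pe = total_potential(pos, ptime, vel, 0.0, cls, scl, bptr, bjarr,
                         nb, br2, lvl, hbp, hbn, iparams, fparams)
    for i in range(N):
        _recompute(i, 0.0, pos, vel, ptime, cls, bptr, bjarr, blo2, bhi2,
                   nb, br2, hbr2, don, acc, don_used, acc_used, hbp, hbn,
                   iparams, fparams, chead, cnext, ccell, cnt,
                   ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                   e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
        _cc_recompute(i, 0.0, pos, vel, ptime, ccell, cc_t, cc_dim, cc_dir,
                      fparams)
        th_t[i] = np.random.exponential(1.0 / nu) if nu > 0.0 else np.inf

    tnow = 0.0
    n_events = 0
    nframes = 0
    next_frame = 0.0
    Fmax = ft.shape[0]
    status = 0
    resc_dt = fparams[FP_RESCDT]
    next_resc = resc_dt if resc_dt > 0.0 else np.inf

    while True:
        diag[0] += 1
        tmin = t_end
        which = -1
        ib = -1
        for i in range(N):
            if ev_t[i] < tmin:
                tmin = ev_t[i]; which = 0; ib = i
            if cc_t[i] < tmin:
                tmin = cc_t[i]; which = 1; ib = i
            if th_t[i] < tmin:
                tmin = th_t[i]; which = 2; ib = i
        if next_resc < tmin:
            tmin = next_resc; which = 3; ib = -1

        while next_frame <= tmin + 1e-12 and nframes < Fmax:
            ke = 0.0
            for i in range(N):
                dt0 = next_frame - ptime[i]
                for d in range(3):
                    x = pos[i, d] + vel[i, d] * dt0
                    x -= L * math.floor(x / L)
                    fpos[nframes, i, d] = x
                    fvel[nframes, i, d] = vel[i, d]
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 +
                                       vel[i, 2] ** 2)
            ft[nframes] = next_frame
            fke[nframes] = ke
            fpe[nframes] = pe
            npl = 0; npp = 0; nll = 0
            for i in range(N):
                for s in range(hbn[i]):
                    j = hbp[i, s]
                    if j > i:
                        if is_pep[i] == 1 and is_pep[j] == 1:
                            npp += 1
                        elif is_pep[i] == 0 and is_pep[j] == 0:
                            nll += 1
                        else:
                            npl += 1
            fhb[nframes, 0] = npl
            fhb[nframes, 1] = npp
            fhb[nframes, 2] = nll
            nframes += 1
            next_frame += frame_dt

        if which == -1:
            tnow = t_end               # reached t_end mid-flight
            break
        if tmin < tnow - 1e-9:
            status = 2
            break
        tnow = tmin

        if which == 3:                 # global kinetic-energy rescale
            ke = 0.0
            for i in range(N):
                dt0 = tnow - ptime[i]
                for d in range(3):
                    pos[i, d] += vel[i, d] * dt0
                ptime[i] = tnow
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 +
                                       vel[i, 2] ** 2)
            lam = math.sqrt(1.5 * N * kT / ke) if ke > 0.0 else 1.0
            for i in range(N):
                for d in range(3):
                    vel[i, d] *= lam
                cnt[i] += 1
            for i in range(N):
                _cc_recompute(i, tnow, pos, vel, ptime, ccell, cc_t, cc_dim,
                              cc_dir, fparams)
                _recompute(i, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2,
                           bhi2, nb, br2, hbr2, don, acc, don_used, acc_used,
                           hbp, hbn, iparams, fparams,
                           chead, cnext, ccell, cnt,
                           ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                           e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
            next_resc += resc_dt
            continue

        if which == 2:                 # thermostat reassignment
            diag[4] += 1
            dt0 = tnow - ptime[ib]
            for d in range(3):
                pos[ib, d] += vel[ib, d] * dt0
            ptime[ib] = tnow
            s = math.sqrt(kT / mass[ib])
            for d in range(3):
                vel[ib, d] = np.random.normal() * s
            cnt[ib] += 1
            th_t[ib] = tnow + np.random.exponential(1.0 / nu)
            _cc_recompute(ib, tnow, pos, vel, ptime, ccell, cc_t, cc_dim,
                          cc_dir, fparams)
            _recompute(ib, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2,
                       bhi2, nb, br2, hbr2, don, acc, don_used, acc_used,
                       hbp, hbn, iparams, fparams,
                       chead, cnext, ccell, cnt,
                       ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                       e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
            continue

        if which == 1:                 # cell crossing
            diag[3] += 1
            dt0 = tnow - ptime[ib]
            for d in range(3):
                pos[ib, d] += vel[ib, d] * dt0
            ptime[ib] = tnow
            _cell_remove(ib, ccell, chead, cnext, cprev, M)
            dd = cc_dim[ib]
            ccell[ib, dd] += cc_dir[ib]
            if ccell[ib, dd] >= M:
                ccell[ib, dd] = 0
                pos[ib, dd] -= L
            elif ccell[ib, dd] < 0:
                ccell[ib, dd] = M - 1
                pos[ib, dd] += L
            _cell_insert(ib, ccell, chead, cnext, cprev, M)
            _cc_recompute(ib, tnow, pos, vel, ptime, ccell, cc_t, cc_dim,
                          cc_dir, fparams)
            _recompute(ib, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2,
                       bhi2, nb, br2, hbr2, don, acc, don_used, acc_used,
                       hbp, hbn, iparams, fparams,
                       chead, cnext, ccell, cnt,
                       ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                       e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
            continue

        # --- pair event
        i = ib
        j = ev_j[i]
        if j < 0 or ev_snap[i] != cnt[j]:
            diag[1] += 1               # stale: cheap two-slot repair
            if j < 0 or not _slot_merge(
                    i, j, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2,
                    bhi2, nb, br2, hbr2, don, acc, don_used, acc_used, hbp,
                    hbn, iparams, fparams, cnt,
                    ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                    e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t):
                _recompute(i, tnow, pos, vel, ptime, cls, bptr, bjarr,
                           blo2, bhi2, nb, br2, hbr2, don, acc, don_used,
                           acc_used, hbp, hbn, iparams, fparams,
                           chead, cnext, ccell, cnt,
                           ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                           e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
            continue
        ty = ev_ty[i]
        d2 = ev_d2[i]
        if iparams[IP_W1] >= 0 and (
                (i == iparams[IP_W1] or i == iparams[IP_W2]) and
                (j == iparams[IP_W1] or j == iparams[IP_W2])):
            print('WATCH t=', tnow, 'i=', i, 'j=', j, 'ty=', ty, 'd2=', d2)
        for bead in (i, j):
            dt0 = tnow - ptime[bead]
            for d in range(3):
                pos[bead, d] += vel[bead, d] * dt0
            ptime[bead] = tnow
        dx = _mi(pos[i, 0] - pos[j, 0], L)
        dy = _mi(pos[i, 1] - pos[j, 1], L)
        dz = _mi(pos[i, 2] - pos[j, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dcol = math.sqrt(d2)
        if ty > -6 and abs(r - dcol) > DTOL:
            # spurious record (e.g. stale image); drop and recompute
            diag[2] += 1
            _recompute(i, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2,
                       bhi2, nb, br2, hbr2, don, acc, don_used, acc_used,
                       hbp, hbn, iparams, fparams,
                       chead, cnext, ccell, cnt,
                       ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                       e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
            continue
        if r <= 0.0:
            r = 1e-12
        nx = dx / r
        ny = dy / r
        nz = dz / r
        vr = ((vel[i, 0] - vel[j, 0]) * nx + (vel[i, 1] - vel[j, 1]) * ny +
              (vel[i, 2] - vel[j, 2]) * nz)
        mu = mass[i] * mass[j] / (mass[i] + mass[j])
        vrp = vr
        changed = False
        if ty == -6:                   # push outward
            if vr < 0.0:
                vrp = -vr; changed = True
        elif ty == -7:                 # pull inward
            if vr > 0.0:
                vrp = -vr; changed = True
        elif ty == -3 or ty == -4 or ty == 0:
            wall_out = (ty == -4)      # reflect when moving past the wall
            if (wall_out and vr > 0.0) or (not wall_out and vr < 0.0):
                vrp = -vr; changed = True
        elif ty == -2:                 # hydrogen-bond reaction boundary
            reacted = _hb_reacted(i, j, hbp, hbn)
            if vr < 0.0 and not reacted:
                i_don = (don[i] - don_used[i] > 0 and
                         acc[j] - acc_used[j] > 0)
                j_don = (don[j] - don_used[j] > 0 and
                         acc[i] - acc_used[i] > 0)
                if (i_don or j_don) and hbn[i] < HBMAX and hbn[j] < HBMAX:
                    _hb_add(i, j, i_don, hbp, hbrole, hbn, don_used,
                            acc_used)
                    vrp = -math.sqrt(vr * vr + 2.0 * hb_eps / mu)
                    pe -= hb_eps
                    changed = True
            elif vr > 0.0 and reacted:
                if 0.5 * mu * vr * vr > hb_eps:
                    _hb_remove(i, j, hbp, hbrole, hbn, don_used, acc_used)
                    vrp = math.sqrt(vr * vr - 2.0 * hb_eps / mu)
                    pe += hb_eps
                else:
                    vrp = -vr          # bond holds: reflect
                changed = True
        elif ty >= 1:
            p = cls[i] * iparams[IP_NC] + cls[j]
            s = scl[i] * scl[j]
            below = lvl[p, ty - 1] * s
            above = lvl[p, ty] * s if ty < nb[p] - 1 else 0.0
            dU = (above - below) if vr > 0.0 else (below - above)
            if dU <= 0.0 or vr * vr > 2.0 * dU / mu:
                arg = vr * vr - 2.0 * dU / mu
                if arg < 0.0:
                    arg = 0.0
                vrp = math.sqrt(arg) if vr > 0.0 else -math.sqrt(arg)
                pe += dU
            else:
                vrp = -vr              # forbidden crossing: reflect
            changed = True
        if ty > -6:
            # nudge the pair onto the exact boundary radius; the at-boundary
            # prediction branches then resolve the state by direction
            half = 0.5 * (dcol - r)
            pos[i, 0] += nx * half
            pos[i, 1] += ny * half
            pos[i, 2] += nz * half
            pos[j, 0] -= nx * half
            pos[j, 1] -= ny * half
            pos[j, 2] -= nz * half
        if changed and vrp != vr:
            dv = mu * (vrp - vr)
            vel[i, 0] += dv * nx / mass[i]
            vel[i, 1] += dv * ny / mass[i]
            vel[i, 2] += dv * nz / mass[i]
            vel[j, 0] -= dv * nx / mass[j]
            vel[j, 1] -= dv * ny / mass[j]
            vel[j, 2] -= dv * nz / mass[j]
            cnt[i] += 1
            cnt[j] += 1
            _cc_recompute(i, tnow, pos, vel, ptime, ccell, cc_t, cc_dim,
                          cc_dir, fparams)
            _cc_recompute(j, tnow, pos, vel, ptime, ccell, cc_t, cc_dim,
                          cc_dir, fparams)
            for bead in (i, j):
                _recompute(bead, tnow, pos, vel, ptime, cls, bptr, bjarr,
                           blo2, bhi2, nb, br2, hbr2, don, acc, don_used,
                           acc_used, hbp, hbn, iparams, fparams,
                           chead, cnext, ccell, cnt,
                           ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                           e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
        else:
            # no velocity change: only the pair's own next boundary must be
            # re-derived; other beads' records involving i and j stay valid
            if not _slot_merge(
                    i, j, tnow, pos, vel, ptime, cls, bptr, bjarr, blo2,
                    bhi2, nb, br2, hbr2, don, acc, don_used, acc_used, hbp,
                    hbn, iparams, fparams, cnt,
                    ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                    e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t):
                _recompute(i, tnow, pos, vel, ptime, cls, bptr, bjarr,
                           blo2, bhi2, nb, br2, hbr2, don, acc, don_used,
                           acc_used, hbp, hbn, iparams, fparams,
                           chead, cnext, ccell, cnt,
                           ev_t, ev_j, ev_d2, ev_ty, ev_snap,
                           e2_t, e2_j, e2_d2, e2_ty, e2_snap, bound_t)
        n_events += 1
        if ty == -3 or ty == -4:
            diag[5] += 1               # bond-wall events
        elif ty == -2:
            diag[7] += 1               # hydrogen-bond boundary events
        else:
            diag[6] += 1               # step-potential events
        if iparams[IP_DEBUG] != 0 and diag[11] == 0:
            pe_dbg = total_potential(pos, ptime, vel, tnow + 1e-7, cls, scl,
                                     bptr, bjarr, nb, br2, lvl, hbp, hbn,
                                     iparams, fparams)
            if abs(pe_dbg - pe) > 1e-6:
                diag[8] = ty
                diag[9] = i
                diag[10] = j
                diag[11] = n_events
        if n_events >= max_events:
            status = 1
            break

    pe_check = total_potential(pos, ptime, vel, tnow, cls, scl, bptr, bjarr,
                               nb, br2, lvl, hbp, hbn, iparams, fparams)
    return status, n_events, nframes, pe, tnow, pe_check
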