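"""Compiled agent-phase kernel for the tick loop.

The per-agent rules here mirror :mod:`inflamsim.agents` exactly; this module
exists because the chronic-outcome experiments run thousands of ticks over
thousands of agents, which a per-agent Python loop cannot sustain.  Agents
live in flat arrays (struct-of-arrays), compacted by the caller after every
tick so that alive entries occupy a prefix.  All randomness uses numba's
internal NumPy-compatible stream, seeded once per run via :func:`seed_rng`,
which makes whole runs bit-reproducible.

Per-tick inputs precomputed by the caller (cheap vectorised NumPy):

- ``wgrad``: per-site gradient weights ``exp(k_grad * (c_nbr - c))``,
  max-shifted per site so large ``k_grad`` cannot overflow;
- ``has_c``: whether any mediator is present in each site's 3x3 block;
- ``dep_elig``: whether the 3x3 summed ``c`` is below the departure
  threshold;
- ``mac_elig`` / ``neu_elig``: recruitment eligibility masks;
- CSR buckets mapping each site to the apoptotic agents occupying it at the
  start of the tick (agents created mid-tick are found by scanning the
  appended tail, which stays short).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .chemotaxis import MOVE_DX, MOVE_DY

# float parameter vector layout
FP_P_NR, FP_P_NC, FP_P_MR, FP_P_MG, FP_P_ML, FP_P_MA = range(6)
FP_DELTA_AC, FP_DELTA_NC, FP_DELTA_MG = 6, 7, 8
N_FPAR = 9

# int parameter vector layout
IP_N_MAX, IP_M_MAX, IP_MAC_PERIOD, IP_NEU_PERIOD, IP_NEU_MOVES = range(5)
IP_MAC_LO, IP_MAC_HI, IP_NEU_LO, IP_NEU_HI, IP_APO_LO, IP_APO_HI = range(5, 11)
IP_APO_IN_CAP = 11
N_IPAR = 12

_DY = MOVE_DY.copy()
_DX = MOVE_DX.copy()


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sample8(weights):
    """Draw an index 0-7 proportional to 8 non-negative weights."""
    total = 0.0
    for j in range(8):
        total += weights[j]
    u = np.random.random() * total
    acc = 0.0
    for j in range(7):
        acc += weights[j]
        if u < acc:
            return j
    return 7


@njit(cache=True)
def _pick_apoptotic(y, x, a0, a_count, apo_y, apo_x, apo_alive,
                    bucket_start, bucket_idx, W):
    """Uniformly random alive apoptotic agent at site (y, x), or -1."""
    s = y * W + x
    count = 0
    for b in range(bucket_start[s], bucket_start[s + 1]):
        if apo_alive[bucket_idx[b]]:
            count += 1
    for i in range(a0, a_count):
        if apo_alive[i] and apo_y[i] == y and apo_x[i] == x:
            count += 1
    if count == 0:
        return -1
    target = np.random.randint(0, count)
    k = 0
    for b in range(bucket_start[s], bucket_start[s + 1]):
        i = bucket_idx[b]
        if apo_alive[i]:
            if k == target:
                return i
            k += 1
    for i in range(a0, a_count):
        if apo_alive[i] and apo_y[i] == y and apo_x[i] == x:
            if k == target:
                return i
            k += 1
    return -1


@njit(cache=True)
def tick_kernel(tick, c, g, pending_c, pending_g,
                wgrad, has_c, dep_elig, mac_elig, neu_elig, mem_table,
                mac_y, mac_x, mac_dir, mac_life, mac_act, mac_alive, m0,
                neu_y, neu_x, neu_dir, neu_life, neu_alive, n0,
                apo_y, apo_x, apo_cd, apo_alive, a0,
                apo_site, bucket_start, bucket_idx,
                fpar, ipar):
    """Recruitment plus one shuffled agent-action phase.  Returns the new
    (macrophage, neutrophil, apoptotic) array high-water counts; the caller
    compacts on the alive masks."""
    H, W = c.shape
    m_count = m0
    n_count = n0
    a_count = a0

    n_alive = n0
    m_alive = m0
    if ipar[IP_APO_IN_CAP] == 1:
        n_alive += a0

    # --- recruitment sweeps (neutrophils every 2 ticks, macrophages every 5)
    if tick % ipar[IP_NEU_PERIOD] == 0:
        order = np.random.permutation(H * W)
        for s in order:
            if n_alive >= ipar[IP_N_MAX]:
                break
            y = s // W
            x = s % W
            if neu_elig[y, x] and np.random.random() < fpar[FP_P_NR]:
                neu_y[n_count] = y
                neu_x[n_count] = x
                neu_dir[n_count] = np.random.randint(0, 8)
                neu_life[n_count] = np.random.randint(
                    ipar[IP_NEU_LO], ipar[IP_NEU_HI] + 1)
                neu_alive[n_count] = True
                n_count += 1
                n_alive += 1
    if tick % ipar[IP_MAC_PERIOD] == 0:
        order = np.random.permutation(H * W)
        for s in order:
            if m_alive >= ipar[IP_M_MAX]:
                break
            y = s // W
            x = s % W
            if mac_elig[y, x] and np.random.random() < fpar[FP_P_MR]:
                mac_y[m_count] = y
                mac_x[m_count] = x
                mac_dir[m_count] = np.random.randint(0, 8)
                mac_life[m_count] = np.random.randint(
                    ipar[IP_MAC_LO], ipar[IP_MAC_HI] + 1)
                mac_act[m_count] = False
                mac_alive[m_count] = True
                m_count += 1
                m_alive += 1

    # --- one uniformly shuffled order over every agent present now
    total = m_count + n_count + a0
    order = np.random.permutation(total)
    weights = np.empty(8)

    for oid in order:
        if oid < m_count:
            i = oid
            if not mac_alive[i]:
                continue
            y = mac_y[i]
            x = mac_x[i]
            # move: apoptotic neighbour > chemotaxis > uniform random
            ncand = 0
            for j in range(8):
                yy = (y + _DY[j]) % H
                xx = (x + _DX[j]) % W
                if apo_site[yy, xx] > 0:
                    weights[ncand] = j
                    ncand += 1
            if ncand > 0:
                d = int(weights[np.random.randint(0, ncand)])
            elif has_c[y, x]:
                for j in range(8):
                    weights[j] = wgrad[y, x, j] * mem_table[mac_dir[i], j]
                d = _sample8(weights)
            else:
                d = np.random.randint(0, 8)
            y = (y + _DY[d]) % H
            x = (x + _DX[d]) % W
            mac_y[i] = y
            mac_x[i] = x
            mac_dir[i] = d
            # phagocytosis of one co-located apoptotic cell
            if apo_site[y, x] > 0:
                v = _pick_apoptotic(y, x, a0, a_count, apo_y, apo_x,
                                    apo_alive, bucket_start, bucket_idx, W)
                if v >= 0 and np.random.random() < fpar[FP_P_MA]:
                    apo_alive[v] = False
                    apo_site[y, x] -= 1
                    mac_act[i] = True
            # anti-inflammatory release, only once activated
            if mac_act[i] and np.random.random() < fpar[FP_P_MG]:
                pending_g[y, x] += fpar[FP_DELTA_MG]
            # departure from resolved tissue
            if dep_elig[y, x] and np.random.random() < fpar[FP_P_ML]:
                mac_alive[i] = False
                m_alive -= 1
                continue
            # ageing
            mac_life[i] -= 1
            if mac_life[i] <= 0:
                mac_alive[i] = False
                m_alive -= 1

        elif oid < m_count + n_count:
            i = oid - m_count
            if not neu_alive[i]:
                continue
            y = neu_y[i]
            x = neu_x[i]
            d = neu_dir[i]
            for _ in range(ipar[IP_NEU_MOVES]):
                for j in range(8):
                    weights[j] = wgrad[y, x, j] * mem_table[d, j]
                d = _sample8(weights)
                y = (y + _DY[d]) % H
                x = (x + _DX[d]) % W
            neu_y[i] = y
            neu_x[i] = x
            neu_dir[i] = d
            if np.random.random() < fpar[FP_P_NC]:
                pending_c[y, x] += fpar[FP_DELTA_NC]
            neu_life[i] -= 1
            if neu_life[i] <= 0:
                # apoptosis: in-place replacement by an apoptotic agent
                neu_alive[i] = False
                apo_y[a_count] = y
                apo_x[a_count] = x
                apo_cd[a_count] = np.random.randint(
                    ipar[IP_APO_LO], ipar[IP_APO_HI] + 1)
                apo_alive[a_count] = True
                apo_site[y, x] += 1
                a_count += 1
                if ipar[IP_APO_IN_CAP] == 0:
                    n_alive -= 1

        else:
            i = oid - m_count - n_count
            if not apo_alive[i]:
                continue
            apo_cd[i] -= 1
            if apo_cd[i] <= 0:
                # necrosis: dump mediator and vanish
                pending_c[apo_y[i], apo_x[i]] += fpar[FP_DELTA_AC]
                apo_alive[i] = False
                apo_site[apo_y[i], apo_x[i]] -= 1
                if ipar[IP_APO_IN_CAP] == 1:
                    n_alive -= 1

    return m_count, n_count, a_count


@njit(cache=True)
def pde_tick(f, D, gamma, dt, n_substeps):
    """One tick of explicit-Euler substeps with the periodic five-point
    Laplacian, matching the NumPy reference in :mod:`inflamsim.mediators`
    operation-for-operation.  Returns the count of clamped negatives."""
    H, W = f.shape
    lap = np.empty_like(f)
    for _ in range(n_substeps):
        for y in range(H):
            ym1 = (y - 1) % H
            yp1 = (y + 1) % H
            for x in range(W):
                lap[y, x] = (f[ym1, x] + f[yp1, x]
                             + f[y, (x - 1) % W] + f[y, (x + 1) % W]
                             - 4.0 * f[y, x])
        for y in range(H):
            for x in range(W):
                f[y, x] += dt * (D * lap[y, x] - gamma * f[y, x])
    clamped = 0
    for y in range(H):
        for x in range(W):
            if f[y, x] < 0.0:
                f[y, x] = 0.0
                clamped += 1
    return clamped


@njit(cache=True)
def tick_precompute(c, k_grad, eps, alpha_ml, wgrad, has_c, dep_elig):
    """Fill the per-site gradient weights, mediator-presence mask and
    departure-eligibility mask in one pass (compiled twin of
    :func:`gradient_weights` / :func:`block3_max` / :func:`block3_sum`)."""
    H, W = c.shape
    for y in range(H):
        ym1 = (y - 1) % H
        yp1 = (y + 1) % H
        for x in range(W):
            xm1 = (x - 1) % W
            xp1 = (x + 1) % W
            ci = c[y, x]
            zmax = -1e300
            for j in range(8):
                z = k_grad * (c[(y + _DY[j]) % H, (x + _DX[j]) % W] - ci)
                wgrad[y, x, j] = z
                if z > zmax:
                    zmax = z
            for j in range(8):
                wgrad[y, x, j] = np.exp(wgrad[y, x, j] - zmax)
            s = ci
            m = ci
            for yy in (ym1, y, yp1):
                for xx in (xm1, x, xp1):
                    if yy == y and xx == x:
                        continue
                    v = c[yy, xx]
                    s += v
                    if v > m:
                        m = v
            has_c[y, x] = m >= eps
            dep_elig[y, x] = s < alpha_ml


def gradient_weights(c: np.ndarray, k_grad: float) -> np.ndarray:
    """Per-site, max-shifted gradient weights for all 8 directions (H, W, 8)."""
    h, w = c.shape
    dc = np.empty((h, w, 8))
    for j in range(8):
        dc[:, :, j] = np.roll(np.roll(c, -int(_DY[j]), axis=0),
                              -int(_DX[j]), axis=1) - c
    z = k_grad * dc
    z -= z.max(axis=2, keepdims=True)
    return np.exp(z)


def block3_sum(field: np.ndarray) -> np.ndarray:
    """Summed field over each site's 3x3 periodic block."""
    out = np.zeros_like(field)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out += np.roll(np.roll(field, dy, axis=0), dx, axis=1)
    return out


def block3_max(field: np.ndarray) -> np.ndarray:
    out = field.copy()
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            np.maximum(out, np.roll(np.roll(field, dy, axis=0), dx, axis=1),
                       out=out)
    return out


def memory_table(sigma_mem: float, wrap: bool = True) -> np.ndarray:
    """(8, 8) table of persistence weights, row = previous direction."""
    from .chemotaxis import ANGLES, angular_distance

    table = np.empty((8, 8))
    for i in range(8):
        d = angular_distance(ANGLES, ANGLES[i], wrap=wrap)
        table[i] = np.exp(-(d * d) / (2.0 * sigma_mem * sigma_mem))
    return table
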