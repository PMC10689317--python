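"""Independent brute-force oracles used by the tests.

Everything here is written as naive, loop-based enumeration straight from
the matrix definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def _offsets(shape):
    ranges = [(-1, 0, 1) if s > 1 else (0,) for s in shape]
    return [o for o in itertools.product(*ranges) if o != (0, 0, 0)]


def _inside(shape, idx):
    return all(0 <= i < s for i, s in zip(idx, shape))


# --- GLSZM ------------------------------------------------------------------

def glszm_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) per maximal 26-connected equal-level zone, by flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for idx in np.ndindex(shape):
        if not mask[idx] or seen[idx]:
            continue
        lv = levels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in _offsets(shape):
                nb = tuple(c + o for c, o in zip(cur, off))
                if _inside(shape, nb) and mask[nb] and not seen[nb] and levels[nb] == lv:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((int(lv), size))
    return zones


def glszm_lahgle_glnn(levels, mask):
    zones = glszm_zones(levels, mask)
    nz = len(zones)
    lahgle = sum(i**2 * j**2 for i, j in zones) / nz
    counts = {}
    for i, _ in zones:
        counts[i] = counts.get(i, 0) + 1
    glnn = sum(c**2 for c in counts.values()) / nz**2
    return lahgle, glnn


# --- GLDM -------------------------------------------------------------------

def gldm_ldhgle(levels, mask, alpha=0):
    shape = levels.shape
    total = 0.0
    nv = 0
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        dep = 1
        for off in _offsets(shape):
            nb = tuple(c + o for c, o in zip(idx, off))
            if _inside(shape, nb) and mask[nb] and abs(int(levels[nb]) - int(levels[idx])) <= alpha:
                dep += 1
        total += int(levels[idx]) ** 2 * dep**2
        nv += 1
    return total / nv


# --- NGTDM ------------------------------------------------------------------

def ngtdm_complexity(levels, mask):
    shape = levels.shape
    ng = int(levels[mask].max())
    n_i = np.zeros(ng + 1)
    s_i = np.zeros(ng + 1)
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        nb_vals = []
        for off in _offsets(shape):
            nb = tuple(c + o for c, o in zip(idx, off))
            if _inside(shape, nb) and mask[nb]:
                nb_vals.append(int(levels[nb]))
        if not nb_vals:
            continue
        lv = int(levels[idx])
        n_i[lv] += 1
        s_i[lv] += abs(lv - float(np.mean(nb_vals)))
    nvc = n_i.sum()
    p_i = n_i / nvc
    total = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            if p_i[i] > 0 and p_i[j] > 0:
                total += abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
    return total / nvc


# --- GLCM MCC ---------------------------------------------------------------

def glcm_mcc(levels, mask):
    """Average-over-directions MCC from explicitly enumerated co-occurrences."""
    shape = levels.shape
    ng = int(levels[mask].max())
    dirs = [o for o in _offsets(shape) if o > tuple(-c for c in o)]
    vals = []
    for off in dirs:
        m = np.zeros((ng, ng))
        for idx in np.ndindex(shape):
            if not mask[idx]:
                continue
            nb = tuple(c + o for c, o in zip(idx, off))
            if _inside(shape, nb) and mask[nb]:
                m[int(levels[idx]) - 1, int(levels[nb]) - 1] += 1
                m[int(levels[nb]) - 1, int(levels[idx]) - 1] += 1
        if m.sum() == 0:
            continue
        p = m / m.sum()
        px = p.sum(axis=1)
        keep = [i for i in range(ng) if px[i] > 0]
        if len(keep) <= 1:
            vals.append(1.0)
            continue
        q = np.zeros((len(keep), len(keep)))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                q[a, b] = sum(p[i, k] * p[j, k] / (px[i] * px[k]) for k in keep)
        ev = sorted(np.real(np.linalg.eigvals(q)), reverse=True)
        vals.append(np.sqrt(min(max(ev[1], 0.0), 1.0)))
    if not vals:
        return 1.0
    return float(np.mean(vals))


# --- survival oracles -------------------------------------------------------

def harrell_c(time, event, score):
    """Pairwise enumeration: usable pairs have the earlier time as an event."""
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


def km_product_limit(time, event):
    """Hand product-limit estimator: {time: survival} at distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = {}
    for t in sorted(set(time)):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        if d > 0:
            s *= 1.0 - d / at_risk
        out[t] = s
    return out


def logrank_chi2(time, event, group):
    """Two-group log-rank O-E/V arithmetic at each distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = int(np.sum((time == t) & (event == 1)))
        d1 = int(np.sum((time == t) & (event == 1) & (group == 1)))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
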