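"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (flood fills, shift-unions, explicit
enumerations, closed forms) and shares no code path with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import log, sqrt

import numpy as np

CROSS_OFFSETS = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
CUBE_OFFSETS = [
    (dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
]


def dilate_shift_union(vol: np.ndarray, offsets) -> np.ndarray:
    """Dilation as an explicit union of shifted copies, clipped at faces."""
    out = np.zeros_like(vol, dtype=bool)
    nz, ny, nx = vol.shape
    for dz, dy, dx in offsets:
        src = vol[
            max(0, -dz) : nz - max(0, dz),
            max(0, -dy) : ny - max(0, dy),
            max(0, -dx) : nx - max(0, dx),
        ]
        out[
            max(0, dz) : nz - max(0, -dz),
            max(0, dy) : ny - max(0, -dy),
            max(0, dx) : nx - max(0, -dx),
        ] |= src
    return out


def label_components_2d(mask: np.ndarray) -> np.ndarray:
    """8-connected 2D labeling by breadth-first flood fill."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if (
                        0 <= yy < mask.shape[0]
                        and 0 <= xx < mask.shape[1]
                        and mask[yy, xx]
                        and not labels[yy, xx]
                    ):
                        labels[yy, xx] = current
                        stack.append((yy, xx))
    return labels


def min_section_brute(vol: np.ndarray) -> np.ndarray:
    """Per-voxel minimal Cartesian section via flood-fill labeling per slice."""
    out = np.zeros(vol.shape, dtype=int)
    big = vol.size + 1
    tmp = np.where(vol, big, 0)
    for axis in range(3):
        for i in range(vol.shape[axis]):
            sl = np.take(vol, i, axis=axis)
            labels = label_components_2d(sl)
            if labels.max() == 0:
                continue
            areas = np.bincount(labels.ravel())
            area_map = np.where(sl, areas[labels], big)
            idx = [slice(None)] * 3
            idx[axis] = i
            view = tmp[tuple(idx)]
            tmp[tuple(idx)] = np.minimum(view, np.where(sl, area_map, view))
    out[vol] = tmp[vol]
    return out


def max_section_per_component_brute(vol: np.ndarray) -> dict[int, int]:
    """For each 26-connected 3D component (BFS), the max 2D section area."""
    labels3 = np.zeros(vol.shape, dtype=int)
    comp = 0
    offsets = [o for o in CUBE_OFFSETS if o != (0, 0, 0)]
    for start in zip(*np.nonzero(vol)):
        if labels3[start]:
            continue
        comp += 1
        stack = [start]
        labels3[start] = comp
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[k] < vol.shape[k] for k in range(3)) and vol[p] and not labels3[p]:
                    labels3[p] = comp
                    stack.append(p)
    best: dict[int, int] = {c: 0 for c in range(1, comp + 1)}
    for axis in range(3):
        for i in range(vol.shape[axis]):
            sl = np.take(vol, i, axis=axis)
            l2 = label_components_2d(sl)
            l3 = np.take(labels3, i, axis=axis)
            for lab2 in range(1, l2.max() + 1):
                area = int((l2 == lab2).sum())
                c3 = int(l3[l2 == lab2][0])
                best[c3] = max(best[c3], area)
    return best


def renyi_reference(histogram) -> int:
    """Rényi-entropy threshold straight from the three-order description.

    For each candidate t and order α the two-class Rényi entropies
    H_α = (1-α)^{-1} ln Σ (p_i/P)^α (Shannon at α→1) are summed; the three
    first-maximizing thresholds are sorted and blended with the β-weight
    rule keyed on 5-grey-level agreement and the mass ω between the outer
    candidates.
    """
    h = np.asarray(histogram, dtype=float)
    p = h / h.sum()
    P1 = np.cumsum(p)
    nz = np.nonzero(h)[0]
    # candidate thresholds keep both classes nonempty: t in [first nonzero,
    # last nonzero - 1]
    first, last = int(nz[0]), int(nz[-1]) - 1

    def entropy(mass: np.ndarray, alpha: float) -> float:
        total = mass.sum()
        q = mass[mass > 0] / total
        if alpha == 1.0:
            return float(-(q * np.log(q)).sum())
        return float(log((q**alpha).sum()) / (1.0 - alpha))

    def argmax(alpha: float) -> int:
        best_t, best_v = first, -np.inf
        for t in range(first, last + 1):
            v = entropy(p[: t + 1], alpha) + entropy(p[t + 1 :], alpha)
            if abs(v) < 1e-12:
                v = 0.0
            if v > best_v:
                best_v, best_t = v, t
        return best_t

    t1, t2, t3 = sorted(argmax(a) for a in (0.5, 1.0, 2.0))
    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    omega = P1[t3] - P1[t1]
    opt = (
        t1 * (P1[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * ((1.0 - P1[t3]) + 0.25 * omega * beta[2])
    )
    return int(opt)


def ranksum_exact_two_sided_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(pooled)
    na = len(a)
    sums = [sum(ranks[pooled[i]] for i in comb) for comb in combinations(range(n), na)]
    mean = (na * (n + 1)) / 2
    dev = abs(observed - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


def quadratic_normal_equations(x, y) -> tuple[float, float, float, float]:
    """2nd-degree least squares via the normal equations, plus R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.stack([x**2, x, np.ones_like(x)], axis=1)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return float(beta[0]), float(beta[1]), float(beta[2]), r2


def welch_p_closed_form(a, b) -> float:
    """Welch two-tailed p from the textbook formulas (t statistic and
    Welch–Satterthwaite degrees of freedom), using only the t CDF."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    tstat = (a.mean() - b.mean()) / sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    return 2.0 * float(tdist.sf(abs(tstat), df))


def disc_area_lattice(radius: float) -> int:
    """Count lattice points with x² + y² ≤ r² by explicit double loop."""
    r = int(np.ceil(radius))
    count = 0
    for x in range(-r, r + 1):
        for y in range(-r, r + 1):
            if x * x + y * y <= radius * radius:
                count += 1
    return count
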