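"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: texture matrices are
enumerated voxel by voxel, AUC is a concordant-pair count, and the
multicollinearity reduction is re-derived by exhaustive graph closure.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

DIRS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
DIRS_13 = [d for d in DIRS_26 if d > (0, 0, 0) or next(c for c in d if c) > 0]
DIRS_13 = []
for d in DIRS_26:
    for c in d:
        if c != 0:
            if c > 0:
                DIRS_13.append(d)
            break


def brute_glcm(bins: np.ndarray, mask: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts by looping over every voxel."""
    m = np.zeros((n_levels, n_levels))
    nz, ny, nx = bins.shape
    dz, dy, dx = direction
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx]:
                    a, b = bins[z, y, x] - 1, bins[zz, yy, xx] - 1
                    m[a, b] += 1
                    m[b, a] += 1
    return m


def brute_glrlm(bins: np.ndarray, mask: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run-length counts by greedy walking from every run start."""
    nz, ny, nx = bins.shape
    dz, dy, dx = direction
    runs = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                pz, py, px = z - dz, y - dy, x - dx
                if (
                    0 <= pz < nz and 0 <= py < ny and 0 <= px < nx
                    and mask[pz, py, px]
                    and bins[pz, py, px] == bins[z, y, x]
                ):
                    continue  # not a run start
                g = bins[z, y, x]
                length = 1
                zz, yy, xx = z + dz, y + dy, x + dx
                while (
                    0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                    and mask[zz, yy, xx] and bins[zz, yy, xx] == g
                ):
                    length += 1
                    zz, yy, xx = zz + dz, yy + dy, xx + dx
                runs.append((g, length))
    max_len = max((l for _, l in runs), default=1)
    m = np.zeros((n_levels, max_len))
    for g, l in runs:
        m[g - 1, l - 1] += 1
    return m


def brute_glszm(bins: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone sizes by explicit 26-connected flood fill."""
    nz, ny, nx = bins.shape
    seen = set()
    zones = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or (z, y, x) in seen:
                    continue
                g = bins[z, y, x]
                stack = [(z, y, x)]
                seen.add((z, y, x))
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in DIRS_26:
                        nzz, nyy, nxx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nzz < nz and 0 <= nyy < ny and 0 <= nxx < nx
                            and (nzz, nyy, nxx) not in seen
                            and mask[nzz, nyy, nxx]
                            and bins[nzz, nyy, nxx] == g
                        ):
                            seen.add((nzz, nyy, nxx))
                            stack.append((nzz, nyy, nxx))
                zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    m = np.zeros((n_levels, max_size))
    for g, s in zones:
        m[g - 1, s - 1] += 1
    return m


def concordance_auc(scores, labels) -> float:
    """AUC as the concordant-pair probability with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_reduction(X: np.ndarray, labels: np.ndarray, threshold: float, pvals: np.ndarray):
    """Connected components of the |r|>threshold graph + smallest-p reps.

    Components are found by repeated closure over the explicit pair list;
    p-values are supplied so the oracle only re-derives the grouping and
    representative choice.
    """
    nf = X.shape[1]
    sd = X.std(axis=0)
    edges = set()
    for i, j in combinations(range(nf), 2):
        if sd[i] == 0 or sd[j] == 0:
            continue
        r = np.corrcoef(X[:, i], X[:, j])[0, 1]
        if abs(r) > threshold:
            edges.add((i, j))
    comps = []
    unassigned = set(range(nf))
    while unassigned:
        start = min(unassigned)
        comp = {start}
        changed = True
        while changed:
            changed = False
            for i, j in edges:
                if i in comp and j not in comp:
                    comp.add(j)
                    changed = True
                if j in comp and i not in comp:
                    comp.add(i)
                    changed = True
        comps.append(sorted(comp))
        unassigned -= comp
    kept = []
    for comp in comps:
        best = min(comp, key=lambda i: (pvals[i], i))
        kept.append(best)
    return sorted(kept)
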