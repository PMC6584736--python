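"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive: plain Python loops, sets, and
breadth-first searches, sharing no code with the package implementations
they check.
"""
from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

ESSENTIAL_DEATH = 255.5


# ------------------------------------------------------------------
# cubical persistence by full GF(2) column reduction (no twist, no clearing)
# ------------------------------------------------------------------

def _cells(values: np.ndarray):
    """Enumerate all cells of the vertex-construction cubical complex as
    (coords, dim, value): voxels are vertices at even lattice coordinates,
    higher cells take the max over their incident voxels."""
    nx, ny, nz = values.shape
    cells = []
    for a in range(2 * nx - 1):
        for b in range(2 * ny - 1):
            for c in range(2 * nz - 1):
                dim = (a % 2) + (b % 2) + (c % 2)
                ax = [a // 2] if a % 2 == 0 else [(a - 1) // 2, (a + 1) // 2]
                ay = [b // 2] if b % 2 == 0 else [(b - 1) // 2, (b + 1) // 2]
                az = [c // 2] if c % 2 == 0 else [(c - 1) // 2, (c + 1) // 2]
                val = max(values[i, j, k] for i in ax for j in ay for k in az)
                cells.append(((a, b, c), dim, float(val)))
    return cells


def _boundary_coords(coords):
    a, b, c = coords
    out = []
    if a % 2:
        out += [(a - 1, b, c), (a + 1, b, c)]
    if b % 2:
        out += [(a, b - 1, c), (a, b + 1, c)]
    if c % 2:
        out += [(a, b, c - 1), (a, b, c + 1)]
    return out


def brute_force_diagrams(values: np.ndarray) -> dict[int, list[tuple[float, float, bool]]]:
    """All nonzero-lifetime birth-death pairs per degree, plus essential
    classes at death ESSENTIAL_DEATH, by reducing the full boundary matrix
    left to right."""
    values = np.asarray(values, dtype=float)
    cells = _cells(values)
    order = sorted(range(len(cells)), key=lambda i: (cells[i][2], cells[i][1], i))
    rank = {cells[i][0]: pos for pos, i in enumerate(order)}

    columns: list[set[int]] = []
    for pos, i in enumerate(order):
        coords, dim, _ = cells[i]
        columns.append({rank[f] for f in _boundary_coords(coords)})

    low_owner: dict[int, int] = {}
    pairs = []  # (birth_pos, death_pos)
    for j in range(len(columns)):
        col = columns[j]
        while col:
            piv = max(col)
            if piv not in low_owner:
                break
            col ^= columns[low_owner[piv]]
        columns[j] = col
        if col:
            piv = max(col)
            low_owner[piv] = j
            pairs.append((piv, j))

    paired = {p for pr in pairs for p in pr}
    out: dict[int, list[tuple[float, float, bool]]] = {0: [], 1: [], 2: []}
    for bpos, dpos in pairs:
        _, dim_b, val_b = cells[order[bpos]]
        _, _, val_d = cells[order[dpos]]
        if val_d > val_b and dim_b <= 2:
            out[dim_b].append((val_b, val_d, False))
    for pos in range(len(order)):
        if pos not in paired:
            _, dim, val = cells[order[pos]]
            if dim <= 2:
                out[dim].append((val, ESSENTIAL_DEATH, True))
    return out


def diagrams_to_multisets(dgms) -> dict[int, list[tuple]]:
    """Package diagrams -> sorted multiset of (birth, death, essential)."""
    out = {}
    for q, dg in dgms.items():
        out[q] = sorted(
            (round(b, 9), round(d, 9), bool(e))
            for b, d, e in zip(dg.births, dg.deaths, dg.essential)
        )
    return out


def oracle_multisets(values) -> dict[int, list[tuple]]:
    raw = brute_force_diagrams(values)
    return {q: sorted((round(b, 9), round(d, 9), e) for b, d, e in raw[q]) for q in raw}


def euler_characteristic_at(values: np.ndarray, h: float) -> int:
    """chi = V - E + F - C by direct census of cells with value <= h."""
    chi = 0
    for _, dim, val in _cells(np.asarray(values, dtype=float)):
        if val <= h:
            chi += (-1) ** dim
    return chi


def component_count_at(values: np.ndarray, h: float) -> int:
    """6-connected components of the sublevel binary volume, by union-find."""
    mask = np.asarray(values) <= h
    idx = {tuple(c): i for i, c in enumerate(np.argwhere(mask))}
    parent = list(range(len(idx)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (x, y, z), i in idx.items():
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (x + d[0], y + d[1], z + d[2])
            if nb in idx:
                ri, rj = find(i), find(idx[nb])
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(len(idx))})


# ------------------------------------------------------------------
# texture matrix oracles
# ------------------------------------------------------------------

_OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
_OFFSETS_26 = _OFFSETS_13 + [tuple(-x for x in o) for o in _OFFSETS_13]


def glcm_oracle(levels: np.ndarray, ng: int) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix by looping every voxel and
    all 26 signed offsets."""
    m = np.zeros((ng, ng))
    shape = levels.shape
    for x, y, z in itertools.product(*map(range, shape)):
        for dx, dy, dz in _OFFSETS_26:
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]:
                m[levels[x, y, z] - 1, levels[u, v, w] - 1] += 1
    return m / m.sum()


def glrlm_oracle(levels: np.ndarray, ng: int, directions=_OFFSETS_13) -> np.ndarray:
    """Run-length matrix by explicitly walking maximal runs per direction."""
    shape = levels.shape
    runs: dict[tuple[int, int], int] = {}
    for d in directions:
        seen = set()
        for start in itertools.product(*map(range, shape)):
            if start in seen:
                continue
            prev = tuple(start[i] - d[i] for i in range(3))
            if all(0 <= prev[i] < shape[i] for i in range(3)) and levels[prev] == levels[start]:
                continue  # not a run start
            length = 0
            cur = start
            while all(0 <= cur[i] < shape[i] for i in range(3)) and levels[cur] == levels[start]:
                seen.add(cur)
                length += 1
                cur = tuple(cur[i] + d[i] for i in range(3))
            runs[(levels[start], length)] = runs.get((levels[start], length), 0) + 1
        # seen marks only this direction's covered voxels; reset next loop
        seen = set()
    max_len = max(l for _, l in runs)
    mat = np.zeros((ng, max_len), dtype=np.int64)
    for (lev, length), cnt in runs.items():
        mat[lev - 1, length - 1] += cnt
    return mat


def glszm_oracle(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone matrix by BFS flood fill over 26-neighborhoods."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for start in itertools.product(*map(range, shape)):
        if visited[start]:
            continue
        level = levels[start]
        size = 0
        queue = deque([start])
        visited[start] = True
        while queue:
            cur = queue.popleft()
            size += 1
            for off in _OFFSETS_26:
                nb = tuple(cur[i] + off[i] for i in range(3))
                if (
                    all(0 <= nb[i] < shape[i] for i in range(3))
                    and not visited[nb]
                    and levels[nb] == level
                ):
                    visited[nb] = True
                    queue.append(nb)
        zones[(level, size)] = zones.get((level, size), 0) + 1
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size), dtype=np.int64)
    for (lev, size), cnt in zones.items():
        mat[lev - 1, size - 1] += cnt
    return mat


def ngtdm_oracle(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """(p_i, s_i): occupancy fractions and summed |level - neighborhood mean|."""
    shape = levels.shape
    p = np.zeros(ng)
    s = np.zeros(ng)
    n = levels.size
    for x, y, z in itertools.product(*map(range, shape)):
        lev = levels[x, y, z]
        nbs = []
        for off in _OFFSETS_26:
            u, v, w = x + off[0], y + off[1], z + off[2]
            if 0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]:
                nbs.append(levels[u, v, w])
        p[lev - 1] += 1.0 / n
        s[lev - 1] += abs(lev - sum(nbs) / len(nbs))
    return p, s


def run_zone_stats_oracle(mat: np.ndarray, n_voxels: int, n_dirs: int) -> list[float]:
    """The 13 shared run/zone statistics via explicit loops."""
    ng, max_l = mat.shape
    nr = mat.sum()
    vals = {k: 0.0 for k in range(13)}
    mu_i = sum((i + 1) * mat[i, l] / nr for i in range(ng) for l in range(max_l))
    mu_l = sum((l + 1) * mat[i, l] / nr for i in range(ng) for l in range(max_l))
    sre = lre = gln = rln = lgl = hgl = slgl = shgl = llgl = lhgl = glv = rlv = 0.0
    for i in range(ng):
        gln += mat[i, :].sum() ** 2
        for l in range(max_l):
            m = mat[i, l]
            if m == 0:
                continue
            gi, rl = i + 1.0, l + 1.0
            sre += m / rl**2
            lre += m * rl**2
            lgl += m / gi**2
            hgl += m * gi**2
            slgl += m / (gi**2 * rl**2)
            shgl += m * gi**2 / rl**2
            llgl += m * rl**2 / gi**2
            lhgl += m * gi**2 * rl**2
            glv += (gi - mu_i) ** 2 * m / nr
            rlv += (rl - mu_l) ** 2 * m / nr
    for l in range(max_l):
        rln += mat[:, l].sum() ** 2
    return [
        sre / nr, lre / nr, gln / nr, rln / nr, nr / (n_voxels * n_dirs),
        lgl / nr, hgl / nr, slgl / nr, shgl / nr, llgl / nr, lhgl / nr, glv, rlv,
    ]


def glcm_stats_oracle(p: np.ndarray) -> dict[str, float]:
    """The 9 co-occurrence statistics via explicit loops."""
    ng = p.shape[0]
    px = [p[i, :].sum() for i in range(ng)]
    mu = sum((i + 1) * px[i] for i in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    out = dict.fromkeys(
        ["Energy", "Contrast", "Correlation", "Homogeneity", "Variance",
         "Sum Average", "Entropy", "Dissimilarity", "Auto Correlation"], 0.0)
    for i in range(ng):
        for j in range(ng):
            pij = p[i, j]
            gi, gj = i + 1, j + 1
            out["Energy"] += pij**2
            out["Contrast"] += (gi - gj) ** 2 * pij
            out["Homogeneity"] += pij / (1 + abs(gi - gj))
            out["Variance"] += (gi - mu) ** 2 * pij
            out["Sum Average"] += (gi + gj) * pij
            out["Dissimilarity"] += abs(gi - gj) * pij
            out["Auto Correlation"] += gi * gj * pij
            if pij > 0:
                out["Entropy"] -= pij * math.log2(pij)
            if sig2 > 0:
                out["Correlation"] += (gi - mu) * (gj - mu) * pij / sig2
    return out


def ngtdm_stats_oracle(p: np.ndarray, s: np.ndarray, n_voxels: int, eps=1e-6) -> dict[str, float]:
    present = [i for i in range(len(p)) if p[i] > 0]
    ngp = len(present)
    psi = sum(p[i] * s[i] for i in present)
    out = {"Coarseness": 1.0 / (eps + psi), "Contrast": 0.0, "Busyness": 0.0,
           "Complexity": 0.0, "Strength": 0.0}
    if ngp > 1:
        con = sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        out["Contrast"] = con / (ngp * (ngp - 1)) * s.sum() / n_voxels
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present)
        out["Busyness"] = psi / denom if denom > 1e-10 else 0.0
        out["Complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (n_voxels * (p[i] + p[j]))
            for i in present for j in present
        )
        out["Strength"] = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
        ) / (eps + s.sum())
    return out
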