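"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plain Python loops / exhaustive enumeration,
deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

EPS = 1e-6
COARSENESS_CAP = 1e6


# -- co-occurrence -----------------------------------------------------------


def glcm_counts_bruteforce(levels: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric pair counts by scanning every voxel."""
    c = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = levels[x, y, z]
                if i == 0:
                    continue
                x2, y2, z2 = x + dx, y + dy, z + dz
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                j = levels[x2, y2, z2]
                if j == 0:
                    continue
                c[i - 1, j - 1] += 1
                c[j - 1, i - 1] += 1
    return c


def glcm_features_bruteforce(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    uni = ent = dis = con = hom = idm = 0.0
    for a in range(n):
        for b in range(n):
            v = p[a, b]
            uni += v * v
            if v > 0:
                ent -= v * math.log2(v)
            d = abs((a + 1) - (b + 1))
            dis += v * d
            con += v * d * d
            hom += v / (1 + d)
            idm += v / (1 + d * d)
    mu_x = sum((a + 1) * p[a, :].sum() for a in range(n))
    mu_y = sum((b + 1) * p[:, b].sum() for b in range(n))
    var_x = sum(((a + 1) - mu_x) ** 2 * p[a, :].sum() for a in range(n))
    var_y = sum(((b + 1) - mu_y) ** 2 * p[:, b].sum() for b in range(n))
    sxy = math.sqrt(var_x) * math.sqrt(var_y)
    if sxy == 0:
        cor = 0.0
    else:
        eij = sum(
            (a + 1) * (b + 1) * p[a, b] for a in range(n) for b in range(n)
        )
        cor = (eij - mu_x * mu_y) / sxy
    return {
        "Uniformity": uni,
        "Entropy": ent,
        "Dissimilarity": dis,
        "Contrast": con,
        "Homogeneity": hom,
        "InverseDifferenceMoment": idm,
        "Correlation": cor,
    }


# -- run length --------------------------------------------------------------


def glrlm_bruteforce(levels: np.ndarray, offset, n_levels: int) -> dict:
    """Run counts {(level, length): count} by walking from each run start."""
    shape = levels.shape

    def at(p):
        if all(0 <= p[k] < shape[k] for k in range(3)):
            return int(levels[tuple(p)])
        return 0

    runs: dict[tuple[int, int], int] = {}
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = levels[x, y, z]
                if g == 0:
                    continue
                prev = (x - offset[0], y - offset[1], z - offset[2])
                if at(prev) == g:
                    continue  # not a run start
                length = 1
                cur = (x + offset[0], y + offset[1], z + offset[2])
                while at(cur) == g:
                    length += 1
                    cur = tuple(cur[k] + offset[k] for k in range(3))
                runs[(int(g), length)] = runs.get((int(g), length), 0) + 1
    return runs


def glrlm_features_bruteforce(runs: dict, n_voxels: int) -> dict[str, float]:
    n_runs = sum(runs.values())
    sre = sum(c / j**2 for (_, j), c in runs.items()) / n_runs
    lre = sum(c * j**2 for (_, j), c in runs.items()) / n_runs
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for (g, j), c in runs.items():
        by_level[g] = by_level.get(g, 0) + c
        by_length[j] = by_length.get(j, 0) + c
    return {
        "ShortRunsEmphasis": sre,
        "LongRunsEmphasis": lre,
        "GrayLevelNonuniformity": sum(v**2 for v in by_level.values()) / n_runs,
        "RunLengthNonuniformity": sum(v**2 for v in by_length.values()) / n_runs,
        "RunPercentage": n_runs / n_voxels,
    }


# -- size zone ---------------------------------------------------------------


def glszm_bruteforce(levels: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) of every 26-connected equal-level zone, by flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    nbrs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    zones = []
    for start in np.ndindex(shape):
        if seen[start] or levels[start] == 0:
            continue
        g = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in nbrs:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if all(0 <= q[k] < shape[k] for k in range(3)) and not seen[q] \
                        and levels[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((int(g), size))
    return zones


def glszm_features_bruteforce(zones: list[tuple[int, int]], n_voxels: int) -> dict:
    n_z = len(zones)
    by_level: dict[int, int] = {}
    by_size: dict[int, int] = {}
    for g, s in zones:
        by_level[g] = by_level.get(g, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
    return {
        "HighIntensityEmphasis": sum(g**2 for g, _ in zones) / n_z,
        "LowIntensityEmphasis": sum(1 / g**2 for g, _ in zones) / n_z,
        "LargeAreaEmphasis": sum(s**2 for _, s in zones) / n_z,
        "SmallAreaEmphasis": sum(1 / s**2 for _, s in zones) / n_z,
        "IntensityVariability": sum(v**2 for v in by_level.values()) / n_z,
        "RunLengthVariability": sum(v**2 for v in by_size.values()) / n_z,
        "ZonePercentage": n_z / n_voxels,
    }


# -- NGTDM -------------------------------------------------------------------


def ngtdm_bruteforce(levels: np.ndarray, n_levels: int):
    """Per-level (n_i, p_i, s_i) from an explicit neighbor-mean table."""
    shape = levels.shape
    nbrs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    n_i = [0] * n_levels
    s_i = [0.0] * n_levels
    total = 0
    for p in np.ndindex(shape):
        g = levels[p]
        if g == 0:
            continue
        vals = []
        for d in nbrs:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if all(0 <= q[k] < shape[k] for k in range(3)) and levels[q] > 0:
                vals.append(levels[q])
        if not vals:
            continue
        total += 1
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - sum(vals) / len(vals))
    return n_i, s_i, total


def ngtdm_features_bruteforce(n_i, s_i, total) -> dict[str, float]:
    n_levels = len(n_i)
    p_i = [n / total for n in n_i]
    occ = [i for i in range(n_levels) if p_i[i] > 0]
    ps = sum(p_i[i] * s_i[i] for i in range(n_levels))
    coarseness = min(1.0 / (EPS + ps), COARSENESS_CAP)
    n_g = len(occ)
    if n_g < 2:
        contrast = 0.0
        complexity = 0.0
        strength = 0.0
    else:
        contrast = (
            sum(
                p_i[a] * p_i[b] * ((a + 1) - (b + 1)) ** 2
                for a in occ
                for b in occ
            )
            / (n_g * (n_g - 1))
            * (sum(s_i) / total)
        )
        complexity = sum(
            abs((a + 1) - (b + 1))
            * (p_i[a] * s_i[a] + p_i[b] * s_i[b])
            / (total * (p_i[a] + p_i[b]))
            for a in occ
            for b in occ
        )
        strength = sum(
            (p_i[a] + p_i[b]) * ((a + 1) - (b + 1)) ** 2 for a in occ for b in occ
        ) / (EPS + sum(s_i))
    denom = sum(
        abs((a + 1) * p_i[a] - (b + 1) * p_i[b])
        for ai, a in enumerate(occ)
        for b in occ[ai + 1:]
    )
    busyness = ps / denom if denom > 0 else 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# -- histogram ---------------------------------------------------------------


def histogram_features_bruteforce(levels: np.ndarray) -> dict[str, float]:
    vals = [int(v) for v in levels.ravel() if v > 0]
    n = len(vals)
    freq: dict[int, int] = {}
    for v in vals:
        freq[v] = freq.get(v, 0) + 1
    mean = sum(g * c / n for g, c in freq.items())
    var = sum((c / n) * (g - mean) ** 2 for g, c in freq.items())
    ent = -sum((c / n) * math.log2(c / n) for c in freq.values())
    return {"Variance": var, "Entropy": ent}


# -- statistics --------------------------------------------------------------


def auc_pair_count(scores, labels) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 x tied pairs) / (n_pos x n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def wilcoxon_exact_perm_p(x, y) -> float:
    """Two-sided exact permutation p for the rank-sum test, by enumerating
    every assignment of the pooled values to the two groups."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def ustat(xs, ys):
        return sum((1.0 if a > b else 0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    obs_dev = abs(ustat(x, y) - n * m / 2.0)
    count = hits = 0
    for comb in itertools.combinations(range(n + m), n):
        in_x = set(comb)
        xs = [pooled[i] for i in range(n + m) if i in in_x]
        ys = [pooled[i] for i in range(n + m) if i not in in_x]
        dev = abs(ustat(xs, ys) - n * m / 2.0)
        count += 1
        if dev >= obs_dev - 1e-12:
            hits += 1
    return hits / count


def confusion_metrics_bruteforce(scores, labels, cutoff, rule) -> dict[str, float]:
    tp = fp = tn = fn = 0
    for s, l in zip(scores, labels):
        pred = s >= cutoff if rule == ">=" else s <= cutoff
        if pred and l:
            tp += 1
        elif pred and not l:
            fp += 1
        elif not pred and l:
            fn += 1
        else:
            tn += 1
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
        "accuracy": (tp + tn) / (tp + fp + tn + fn),
    }
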