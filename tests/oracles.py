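"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — explicit loops, pairwise enumeration,
direct formula evaluation — kept separate from the library code paths they
check.
"""

import math

import numpy as np


def cell_of(point, origin, spacing, dims):
    """Half-open cell membership by explicit per-axis comparison."""
    idx = []
    for axis in range(3):
        rel = (point[axis] - origin[axis]) / spacing
        i = math.floor(rel)
        if i == dims[axis] and math.isclose(rel, dims[axis]):
            i -= 1  # upper boundary belongs to the last cell
        if not 0 <= i < dims[axis]:
            return None
        idx.append(i)
    return tuple(idx)


def bin_atoms(points, origin, spacing, dims):
    counts = np.zeros(dims, dtype=int)
    for p in points:
        idx = cell_of(p, origin, spacing, dims)
        if idx is not None:
            counts[idx] += 1
    return counts


def regions_by_enumeration(counts, connectivity=26):
    """Core/shell via triple loop over cells and their neighbours."""
    dims = counts.shape
    core, shell = set(), set()
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
        and abs(dx) + abs(dy) + abs(dz) <= {6: 1, 18: 2, 26: 3}[connectivity]
    ]
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                if counts[i, j, k] > 0:
                    core.add((i, j, k))
                    continue
                for dx, dy, dz in offsets:
                    ni, nj, nk = i + dx, j + dy, k + dz
                    if (
                        0 <= ni < dims[0]
                        and 0 <= nj < dims[1]
                        and 0 <= nk < dims[2]
                        and counts[ni, nj, nk] > 0
                    ):
                        shell.add((i, j, k))
                        break
    return core, shell


def steric_by_enumeration(counts, origin, spacing, receptor_points,
                          region_cells):
    """Count region cells holding >= 1 receptor atom, cell by cell."""
    score = 0
    pts = np.asarray(receptor_points, dtype=float)
    for (i, j, k) in region_cells:
        lo = np.asarray(origin) + np.array([i, j, k]) * spacing
        hi = lo + spacing
        inside = ((pts >= lo) & (pts < hi)).all(axis=1)
        if inside.any():
            score += 1
    return score


def ef_by_counting(ids, scores, labels, fraction, lower_better=True):
    """Concentration-form EF from an explicitly sorted list."""
    order = sorted(
        range(len(ids)),
        key=lambda i: (scores[i] if lower_better else -scores[i], ids[i]),
    )
    n = max(1, math.floor(fraction * len(ids)))
    a = sum(1 for i in order[:n] if labels[i])
    big_a = sum(map(bool, labels))
    return (a / n) / (big_a / len(ids))


def auc_by_pairs(scores, labels, lower_better=True):
    """AUC as the fraction of (active, decoy) pairs won, ties half."""
    goodness = np.asarray(scores, dtype=float)
    if lower_better:
        goodness = -goodness
    act = goodness[np.asarray(labels, bool)]
    dec = goodness[~np.asarray(labels, bool)]
    wins = (act[:, None] > dec[None, :]).sum()
    ties = (act[:, None] == dec[None, :]).sum()
    return (wins + 0.5 * ties) / (len(act) * len(dec))


def midranks(values_badness):
    """1-based average ranks, small-is-best, computed by counting."""
    v = np.asarray(values_badness, dtype=float)
    ranks = np.empty(len(v))
    for i, x in enumerate(v):
        less = (v < x).sum()
        equal = (v == x).sum()
        ranks[i] = less + (equal + 1) / 2
    return ranks


def bedroc_by_formula(scores, labels, alpha=20.0, lower_better=True):
    """Truchon-Bayly BEDROC evaluated term by term from counted ranks."""
    badness = np.asarray(scores, dtype=float)
    if not lower_better:
        badness = -badness
    labels = np.asarray(labels, bool)
    n = len(badness)
    big_a = labels.sum()
    ra = big_a / n
    r = midranks(badness)[labels]
    rie = sum(math.exp(-alpha * ri / n) for ri in r) / (
        ra * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1)
    )
    scale = ra * math.sinh(alpha / 2) / (
        math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
    )
    return rie * scale + 1 / (1 - math.exp(alpha * (1 - ra)))


def pearson_by_hand(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float((cx * cy).sum() / math.sqrt((cx**2).sum() * (cy**2).sum()))
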