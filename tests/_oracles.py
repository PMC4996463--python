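"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain nested loops / dense linear algebra with
no shared code with the package, so agreement is meaningful.
"""

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
UNIQUE_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def brute_cooccurrence(levels, roi, n_levels):
    """Ordered-pair counts over all 26 neighbor offsets, normalized."""
    counts = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not roi[i, j, k]:
                    continue
                for dx, dy, dz in ALL_26:
                    a, b, c = i + dx, j + dy, k + dz
                    if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and roi[a, b, c]:
                        counts[levels[i, j, k] - 1, levels[a, b, c] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_rlm(levels, roi, n_levels, directions=UNIQUE_13):
    """Run-length counts by walking every line voxel by voxel."""
    runs = []  # (level, length)
    nx, ny, nz = levels.shape

    def inside(i, j, k):
        return 0 <= i < nx and 0 <= j < ny and 0 <= k < nz

    for d in directions:
        dx, dy, dz = d
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if not roi[i, j, k]:
                        continue
                    pi, pj, pk = i - dx, j - dy, k - dz
                    # run start: predecessor absent, out of ROI, or different level
                    if (
                        inside(pi, pj, pk)
                        and roi[pi, pj, pk]
                        and levels[pi, pj, pk] == levels[i, j, k]
                    ):
                        continue
                    length = 1
                    ci, cj, ck = i + dx, j + dy, k + dz
                    while (
                        inside(ci, cj, ck)
                        and roi[ci, cj, ck]
                        and levels[ci, cj, ck] == levels[i, j, k]
                    ):
                        length += 1
                        ci, cj, ck = ci + dx, cj + dy, ck + dz
                    runs.append((levels[i, j, k], length))
    if not runs:
        return np.zeros((n_levels, 1)), 0
    max_len = max(length for _, length in runs)
    rlm = np.zeros((n_levels, max_len))
    for lev, length in runs:
        rlm[lev - 1, length - 1] += 1
    return rlm, len(runs)


def brute_texture_features(levels, roi, n_levels):
    """All 16 measures straight from the printed formulas."""
    cm = brute_cooccurrence(levels, roi, n_levels)
    rlm, nr = brute_rlm(levels, roi, n_levels)
    n = n_levels
    out = {}
    ent = 0.0
    hom = con = dis = uni = 0.0
    for i in range(n):
        for j in range(n):
            p = cm[i, j]
            if p > 0:
                ent -= p * np.log(p)
            hom += p / (1 + (i - j) ** 2)
            con += p * (i - j) ** 2
            dis += p * abs(i - j)
            uni += p * p
    out.update(entropy=ent, homogeneity=hom, contrast=con, dissimilarity=dis, uniformity=uni)
    mx = rlm.shape[1]
    acc = dict(lre=0.0, sre=0.0, lgre=0.0, hgre=0.0, srlge=0.0, srhge=0.0,
               lrlge=0.0, lrhge=0.0)
    voxel_runs = 0.0
    for i in range(1, n + 1):
        for j in range(1, mx + 1):
            r = rlm[i - 1, j - 1]
            acc["lre"] += r * j**2
            acc["sre"] += r / j**2
            acc["lgre"] += r / i**2
            acc["hgre"] += r * i**2
            acc["srlge"] += r / (i**2 * j**2)
            acc["srhge"] += r * i**2 / j**2
            acc["lrlge"] += r * j**2 / i**2
            acc["lrhge"] += r * i**2 * j**2
            voxel_runs += r * j
    for k, v in acc.items():
        out[k] = v / nr
    out["glnu"] = sum(rlm[i].sum() ** 2 for i in range(n)) / nr
    out["rlnu"] = sum(rlm[:, j].sum() ** 2 for j in range(mx)) / nr
    out["rpc"] = nr / voxel_runs
    return out


def brute_min_distances(points_a, points_b):
    """Pooled min distances: a->b for every a, b->a for every b."""
    d = cdist(points_a, points_b)
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


def brute_max_diameter(points):
    return cdist(points, points).max()


def brute_logrank_p(times, events, group_b):
    """Textbook O-E / hypergeometric-variance log-rank, looped over times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    group_b = np.asarray(group_b, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_b = (at_risk & group_b).sum()
        d = (events & (times == t)).sum()
        d_b = (events & (times == t) & group_b).sum()
        o_minus_e += d_b - d * n_b / n
        if n > 1:
            var += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    if var <= 0:
        return 1.0
    return float(stats.chi2.sf(o_minus_e**2 / var, df=1))


def brute_cox_loghr(times, events, x, grid=None):
    """Argmax of the Breslow partial log-likelihood on a dense beta grid."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    if grid is None:
        grid = np.linspace(-5, 5, 20001)

    def loglik(beta):
        ll = 0.0
        for t in np.unique(times[events]):
            dead = events & (times == t)
            at_risk = times >= t
            ll += beta * x[dead].sum() - dead.sum() * np.log(
                np.exp(beta * x[at_risk]).sum()
            )
        return ll

    vals = np.array([loglik(b) for b in grid])
    return grid[np.argmax(vals)]
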