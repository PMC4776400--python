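"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions, deliberately sharing no
code with the package: naive double loops, explicit normal equations,
BFS flood fill, lattice enumeration.
"""

from collections import deque

import numpy as np


def sampen_bruteforce(x, m, r_abs):
    """O(N^2) sample entropy by direct pair enumeration."""
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r_abs:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r_abs:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def pooled_t_oracle(a, b):
    """Two-sample pooled-variance t and two-sided p from the textbook
    formulas (explicit sums, scipy only for the t CDF)."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    s2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(s2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def pearson_oracle(x, y):
    """r and two-tailed p from the explicit product-moment formula."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p


def rankdata_oracle(x):
    """Average ranks, written out longhand."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank both variables, then the Pearson formula."""
    return pearson_oracle(rankdata_oracle(x), rankdata_oracle(y))[0]


def bh_oracle(p):
    """Benjamini-Hochberg step-up q values by direct enumeration."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        q[idx] = val
        prev = val
    return q


def flood_fill_clusters(mask, connectivity=6):
    """Connected components by BFS; returns a label array (arbitrary
    label order) and the list of component sizes."""
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    labels = np.zeros(mask.shape, dtype=int)
    sizes = []
    current = 0
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if labels[idx]:
            continue
        current += 1
        queue = deque([idx])
        labels[idx] = current
        size = 0
        while queue:
            p = queue.popleft()
            size += 1
            for o in offsets:
                q = tuple(np.add(p, o))
                if all(0 <= q[i] < mask.shape[i] for i in range(3)):
                    if mask[q] and not labels[q]:
                        labels[q] = current
                        queue.append(q)
        sizes.append(size)
    return labels, sizes


def lattice_ball_count(radius_mm, voxel_size):
    """Number of lattice offsets with ||offset * voxel_size|| <= radius."""
    bounds = [int(np.floor(radius_mm / v)) for v in voxel_size]
    count = 0
    for dx in range(-bounds[0], bounds[0] + 1):
        for dy in range(-bounds[1], bounds[1] + 1):
            for dz in range(-bounds[2], bounds[2] + 1):
                d2 = (
                    (dx * voxel_size[0]) ** 2
                    + (dy * voxel_size[1]) ** 2
                    + (dz * voxel_size[2]) ** 2
                )
                if d2 <= radius_mm**2:
                    count += 1
    return count


def surround_subtract_oracle(frames, first_label="tag"):
    """Sliding-interpolation control-tag differencing, re-derived.

    frames: 1-D array of alternating frames.  Returns one difference per
    original pair, control minus interpolated tag (positive for perfused).
    """
    n = len(frames)
    is_control = [
        (i % 2 == 0) == (first_label == "control") for i in range(n)
    ]
    per_frame = np.empty(n)
    for i in range(n):
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < n]
        interp = np.mean([frames[j] for j in neighbors])
        if is_control[i]:
            per_frame[i] = frames[i] - interp
        else:
            per_frame[i] = interp - frames[i]
    return 0.5 * (per_frame[0::2] + per_frame[1::2])
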