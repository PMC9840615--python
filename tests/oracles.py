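"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def shoelace(vertices):
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def gift_wrap_hull_area(points):
    """Convex hull by gift wrapping + shoelace area; O(n·h) brute force."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0
                             and np.linalg.norm(pts[j] - pts[cur])
                             > np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    if len(hull) < 3:
        return 0.0
    return shoelace(pts[hull])


def pearson_oracle(x, y):
    """Closed-form covariance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
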