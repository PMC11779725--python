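"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, exhaustive enumeration) and shares no code with the package's
own measurement path.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# connected components by flood fill


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """8- (or 4-) connected components as sets of (row, col) pixels."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    if connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp = set()
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                comp.add((y, x))
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
            comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# marching-squares contour walk (level 0.5 on a binary grid)

# Segment table for one 2x2 cell with corners (tl, tr, bl, br) in {0,1}.
# Vertices sit at edge midpoints of the cell at (row, col) offsets:
#   top (0, .5), bottom (1, .5), left (.5, 0), right (.5, 1).
# Saddle cases follow the convention that the below-level phase is fully
# (8-) connected, so diagonal foreground corners are separated.
_T, _B, _L, _R = (0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)
_CASES: dict[tuple[int, int, int, int], list[tuple]] = {
    (0, 0, 0, 0): [],
    (1, 0, 0, 0): [(_L, _T)],
    (0, 1, 0, 0): [(_T, _R)],
    (0, 0, 1, 0): [(_B, _L)],
    (0, 0, 0, 1): [(_R, _B)],
    (1, 1, 0, 0): [(_L, _R)],
    (0, 0, 1, 1): [(_R, _L)],
    (1, 0, 1, 0): [(_B, _T)],
    (0, 1, 0, 1): [(_T, _B)],
    (1, 1, 1, 0): [(_B, _R)],
    (1, 1, 0, 1): [(_L, _B)],
    (1, 0, 1, 1): [(_R, _T)],
    (0, 1, 1, 1): [(_T, _L)],
    (1, 1, 1, 1): [],
    (1, 0, 0, 1): [(_L, _T), (_R, _B)],  # saddle: separate the diagonal 1s
    (0, 1, 1, 0): [(_T, _R), (_B, _L)],
}


def _ms_segments(mask: np.ndarray) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    g = np.pad(np.asarray(mask, bool).astype(int), 1)
    segs = []
    h, w = g.shape
    for i in range(h - 1):
        for j in range(w - 1):
            key = (g[i, j], g[i, j + 1], g[i + 1, j], g[i + 1, j + 1])
            for (ar, ac), (br, bc) in _CASES[key]:
                segs.append(((i + ar - 1, j + ac - 1), (i + br - 1, j + bc - 1)))
    return segs


def _chain_loops(segs) -> list[list[tuple[float, float]]]:
    adj: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for a, b in segs:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    unused = {frozenset(s) for s in segs}
    loops = []
    while unused:
        a, b = tuple(next(iter(unused)))
        loop = [a, b]
        unused.discard(frozenset((a, b)))
        while loop[-1] != loop[0]:
            cur = loop[-1]
            nxt = next(n for n in adj[cur] if frozenset((cur, n)) in unused)
            unused.discard(frozenset((cur, nxt)))
            loop.append(nxt)
        loops.append(loop[:-1])
    return loops


def contour_walk_perimeter(mask: np.ndarray, smooth_window: int = 5) -> float:
    """Perimeter of the outer level-0.5 contour via an independent
    marching-squares walk, smoothed with the same circular moving
    average convention as the measurement path."""
    loops = _chain_loops(_ms_segments(mask))
    if not loops:
        raise ValueError("empty mask")

    def shoelace(lp):
        a = 0.0
        for (y0, x0), (y1, x1) in zip(lp, lp[1:] + lp[:1]):
            a += x0 * y1 - x1 * y0
        return 0.5 * a

    outer = max(loops, key=lambda lp: (abs(shoelace(lp)), len(lp), tuple(-c for c in min(lp))))
    pts = [np.array(p) for p in outer]
    n = len(pts)
    if smooth_window > 1 and n > smooth_window:
        half = smooth_window // 2
        pts = [sum(pts[(i + d) % n] for d in range(-half, half + 1)) / smooth_window for i in range(n)]
    total = 0.0
    for i in range(n):
        d = pts[(i + 1) % n] - pts[i]
        total += math.hypot(d[0], d[1])
    return total


# ---------------------------------------------------------------------------
# detection metrics


def greedy_match_oracle(pred_boxes, truth_boxes, iou_thr=0.5):
    """(tp, ranked) recomputed with plain loops: descending confidence,
    best-IoU unconsumed truth, ties to the lower truth index."""

    def iou(a, b):
        ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
        iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
        inter = ix * iy
        return inter / (a.area + b.area - inter) if inter else 0.0

    conf = lambda b: b.confidence if b.confidence is not None else 1.0
    order = sorted(range(len(pred_boxes)), key=lambda i: (-conf(pred_boxes[i]), i))
    taken = set()
    ranked = []
    for i in order:
        cands = [(iou(pred_boxes[i], t), j) for j, t in enumerate(truth_boxes) if j not in taken]
        cands = [(v, j) for v, j in cands if v >= iou_thr]
        if cands:
            v, j = max(cands, key=lambda c: (c[0], -c[1]))
            taken.add(j)
            ranked.append((conf(pred_boxes[i]), True))
        else:
            ranked.append((conf(pred_boxes[i]), False))
    return sum(m for _, m in ranked), ranked


def ap_oracle(ranked, n_truth):
    """All-point AP from the precision-recall staircase, by enumeration."""
    if n_truth == 0:
        return 1.0 if not ranked else 0.0
    ranked = sorted(ranked, key=lambda t: -t[0])
    pr = []
    tp = 0
    for k, (_, m) in enumerate(ranked, 1):
        tp += m
        pr.append((tp / n_truth, tp / k))
    ap = 0.0
    prev = 0.0
    for r, _ in pr:
        if r > prev:
            best = max(p for rr, p in pr if rr >= r)
            ap += (r - prev) * best
            prev = r
    return ap


# ---------------------------------------------------------------------------
# misc


def point_in_polygon_even_odd(px: float, py: float, poly) -> bool:
    """Classic even-odd ray crossing test for a single point."""
    inside = False
    n = len(poly)
    for k in range(n):
        (ax, ay), (bx, by) = poly[k], poly[(k + 1) % n]
        if (ay > py) != (by > py):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < xint:
                inside = not inside
    return inside


def two_pass_mean_sd(values) -> tuple[float, float]:
    """Two-pass sample mean and SD (ddof=1; SD 0 for singleton)."""
    vals = list(map(float, values))
    n = len(vals)
    mean = sum(vals) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var)


def moment_eccentricity_oracle(pixels) -> float:
    """Eccentricity from explicit second-central-moment loops, using the
    same per-pixel 1/12 variance convention as the measurement path."""
    xs = [p[1] for p in pixels]
    ys = [p[0] for p in pixels]
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    mxx = sum((x - mx) ** 2 for x in xs) / n + 1 / 12
    myy = sum((y - my) ** 2 for y in ys) / n + 1 / 12
    mxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    tr = mxx + myy
    det = mxx * myy - mxy * mxy
    disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
    l1, l2 = tr / 2 + disc, tr / 2 - disc
    return math.sqrt(max(1 - l2 / l1, 0.0)) if l1 > 0 else 0.0
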