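"""Independent brute-force oracles used to verify the implementation.

Deliberately naive: pure-Python loops, flood fill, all-pairs searches.
They share no code with the package's own (vectorized / library-backed)
paths.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def loop_max_projection(planes: np.ndarray) -> np.ndarray:
    """Per-pixel max over the leading axis, by explicit looping."""
    ny, nx = planes.shape[-2:]
    flat = planes.reshape(-1, ny, nx)
    out = np.empty((ny, nx), dtype=flat.dtype)
    for i in range(ny):
        for j in range(nx):
            best = flat[0, i, j]
            for k in range(1, flat.shape[0]):
                if flat[k, i, j] > best:
                    best = flat[k, i, j]
            out[i, j] = best
    return out


def loop_threshold(image: np.ndarray, threshold: float) -> np.ndarray:
    ny, nx = image.shape
    out = np.zeros((ny, nx), dtype=bool)
    for i in range(ny):
        for j in range(nx):
            out[i, j] = image[i, j] > threshold
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """Connected components by breadth-first flood fill.

    Returns (labels, list of (area, sorted pixel set)) with labels in
    scan order.
    """
    if connectivity == 4:
        neighbors = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neighbors = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                     if (dy, dx) != (0, 0)]
    ny, nx = mask.shape
    labels = np.zeros((ny, nx), dtype=int)
    comps = []
    next_label = 0
    for i in range(ny):
        for j in range(nx):
            if mask[i, j] and labels[i, j] == 0:
                next_label += 1
                queue = deque([(i, j)])
                labels[i, j] = next_label
                pixels = []
                while queue:
                    y, x = queue.popleft()
                    pixels.append((y, x))
                    for dy, dx in neighbors:
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < ny and 0 <= xx < nx and mask[yy, xx] \
                                and labels[yy, xx] == 0:
                            labels[yy, xx] = next_label
                            queue.append((yy, xx))
                comps.append((len(pixels), sorted(pixels)))
    return labels, comps


def brute_force_distance_map(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """All-pairs nearest-foreground Euclidean distance."""
    fg = np.argwhere(mask)
    ny, nx = mask.shape
    out = np.full((ny, nx), np.inf)
    for i in range(ny):
        for j in range(nx):
            for fy, fx in fg:
                d = np.hypot(i - fy, j - fx) * pixel_size_um
                if d < out[i, j]:
                    out[i, j] = d
    return out


def dilate_then_erode(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Explicit two-step closing on a zero-padded canvas."""
    offsets = [(dy - selem.shape[0] // 2, dx - selem.shape[1] // 2)
               for dy in range(selem.shape[0]) for dx in range(selem.shape[1])
               if selem[dy, dx]]
    pad = 2
    canvas = np.pad(mask, pad, constant_values=False)
    ny, nx = canvas.shape
    dilated = np.zeros_like(canvas)
    for i in range(ny):
        for j in range(nx):
            if canvas[i, j]:
                for dy, dx in offsets:
                    yy, xx = i + dy, j + dx
                    if 0 <= yy < ny and 0 <= xx < nx:
                        dilated[yy, xx] = True
    eroded = np.zeros_like(canvas)
    for i in range(ny):
        for j in range(nx):
            ok = True
            for dy, dx in offsets:
                yy, xx = i + dy, j + dx
                if not (0 <= yy < ny and 0 <= xx < nx and dilated[yy, xx]):
                    ok = False
                    break
            eroded[i, j] = ok
    return eroded[pad:-pad, pad:-pad]


def point_in_polygon(y: float, x: float, verts: np.ndarray) -> bool:
    """Scalar even-odd crossing test (ray toward -x), half-open in y."""
    inside = False
    n = len(verts)
    for k in range(n):
        y1, x1 = verts[k]
        y2, x2 = verts[(k + 1) % n]
        if y1 == y2:
            continue
        if (y1 > y) != (y2 > y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_at:
                inside = not inside
    return inside


def student_t_p_value(t: float, df: int) -> float:
    """Two-tailed p from the incomplete-beta relation, not scipy.stats.t."""
    from scipy.special import betainc

    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def pooled_t_statistic(a, b):
    """Textbook pooled two-sample t, computed stepwise."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / (sp2 * (1.0 / na + 1.0 / nb)) ** 0.5
    return t, df
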