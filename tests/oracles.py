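"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (BFS, exhaustive enumeration, grid
search) and shares no code path with the package.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(binary: np.ndarray, eight_connected: bool = True) -> np.ndarray:
    """BFS connected-component labeling of a binary image."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    if eight_connected:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    next_label = 0
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            if binary[r, c] and labels[r, c] == 0:
                next_label += 1
                queue = deque([(r, c)])
                labels[r, c] = next_label
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < binary.shape[0]
                            and 0 <= nc < binary.shape[1]
                            and binary[nr, nc]
                            and labels[nr, nc] == 0
                        ):
                            labels[nr, nc] = next_label
                            queue.append((nr, nc))
    return labels


def brute_force_otsu(image: np.ndarray) -> int:
    """Exhaustive inter-class-variance maximization over all 65,536 gray levels."""
    img = np.asarray(image, dtype=np.int64).ravel()
    hist = np.bincount(img, minlength=65536).astype(float)
    total = hist.sum()
    best_t, best_var = 0, -1.0
    levels = np.arange(65536, dtype=float)
    for t in range(65536):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * levels[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * levels[t + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def exhaustive_gated_assignment(
    pos_a: np.ndarray, pos_b: np.ndarray, gate: float
) -> tuple[int, float]:
    """Best one-to-one gated assignment by full enumeration.

    Objective: maximize the number of matched pairs with distance <= gate,
    then minimize the total matched distance.  Returns (n_matched, cost).
    """
    pos_a = np.asarray(pos_a, float).reshape(-1, 2)
    pos_b = np.asarray(pos_b, float).reshape(-1, 2)
    na, nb = len(pos_a), len(pos_b)
    dist = np.hypot(pos_a[:, None, 0] - pos_b[None, :, 0], pos_a[:, None, 1] - pos_b[None, :, 1])
    best = (0, 0.0)

    def rec(i: int, used: int, count: int, cost: float) -> None:
        nonlocal best
        if i == na:
            if count > best[0] or (count == best[0] and cost < best[1] - 1e-12):
                best = (count, cost)
            return
        rec(i + 1, used, count, cost)  # leave a_i unmatched
        for j in range(nb):
            if not used & (1 << j) and dist[i, j] <= gate:
                rec(i + 1, used | (1 << j), count + 1, cost + dist[i, j])

    rec(0, 0, 0, 0.0)
    return best


def ecdf_sup_distance_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Max |ECDF_a - ECDF_b| by explicit evaluation at every breakpoint."""
    a, b = np.sort(np.asarray(a, float)), np.sort(np.asarray(b, float))
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.sum(a <= x) / len(a)
        fb = np.sum(b <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best


def grid_search_exp_fit(
    t_min: np.ndarray, y: np.ndarray, k_lo: float = 1e-4, k_hi: float = 10.0, n_grid: int = 400
) -> tuple[float, float, float]:
    """Independent single-exponential fitter: profile k on a log grid.

    For fixed k, y = A exp(-k t) + y0 is linear in (A, y0), solved exactly;
    the best grid k is refined by golden-section search on the profiled SSE.
    Returns (A, k, y0).
    """

    def sse_and_lin(k: float) -> tuple[float, float, float]:
        x = np.exp(-k * t_min)
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), float(coef[0]), float(coef[1])

    grid = np.geomspace(k_lo, k_hi, n_grid)
    sses = [sse_and_lin(k)[0] for k in grid]
    i = int(np.argmin(sses))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(200):
        if sse_and_lin(c)[0] < sse_and_lin(d)[0]:
            b = d
        else:
            a = c
        c, d = b - phi * (b - a), a + phi * (b - a)
    k_best = (a + b) / 2.0
    _, amp, y0 = sse_and_lin(k_best)
    return amp, k_best, y0


def disk_area_px(radius_um: float, pixel_size: float) -> float:
    """Analytic area of a cell disk in pixel units."""
    return np.pi * (radius_um / pixel_size) ** 2
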