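"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the package itself.
"""

import numpy as np


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass textbook Pearson correlation."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def correlation_matrix_brute(frames: np.ndarray) -> np.ndarray:
    """Frame-pairwise Pearson matrix with explicit loops."""
    t = frames.shape[0]
    out = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            r = pearson_brute(frames[i], frames[j])
            out[i, j] = out[j, i] = r
    return out


def bh_stepup_brute(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, textbook step-up."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def perimeter_sum(vertices: np.ndarray) -> float:
    d = np.roll(vertices, -1, axis=0) - vertices
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def star_polygon(rng: np.random.Generator, n_vertices: int = 24) -> np.ndarray:
    """Random simple (star-shaped) polygon around the origin."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # enforce distinct angles so edges cannot be collinear duplicates
    theta += np.linspace(0, 1e-6, n_vertices)
    r = rng.uniform(0.5, 2.0, n_vertices)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
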