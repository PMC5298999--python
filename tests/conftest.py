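"""Shared fixtures and independent numerical oracles.

The oracles here (golden-spiral surface sampler, brute-force shortest-path
shelling, exhaustive signed-rank null) deliberately share no code with the
implementation paths they check.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest

from igvor import fixtures as fx
from igvor.sam_voronoi import extract_interface


# --- independent oracles ---------------------------------------------------

def spiral_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform directions (surface-sampling oracle)."""
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    phi = math.pi * (1 + 5 ** 0.5) * i
    s = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def shrake_rupley_areas(centers: np.ndarray, radii: np.ndarray,
                        n_points: int = 50_000) -> np.ndarray:
    """Numerical per-atom exposed areas by surface-point counting."""
    dirs = spiral_points(n_points)
    out = np.empty(len(centers))
    for i in range(len(centers)):
        pts = centers[i] + radii[i] * dirs
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(centers)):
            if j != i:
                exposed &= ((pts - centers[j]) ** 2).sum(1) > radii[j] ** 2
        out[i] = 4 * math.pi * radii[i] ** 2 * exposed.mean()
    return out


def brute_force_shelling(patch: set, graph: dict, boundary: set) -> dict:
    """Per-atom shortest hop distance to the rim, by exhaustive relaxation."""
    INF = 10 ** 9
    dist = {a: (1 if a in boundary else INF) for a in patch}
    for _ in range(len(patch)):
        for a in patch:
            for b in graph.get(a, ()):
                if b in patch and dist[b] + 1 < dist[a]:
                    dist[a] = dist[b] + 1
    return {a: (1 if d >= INF else d) for a, d in dist.items()}


def exact_wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p-value by enumerating all 2^n sign patterns.

    Zero differences must already be removed; assumes untied |d|.
    """
    d = np.asarray(diffs, float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2 ** n


# --- shared structural fixtures --------------------------------------------

@pytest.fixture(scope="session")
def slab():
    """Slab Ig-Ag complex with its Voronoi interface."""
    f = fx.make_slab_complex()
    s = f.structure()
    return s, extract_interface(s)


@pytest.fixture(scope="session")
def slab_water():
    f = fx.make_slab_complex(with_water=True)
    s = f.structure()
    return s, extract_interface(s)
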