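"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, BFS flood fill) that
share no code with the package's vectorized/library-based paths.
"""

from __future__ import annotations

import math
from collections import deque


def agatston_oracle(hu, spacing, heart, threshold=130.0, min_area_mm2=1.0):
    """Agatston score by BFS flood fill and explicit per-slice loops.

    hu: nested-indexable 3-D array (z, y, x); spacing: (dx, dy, dz).
    26-connected components of (hu >= threshold) & heart; a component is
    kept if any single-slice area reaches ``min_area_mm2``; each kept
    component contributes, per slice, area * weight(max HU of that slice).
    """
    nz = len(hu)
    ny = len(hu[0])
    nx = len(hu[0][0])
    dx, dy, dz = spacing
    pixel_area = dx * dy
    seen = [[[False] * nx for _ in range(ny)] for _ in range(nz)]

    def eligible(z, y, x):
        return bool(heart[z][y][x]) and hu[z][y][x] >= threshold

    total = 0.0
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if seen[z0][y0][x0] or not eligible(z0, y0, x0):
                    continue
                # flood fill one 26-connected component
                comp = []
                queue = deque([(z0, y0, x0)])
                seen[z0][y0][x0] = True
                while queue:
                    z, y, x = queue.popleft()
                    comp.append((z, y, x))
                    for az in (-1, 0, 1):
                        for ay in (-1, 0, 1):
                            for ax in (-1, 0, 1):
                                if az == ay == ax == 0:
                                    continue
                                z2, y2, x2 = z + az, y + ay, x + ax
                                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                                    if not seen[z2][y2][x2] and eligible(z2, y2, x2):
                                        seen[z2][y2][x2] = True
                                        queue.append((z2, y2, x2))
                # per-slice area and max HU
                slices = {}
                for z, y, x in comp:
                    cnt, mx = slices.get(z, (0, -10000.0))
                    slices[z] = (cnt + 1, max(mx, float(hu[z][y][x])))
                if all(cnt * pixel_area < min_area_mm2 for cnt, _ in slices.values()):
                    continue
                for cnt, mx in slices.values():
                    if mx >= 400:
                        w = 4
                    elif mx >= 300:
                        w = 3
                    elif mx >= 200:
                        w = 2
                    elif mx >= threshold:
                        w = 1
                    else:
                        w = 0
                    total += cnt * pixel_area * w
    return total


def weighted_kappa_oracle(cats_a, cats_b, k=5):
    """Linearly weighted kappa by explicit double loops over the k x k table."""
    n = len(cats_a)
    table = [[0.0] * k for _ in range(k)]
    for a, b in zip(cats_a, cats_b):
        table[a - 1][b - 1] += 1.0 / n
    row = [sum(table[i][j] for j in range(k)) for i in range(k)]
    col = [sum(table[i][j] for i in range(k)) for j in range(k)]
    po = 0.0
    pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1.0 - abs(i - j) / (k - 1)
            po += w * table[i][j]
            pe += w * row[i] * col[j]
    if 1.0 - pe == 0.0:
        return None
    return (po - pe) / (1.0 - pe)


def pseudomass_oracle(hu, inserted_mask, spacing):
    """Sum of HU over masked voxels times voxel volume, by explicit loops."""
    dx, dy, dz = spacing
    total = 0.0
    for z in range(len(hu)):
        for y in range(len(hu[0])):
            for x in range(len(hu[0][0])):
                if inserted_mask[z][y][x]:
                    total += max(float(hu[z][y][x]), 0.0) * dx * dy * dz
    return total
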