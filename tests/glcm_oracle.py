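"""Independent brute-force co-occurrence oracle.

Enumerates every in-mask voxel pair for every unit offset with plain Python
loops and computes the nine features directly from the pair-count dictionary.
Deliberately shares no code with the package's vectorized GLCM engine.
"""

import math
from itertools import product


def brute_force_glcm(levels, mask, n_levels=8):
    """Direction-averaged feature dict via exhaustive pair enumeration."""
    nx, ny, nz = levels.shape
    directions = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    per_direction = []
    for dx, dy, dz in directions:
        counts = {}
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        continue
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        key = (int(levels[x, y, z]), int(levels[u, v, w]))
                        counts[key] = counts.get(key, 0) + 1
        if counts:
            per_direction.append(_features(counts))
    if not per_direction:
        raise ValueError("no valid pairs")
    names = per_direction[0].keys()
    return {n: sum(f[n] for f in per_direction) / len(per_direction) for n in names}


def _features(counts):
    total = sum(counts.values())
    p = {ij: c / total for ij, c in counts.items()}
    px, py = {}, {}
    for (i, j), q in p.items():
        px[i] = px.get(i, 0.0) + q
        py[j] = py.get(j, 0.0) + q
    mu_x = sum(i * q for i, q in px.items())
    mu_y = sum(j * q for j, q in py.items())
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * q for i, q in px.items()))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * q for j, q in py.items()))
    mu = (mu_x + mu_y) / 2.0

    out = {
        "Energy": sum(q**2 for q in p.values()),
        "Contrast": sum(abs(i - j) * q for (i, j), q in p.items()),
        "Variance": sum((i - mu) ** 2 * q for (i, _), q in p.items()),
        "Homogeneity": sum(q / (1 + abs(i - j)) for (i, j), q in p.items()),
        "SumMean": 0.5 * sum((i + j) * q for (i, j), q in p.items()),
        "Entropy": -sum(q * math.log(q) for q in p.values() if q > 0),
        "Inertia": sum((i - j) ** 2 * q for (i, j), q in p.items()),
        "ClusterShade": sum((i + j - mu_x - mu_y) ** 3 * q for (i, j), q in p.items()),
    }
    if sd_x * sd_y > 0:
        out["Correlation"] = sum(
            (i - mu_x) * (j - mu_y) * q for (i, j), q in p.items()
        ) / (sd_x * sd_y)
    else:
        out["Correlation"] = 0.0
    return out
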