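"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the quaternion
eigenvalue method for minimum RMSD, closed-form sphere/cap areas, and
a brute-force reflection enumerator.
"""

from __future__ import annotations

import math

import numpy as np


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD via the largest eigenvalue of the quaternion key matrix."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    S = P.T @ Q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    e = (P * P).sum() + (Q * Q).sum() - 2.0 * lam_max
    return math.sqrt(max(e, 0.0) / len(P))


def sphere_area(radius: float) -> float:
    return 4.0 * math.pi * radius * radius


def two_sphere_accessible_area(radius: float, center_distance: float) -> float:
    """Exposed area of one of two equal spheres with overlapping surfaces.

    The buried part of each sphere is a spherical cap of height
    h = R − d/2; accessible area = 4πR² − 2πRh.
    """
    if center_distance >= 2 * radius:
        return sphere_area(radius)
    h = radius - center_distance / 2.0
    return sphere_area(radius) - 2.0 * math.pi * radius * h


def brute_force_unique_reflections(
    a: float, b: float, c: float, d_min: float, d_max: float
) -> int:
    """Friedel-merged reflection count for a primitive orthorhombic cell.

    Plain triple loop with a set of Friedel-canonical tuples; no metric
    tensor, no vectorisation.
    """
    unique: set[tuple[int, int, int]] = set()
    hmax = int(math.ceil(a / d_min)) + 1
    kmax = int(math.ceil(b / d_min)) + 1
    lmax = int(math.ceil(c / d_min)) + 1
    for h in range(-hmax, hmax + 1):
        for k in range(-kmax, kmax + 1):
            for l in range(-lmax, lmax + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                inv_d2 = (h / a) ** 2 + (k / b) ** 2 + (l / c) ** 2
                d = 1.0 / math.sqrt(inv_d2)
                if d_min <= d <= d_max:
                    unique.add(max((h, k, l), (-h, -k, -l)))
    return len(unique)
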