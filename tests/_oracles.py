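"""Independent brute-force oracles, deliberately coded from scratch with
plain Python scalars (no shared code paths with the package)."""

from __future__ import annotations

import math
from statistics import NormalDist


def clam_oracle(y1: list[int], y2: list[int], K: float, alpha: float,
                coverage_limit: int) -> list[str]:
    """Scalar re-implementation of the supermajority decision rules."""
    N1, N2 = sum(y1), sum(y2)
    f1 = sum(1 for v in y1 if v == 1)
    f2 = sum(1 for v in y2 if v == 1)
    cov1 = 1.0 - f1 / N1
    cov2 = 1.0 - f2 / N2
    zcrit = NormalDist().inv_cdf(1.0 - alpha)

    def adj(v, N, cov):
        raw = v / N
        return cov * raw if v < coverage_limit else raw

    def rejects(pa, pb, c, ya, yb, Na, Nb):
        var = ya / Na ** 2 + c * c * yb / Nb ** 2
        if var <= 0.0:
            return False
        return (pa - c * pb) / math.sqrt(var) > zcrit

    out = []
    c_hi = K / (1.0 - K)
    c_lo = (1.0 - K) / K
    for a, b in zip(y1, y2):
        p1 = adj(a, N1, cov1)
        p2 = adj(b, N2, cov2)
        if rejects(p1, p2, c_hi, a, b, N1, N2):
            out.append("specialist_h1")
        elif rejects(p2, p1, c_hi, b, a, N2, N1):
            out.append("specialist_h2")
        elif rejects(p1, p2, c_lo, a, b, N1, N2) and \
                rejects(p2, p1, c_lo, b, a, N2, N1):
            out.append("generalist")
        else:
            out.append("too_rare")
    return out


def random_community(rng, n_species=None):
    """Counts with a mix of zeros, singletons and abundant species."""
    if n_species is None:
        n_species = int(rng.integers(4, 25))
    y1, y2 = [], []
    for _ in range(n_species):
        kind = rng.integers(0, 4)
        if kind == 0:
            a, b = int(rng.integers(0, 3)), int(rng.integers(0, 3))
        elif kind == 1:
            a, b = int(rng.integers(0, 60)), int(rng.integers(0, 4))
        elif kind == 2:
            a, b = int(rng.integers(0, 4)), int(rng.integers(0, 60))
        else:
            a, b = int(rng.integers(5, 200)), int(rng.integers(5, 200))
        y1.append(a)
        y2.append(b)
    if sum(y1) == 0:
        y1[0] = 1
    if sum(y2) == 0:
        y2[0] = 1
    return y1, y2
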