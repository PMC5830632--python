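"""CLAM habitat-affinity classification.

Species are classified from their total captures in two habitat pools —
here continuous primary forest (habitat 1) versus forest fragments plus
secondary forest (habitat 2) — into one of four categories: primary-forest
specialist, secondary/disturbed-forest specialist, habitat generalist, or
too rare to classify.  The decision rules are the supermajority multinomial
scheme: with specialization threshold K (default 2/3) a species is a
habitat-1 specialist when its relative abundance there exceeds
K/(1-K) times its relative abundance in habitat 2, tested one-sidedly at
level alpha with a normal approximation and Poisson count variances, on
coverage-adjusted relative abundances (the Good-Turing style correction
that discounts rare species' abundances by the estimated sample coverage).

For the downstream assemblage analysis the four categories collapse to two
functional groups: primary-forest specialists and too-rare species form the
"specialist" group; generalists and the (few) disturbed-forest specialists
form the "generalist" group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ClamInput",
    "ClamResult",
    "CATEGORIES",
    "coverage_adjusted_abundance",
    "classify_species",
    "collapse_groups",
    "clam_from_captures",
]

CATEGORIES = ("specialist_h1", "specialist_h2", "generalist", "too_rare")

#: Four-way category -> binary functional group.  Primary-forest specialists
#: and too-rare species are pooled conservatively; disturbed-forest
#: specialists are pooled with generalists.
COLLAPSE = {
    "specialist_h1": "specialist",
    "too_rare": "specialist",
    "generalist": "generalist",
    "specialist_h2": "generalist",
}


@dataclass
class ClamInput:
    """Per-species capture totals in the two habitat pools.

    K is the supermajority specialization threshold (must exceed 1/2),
    alpha the one-sided test level, coverage_limit the count below which a
    species' relative abundance is discounted by the habitat's estimated
    sample coverage.
    """

    species_ids: list[str]
    y1: np.ndarray
    y2: np.ndarray
    K: float = 2.0 / 3.0
    alpha: float = 0.01
    coverage_limit: int = 10

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=np.int64)
        self.y2 = np.asarray(self.y2, dtype=np.int64)
        if not (len(self.species_ids) == len(self.y1) == len(self.y2)):
            raise ValueError("species_ids, y1, y2 must have equal length")
        if np.any(self.y1 < 0) or np.any(self.y2 < 0):
            raise ValueError("counts must be non-negative")
        if not 0.5 < self.K < 1.0:
            raise ValueError("K must lie in (0.5, 1): supermajority rule")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.coverage_limit < 1:
            raise ValueError("coverage_limit must be a positive integer")


@dataclass
class ClamResult:
    """Four-way categories, collapsed groups and adjusted abundances."""

    species_ids: list[str]
    category: list[str]
    collapsed: list[str]
    pi1_hat: np.ndarray
    pi2_hat: np.ndarray
    y1: np.ndarray = field(default=None)
    y2: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species_id": self.species_ids,
            "y1": self.y1,
            "y2": self.y2,
            "p1_adj": self.pi1_hat,
            "p2_adj": self.pi2_hat,
            "category": self.category,
            "collapsed": self.collapsed,
        })

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.collapsed:
            out[c] = out.get(c, 0) + 1
        return out


def coverage_adjusted_abundance(counts: np.ndarray,
                                coverage_limit: int = 10) -> np.ndarray:
    """Coverage-adjusted relative abundances for one habitat.

    Sample coverage is estimated as ``C_hat = 1 - f1/N`` where ``f1`` is the
    number of singleton species and ``N`` the total count.  Species with
    fewer than ``coverage_limit`` individuals have their raw relative
    abundance ``y/N`` multiplied by ``C_hat``; abundant species keep ``y/N``.
    """
    y = np.asarray(counts, dtype=np.int64)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    N = int(y.sum())
    if N == 0:
        raise ValueError("habitat unsampled: total count is zero")
    f1 = int(np.sum(y == 1))
    c_hat = 1.0 - f1 / N
    p = y / N
    return np.where(y < coverage_limit, c_hat * p, p)


def _one_sided_reject(p_a: np.ndarray, p_b: np.ndarray, c: float,
                      y_a: np.ndarray, y_b: np.ndarray,
                      N_a: int, N_b: int, z_crit: float) -> np.ndarray:
    """Reject H0: p_a <= c * p_b, one-sided, normal approximation.

    The statistic is the adjusted-abundance difference ``p_a - c * p_b``
    with independent Poisson variances ``y_a/N_a^2 + c^2 * y_b/N_b^2``.
    Species with zero variance (no captures at all) never reject; ties at
    the critical boundary resolve to non-rejection (conservative).
    """
    var = y_a / N_a**2 + c**2 * y_b / N_b**2
    stat = p_a - c * p_b
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, stat / np.sqrt(var), -np.inf)
    return z > z_crit


def classify_species(inp: ClamInput) -> ClamResult:
    """Run the supermajority classification for every species.

    Decision order: habitat-1 specialist test, habitat-2 specialist test,
    then the generalist pair of tests (both relative abundances shown to be
    above the minority ratio (1-K)/K of the other); species rejecting none
    are too rare to classify.
    """
    N1 = int(inp.y1.sum())
    N2 = int(inp.y2.sum())
    if N1 == 0 or N2 == 0:
        raise ValueError("each habitat needs at least one capture overall")
    p1 = coverage_adjusted_abundance(inp.y1, inp.coverage_limit)
    p2 = coverage_adjusted_abundance(inp.y2, inp.coverage_limit)
    c_major = inp.K / (1.0 - inp.K)
    c_minor = (1.0 - inp.K) / inp.K
    z_crit = float(norm.ppf(1.0 - inp.alpha))

    spec1 = _one_sided_reject(p1, p2, c_major, inp.y1, inp.y2, N1, N2, z_crit)
    spec2 = _one_sided_reject(p2, p1, c_major, inp.y2, inp.y1, N2, N1, z_crit)
    gen_a = _one_sided_reject(p1, p2, c_minor, inp.y1, inp.y2, N1, N2, z_crit)
    gen_b = _one_sided_reject(p2, p1, c_minor, inp.y2, inp.y1, N2, N1, z_crit)

    category = []
    for i in range(len(inp.species_ids)):
        if spec1[i]:
            category.append("specialist_h1")
        elif spec2[i]:
            category.append("specialist_h2")
        elif gen_a[i] and gen_b[i]:
            category.append("generalist")
        else:
            category.append("too_rare")
    collapsed = [COLLAPSE[c] for c in category]
    return ClamResult(species_ids=list(inp.species_ids), category=category,
                      collapsed=collapsed, pi1_hat=p1, pi2_hat=p2,
                      y1=inp.y1.copy(), y2=inp.y2.copy())


def collapse_groups(result: ClamResult) -> dict[str, str]:
    """Map each species to its binary functional group."""
    return {s: COLLAPSE[c] for s, c in zip(result.species_ids, result.category)}


def clam_from_captures(captures, covars, *, K: float = 2.0 / 3.0,
                       alpha: float = 0.01,
                       coverage_limit: int = 10) -> ClamResult:
    """Classify from a CaptureTable + covariates: habitat 1 is continuous
    primary forest, habitat 2 pools fragments and secondary forest.

    Raw (not effort-weighted) capture totals are used.
    """
    species = captures.species_ids
    hab = {r.site_id: r.habitat
           for r in covars.table.itertuples(index=False)}
    site_of = dict(zip(captures.sessions["session_id"],
                       captures.sessions["site_id"]))
    y1 = np.zeros(len(species), dtype=np.int64)
    y2 = np.zeros(len(species), dtype=np.int64)
    idx = {s: i for i, s in enumerate(species)}
    for r in captures.records.itertuples(index=False):
        h = hab[site_of[r.session_id]]
        if h == "continuous":
            y1[idx[r.species_id]] += int(r.individuals)
        else:
            y2[idx[r.species_id]] += int(r.individuals)
    return classify_species(ClamInput(species, y1, y2, K=K, alpha=alpha,
                                      coverage_limit=coverage_limit))
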