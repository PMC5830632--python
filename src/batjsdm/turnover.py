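"""Model-based assemblage-similarity (turnover) statistics.

The similarity between two assemblages (habitat x period conditions) is
the Pearson correlation, across species, of log-transformed model-predicted
occurrence probabilities (occupancy scale) or expected abundances
(abundance scale), computed per posterior draw.  Comparing the same
habitat pair between survey periods, the posterior probability of a
similarity increase is the fraction of draws in which the period-1
similarity is strictly below the period-2 similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .prediction import PredictionSet

__all__ = ["SimilarityResult", "assemblage_similarity",
           "similarity_increase_probability"]

log = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    """Per-draw similarity values for one assemblage pair and scale."""

    pair: tuple[str, str]
    scale: str
    values: np.ndarray          # one correlation per draw, in [-1, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(np.abs(v) > 1.0 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)

    @property
    def posterior_mean(self) -> float:
        return float(self.values.mean())


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (d, S) matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    if np.any(den == 0):
        raise ValueError("degenerate assemblage: zero variance across species")
    return num / den


def assemblage_similarity(pred_a: PredictionSet, pred_b: PredictionSet,
                          scale: str = "occupancy",
                          species_subset=None,
                          floor: float | None = 1e-12,
                          posterior_mean_inputs: bool = False,
                          labels: tuple[str, str] | None = None
                          ) -> SimilarityResult:
    """Correlation (across species) of log predictions between A and B.

    ``scale`` selects occurrence probabilities (``"occupancy"``) or expected
    counts (``"abundance"``).  Values that underflow to zero are raised to
    ``floor`` before logging (with a warning); pass ``floor=None`` to make
    zeros a hard error.  ``posterior_mean_inputs`` computes one correlation
    on posterior-mean predictions instead of one per draw.
    """
    if scale not in ("occupancy", "abundance"):
        raise ValueError("scale must be 'occupancy' or 'abundance'")
    if pred_a.n_draws != pred_b.n_draws:
        raise ValueError("prediction sets have mismatched draw counts")
    if pred_a.species_ids != pred_b.species_ids:
        raise ValueError("prediction sets have mismatched species order")
    idx = pred_a.subset_index(species_subset)
    if idx.size < 3:
        raise ValueError("need at least 3 species for a similarity value")
    attr = "occ_prob" if scale == "occupancy" else "expected_count"
    va = getattr(pred_a, attr)[:, idx]
    vb = getattr(pred_b, attr)[:, idx]
    if posterior_mean_inputs:
        va = va.mean(axis=0, keepdims=True)
        vb = vb.mean(axis=0, keepdims=True)
    n_zero = int((va <= 0).sum() + (vb <= 0).sum())
    if n_zero:
        if floor is None:
            raise ValueError(
                f"{n_zero} predicted value(s) are zero on the {scale} scale; "
                "set a positive floor= to clip before log-transforming")
        log.warning("floored %d zero prediction(s) at %g before logging",
                    n_zero, floor)
        va = np.maximum(va, floor)
        vb = np.maximum(vb, floor)
    vals = _corr_rows(np.log(va), np.log(vb))
    if labels is None:
        labels = (str(pred_a.condition), str(pred_b.condition))
    return SimilarityResult(pair=labels, scale=scale, values=vals)


def similarity_increase_probability(sim_p1: SimilarityResult,
                                    sim_p2: SimilarityResult) -> float:
    """Fraction of draws with period-1 similarity strictly below period-2."""
    if sim_p1.values.shape != sim_p2.values.shape:
        raise ValueError("similarity results have mismatched draw counts")
    return float(np.mean(sim_p1.values < sim_p2.values))
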