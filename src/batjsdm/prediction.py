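"""Posterior prediction under standardized effort.

Predictions are made for a 6-row habitat x period grid in which mist-net
effort is standardized to the habitat's mean across both survey periods
(so periods are comparable within a habitat) and secondary-forest cover to
the habitat's site mean in the given period.  Per posterior draw and
species the occurrence probability comes from the probit submodel and the
expected number of captured individuals is the hurdle product

    E[count] = P(occ) * (exp(x'b2 + (sigma_i^2 + ||l2_i||^2) / 2) + 1),

the "+1" restoring the count scale (conditional on presence the smallest
count is one).  By default the site random effect is marginalized
analytically — probit variance inflation in model 1, lognormal mean in
model 2 — which reads as prediction for a generic new site; conditioning
on a typical site (eta = 0) is available via ``marginal=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core_data import DESIGN_COLUMNS, SiteCovariateTable
from .model import PosteriorSamples

__all__ = ["PredictionGrid", "PredictionSet", "build_prediction_grid",
           "design_row", "predict_occurrence", "predict_expected_count",
           "predict_set", "expected_richness", "expected_individuals",
           "change_summary"]


@dataclass
class PredictionGrid:
    """Standardized habitat x period prediction conditions."""

    table: pd.DataFrame  # habitat, period, sec_cover (proportion), log_effort

    def row(self, habitat: str, period: int) -> pd.Series:
        t = self.table
        r = t[(t["habitat"] == habitat) & (t["period"] == period)]
        if r.empty:
            raise KeyError(f"no grid row for {habitat!r}, period {period}")
        return r.iloc[0]


def build_prediction_grid(covars: SiteCovariateTable,
                          sessions: pd.DataFrame) -> PredictionGrid:
    """Six-row grid of standardized conditions from the observed design.

    Effort standard: mean ``effort_mnh`` over the habitat's sessions pooling
    both periods.  Cover standard: mean site cover of that habitat in that
    period, as a proportion.
    """
    hab_of = dict(zip(covars.table["site_id"], covars.table["habitat"]))
    ses = sessions.copy()
    ses["habitat"] = ses["site_id"].map(hab_of)
    rows = []
    for habitat in ("continuous", "fragment", "secondary"):
        sub = ses[ses["habitat"] == habitat]
        for period in (1, 2):
            if sub[sub["period"] == period].empty:
                raise ValueError(
                    f"no sessions for habitat {habitat!r}, period {period}")
        effort = float(sub["effort_mnh"].mean())
        for period in (1, 2):
            cv = covars.table
            cov = cv[(cv["habitat"] == habitat) & (cv["period"] == period)]
            if cov.empty:
                raise ValueError(
                    f"no covariates for habitat {habitat!r}, period {period}")
            rows.append({
                "habitat": habitat,
                "period": period,
                "sec_cover": float(cov["sec_cover_500m"].mean()) / 100.0,
                "log_effort": float(np.log(effort)),
            })
    return PredictionGrid(pd.DataFrame(rows))


def design_row(habitat: str, period: int, sec_cover: float,
               log_effort: float) -> np.ndarray:
    """One design vector in the fixed ``DESIGN_COLUMNS`` coding."""
    frag = 1.0 if habitat == "fragment" else 0.0
    sec = 1.0 if habitat == "secondary" else 0.0
    p2 = 1.0 if int(period) == 2 else 0.0
    return np.array([1.0, frag, sec, p2, sec_cover, log_effort,
                     p2 * frag, p2 * sec, p2 * sec_cover])


@dataclass
class PredictionSet:
    """Per-draw, per-species predictions for one grid row."""

    occ_prob: np.ndarray        # d x S in [0, 1]
    expected_count: np.ndarray  # d x S, >= occ_prob
    species_ids: list[str]
    condition: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.occ_prob.shape[0]

    def subset_index(self, species_subset) -> np.ndarray:
        if species_subset is None:
            return np.arange(len(self.species_ids))
        idx = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in species_subset if s not in idx]
        if missing:
            raise KeyError(f"unknown species in subset: {missing[:5]}")
        return np.array([idx[s] for s in species_subset], dtype=int)


def _grid_x(samples: PosteriorSamples, row) -> np.ndarray:
    x = design_row(row["habitat"], int(row["period"]),
                   float(row["sec_cover"]), float(row["log_effort"]))
    if len(x) != len(samples.design_columns):
        raise ValueError("grid row coding does not match fitted design")
    return x


def predict_occurrence(samples: PosteriorSamples, row,
                       marginal: bool = True) -> np.ndarray:
    """Per-draw, per-species occurrence probability for one grid row.

    Marginalizing the site effect inflates the probit variance by the
    squared loading norm: ``Phi(x'b / sqrt(1 + ||lambda_i||^2))``.
    """
    x = _grid_x(samples, row)
    lin = np.einsum("p,dps->ds", x, samples["B1"])
    if marginal:
        lam2 = np.sum(samples["Lambda1"] ** 2, axis=2)  # d x S
        lin = lin / np.sqrt(1.0 + lam2)
    return ndtr(lin)


def predict_expected_count(samples: PosteriorSamples, row,
                           marginal: bool = True,
                           occ_prob: np.ndarray | None = None) -> np.ndarray:
    """Per-draw expected captures: hurdle product of occurrence probability
    and the (lognormal-marginalized) conditional count plus one."""
    x = _grid_x(samples, row)
    if occ_prob is None:
        occ_prob = predict_occurrence(samples, row, marginal=marginal)
    lin = np.einsum("p,dps->ds", x, samples["B2"])
    half_var = 0.5 * samples["sigma2"]
    if marginal:
        half_var = half_var + 0.5 * np.sum(samples["Lambda2"] ** 2, axis=2)
    arg = lin + half_var
    if np.any(arg > 700.0):
        d, s = np.unravel_index(int(np.argmax(arg)), arg.shape)
        raise OverflowError(
            f"conditional-count prediction overflows at draw {d}, species "
            f"{s} (log rate {arg[d, s]:.1f}); the chain likely diverged")
    return occ_prob * (np.exp(arg) + 1.0)


def predict_set(samples: PosteriorSamples, row,
                marginal: bool = True) -> PredictionSet:
    occ = predict_occurrence(samples, row, marginal=marginal)
    cnt = predict_expected_count(samples, row, marginal=marginal,
                                 occ_prob=occ)
    cond = dict(row) if not isinstance(row, dict) else row
    return PredictionSet(occ_prob=occ, expected_count=cnt,
                         species_ids=list(samples.species_ids),
                         condition={k: (v.item() if hasattr(v, "item") else v)
                                    for k, v in dict(cond).items()})


def _summary(draws: np.ndarray) -> tuple[float, float]:
    return float(draws.mean()), float(draws.std(ddof=0))


def expected_richness(pred: PredictionSet,
                      species_subset=None) -> tuple[float, float]:
    """Posterior mean and sd of per-visit expected species richness —
    the per-draw sum of occurrence probabilities over the subset."""
    idx = pred.subset_index(species_subset)
    if idx.size == 0:
        raise ValueError("species subset is empty")
    return _summary(pred.occ_prob[:, idx].sum(axis=1))


def expected_individuals(pred: PredictionSet,
                         species_subset=None) -> tuple[float, float]:
    """Posterior mean and sd of the per-visit expected number of captured
    individuals (per-draw sum of expected counts over the subset)."""
    idx = pred.subset_index(species_subset)
    if idx.size == 0:
        raise ValueError("species subset is empty")
    return _summary(pred.expected_count[:, idx].sum(axis=1))


def richness_draws(pred: PredictionSet, species_subset=None) -> np.ndarray:
    idx = pred.subset_index(species_subset)
    return pred.occ_prob[:, idx].sum(axis=1)


def individuals_draws(pred: PredictionSet, species_subset=None) -> np.ndarray:
    idx = pred.subset_index(species_subset)
    return pred.expected_count[:, idx].sum(axis=1)


def change_summary(pred_p1: PredictionSet,
                   pred_p2: PredictionSet,
                   support_level: float = 0.95) -> pd.DataFrame:
    """Species-level period-2 minus period-1 differences with posterior
    support.

    Support is the fraction of draws in which the difference is strictly
    positive (and, symmetrically, strictly negative); the ``*_high_support``
    flag marks species whose larger directional fraction exceeds
    ``support_level``.  Ties count toward neither direction.
    """
    if pred_p1.n_draws != pred_p2.n_draws:
        raise ValueError("prediction sets have mismatched draw counts")
    if pred_p1.species_ids != pred_p2.species_ids:
        raise ValueError("prediction sets have mismatched species order")
    rows = []
    for name, a1, a2 in (("occupancy", pred_p1.occ_prob, pred_p2.occ_prob),
                         ("count", pred_p1.expected_count,
                          pred_p2.expected_count)):
        diff = a2 - a1
        frac_pos = (diff > 0).mean(axis=0)
        frac_neg = (diff < 0).mean(axis=0)
        rows.append(pd.DataFrame({
            "species_id": pred_p1.species_ids,
            "statistic": name,
            "delta_mean": diff.mean(axis=0),
            "frac_positive": frac_pos,
            "frac_negative": frac_neg,
            "direction": np.where(frac_pos >= frac_neg, "increase",
                                  "decrease"),
            "support": np.maximum(frac_pos, frac_neg),
            "high_support": np.maximum(frac_pos, frac_neg) > support_level,
        }))
    return pd.concat(rows, ignore_index=True)
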