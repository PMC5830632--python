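"""Synthetic data with the statistical structure the analysis assumes.

The default landscape emulates the study design the pipeline targets: 19
sites in three habitat classes (6 continuous forest, 6 fragments, 7
secondary forest), two survey periods and 301 mist-netting sessions with
heterogeneous effort; 50 species split into old-growth specialists and
habitat generalists; counts generated from the hurdle model itself (probit
occurrence, then one plus an overdispersed Poisson), with community-level
coefficients drawn around trait-driven means under the phylogenetic
covariance W(rho) and latent-factor site effects.  The default
parameterization is calibrated so that roughly 70% of session x species
cells are zero, the zero fraction the analysis is designed around.

Everything is seeded explicitly; the returned ``SimulationTruth`` records
every parameter used, so parameter-recovery tests know the ground truth.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.special import ndtr

from .core_data import (CaptureTable, PhyloCorrelation, SiteCovariateTable,
                        TraitTable, build_design_matrix,
                        phylo_correlation_from_tree)

__all__ = ["LandscapeLayout", "SimulationTruth", "SimulatedDataset",
           "simulate_phylogeny", "simulate_parameters", "simulate_dataset",
           "default_layout"]


@dataclass
class LandscapeLayout:
    """Sites, session counts, effort and cover distributions.

    ``sessions_per_site[(habitat, period)]`` is the per-site session count;
    ``extra_sessions`` adds single sessions to named sites so the total can
    hit an exact target (301 by default).  Effort is lognormal with a
    per-habitat median (mnh) and a common log-sd; cover is uniform within
    habitat-specific ranges, shifted upward in period 2 (regeneration).
    """

    sites: pd.DataFrame                      # site_id, habitat
    sessions_per_site: dict = field(default_factory=dict)
    extra_sessions: list = field(default_factory=list)
    effort_median: dict = field(default_factory=lambda: {
        "continuous": 180.0, "fragment": 180.0, "secondary": 60.0})
    effort_sdlog: float = 0.5
    cover_range: dict = field(default_factory=lambda: {
        "continuous": (0.0, 10.0), "fragment": (30.0, 70.0),
        "secondary": (60.0, 95.0)})
    cover_period2_shift: float = 10.0

    @property
    def n_sessions(self) -> int:
        n = sum(self.sessions_per_site[(h, p)]
                for h in self.sites["habitat"]
                for p in (1, 2))
        return n + len(self.extra_sessions)


def default_layout() -> LandscapeLayout:
    """6 continuous-forest, 6 fragment and 7 secondary-forest sites; session
    counts chosen so the two periods total exactly 301 sessions."""
    rows = ([("CF%02d" % i, "continuous") for i in range(1, 7)]
            + [("FR%02d" % i, "fragment") for i in range(1, 7)]
            + [("SF%02d" % i, "secondary") for i in range(1, 8)])
    sites = pd.DataFrame(rows, columns=["site_id", "habitat"])
    sessions = {("continuous", 1): 10, ("fragment", 1): 10, ("secondary", 1): 5,
                ("continuous", 2): 8, ("fragment", 2): 8, ("secondary", 2): 7}
    return LandscapeLayout(sites=sites, sessions_per_site=sessions,
                           extra_sessions=[("SF01", 1)])


def simulate_phylogeny(S: int, seed: int) -> str:
    """Pure-birth ultrametric tree with S tips, rescaled to unit depth.

    Uses the general-sampling-approach simulator so terminal branches are
    strictly positive (the correlation matrix stays non-singular).
    """
    if S < 2:
        raise ValueError("need at least 2 species")
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=S,
        gsa_ntax=S + 2, rng=_random.Random(int(seed)))
    tree.calc_node_root_distances()
    depth = max(l.root_distance for l in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                    key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:02d}"
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# Trait-level coefficient means (Gamma), one column per trait regressor
# (intercept applies to all species; the second column is the specialist
# offset).  Row order follows core_data.DESIGN_COLUMNS.  The occurrence
# intercepts are calibrated so the default landscape yields ~70% zero cells;
# the signs encode the emulated ecology: specialists are rarer, avoid
# fragments/secondary forest in period 1, and benefit from matrix
# regeneration (positive period-2 interactions), generalists the reverse.
GAMMA1_DEFAULT = np.array([
    #  all     specialist offset
    [-2.40, -0.80],   # intercept
    [0.10, -0.30],    # fragment
    [0.30, -0.60],    # secondary
    [-0.10, -0.10],   # period 2
    [0.40, -0.50],    # secondary cover (proportion)
    [0.30, 0.00],     # log effort
    [0.10, 0.35],     # period2 x fragment
    [-0.35, 0.45],    # period2 x secondary
    [0.20, 0.40],     # period2 x cover
])

GAMMA2_DEFAULT = np.array([
    [-0.70, -0.50],
    [0.05, -0.15],
    [0.30, -0.30],
    [-0.05, 0.00],
    [0.25, -0.25],
    [0.20, 0.00],
    [0.05, 0.20],
    [-0.30, 0.25],
    [0.15, 0.25],
])


@dataclass
class SimulationTruth:
    """Complete generative parameter set for one synthetic dataset."""

    seed: int
    layout: LandscapeLayout
    species_ids: list[str]
    newick: str
    traits: TraitTable
    B1: np.ndarray
    B2: np.ndarray
    Gamma1: np.ndarray
    Gamma2: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    rho1: float
    rho2: float
    Lambda1: np.ndarray
    Lambda2: np.ndarray
    Eta1: np.ndarray
    Eta2: np.ndarray
    sigma2: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


def simulate_parameters(S: int = 50, layout: LandscapeLayout | None = None,
                        seed: int = 1, *, rho: float = 0.5,
                        n_factors: int = 2, factor_scale: float = 0.3,
                        v_diag: float = 0.10,
                        gamma1: np.ndarray | None = None,
                        gamma2: np.ndarray | None = None,
                        specialist_fraction: float = 0.54,
                        newick: str | None = None) -> SimulationTruth:
    """Draw a ground-truth parameter set.

    Trait means default to the calibrated ``GAMMA*_DEFAULT`` tables; species
    coefficients are drawn from the matrix normal around Gamma T' with
    column covariance ``W(rho) = rho C + (1 - rho) I`` and row covariance
    ``v_diag * I``; loadings are N(0, factor_scale^2) and site scores
    standard normal; overdispersion variances are uniform on [0.2, 0.5].
    """
    if layout is None:
        layout = default_layout()
    ss = np.random.SeedSequence(int(seed))
    tree_seed, par_seed = [int(c.generate_state(1)[0] % (2**31))
                           for c in ss.spawn(2)]
    rng = np.random.default_rng(par_seed)

    if newick is None:
        newick = simulate_phylogeny(S, tree_seed)
    phylo = phylo_correlation_from_tree(newick)
    species = phylo.species_order
    if len(species) != S:
        raise ValueError("tree tip count does not match S")

    n_spec = int(round(specialist_fraction * S))
    spec_idx = rng.choice(S, size=n_spec, replace=False)
    affinity = np.array(["generalist"] * S, dtype=object)
    affinity[spec_idx] = "specialist"
    traits = TraitTable(pd.DataFrame({"species_id": species,
                                      "affinity": affinity}))
    T = traits.design(species)

    Gamma1 = np.array(gamma1 if gamma1 is not None else GAMMA1_DEFAULT, float)
    Gamma2 = np.array(gamma2 if gamma2 is not None else GAMMA2_DEFAULT, float)
    p = Gamma1.shape[0]
    V1 = V2 = v_diag * np.eye(p)

    d, Q = np.linalg.eigh(phylo.C)
    w = rho * np.clip(d, 0, None) + (1.0 - rho)
    rootW = (Q * np.sqrt(w)) @ Q.T

    def draw_B(Gamma, V):
        rootV = np.sqrt(np.diag(V))[:, None]
        return Gamma @ T.T + rootV * rng.standard_normal((p, S)) @ rootW.T

    B1 = draw_B(Gamma1, V1)
    B2 = draw_B(Gamma2, V2)
    n_sites = len(layout.sites)
    H = n_factors
    Lambda1 = rng.normal(0.0, factor_scale, size=(S, H))
    Lambda2 = rng.normal(0.0, factor_scale, size=(S, H))
    Eta1 = rng.standard_normal((n_sites, H))
    Eta2 = rng.standard_normal((n_sites, H))
    sigma2 = rng.uniform(0.2, 0.5, size=S)
    return SimulationTruth(seed=int(seed), layout=layout, species_ids=species,
                           newick=newick, traits=traits, B1=B1, B2=B2,
                           Gamma1=Gamma1, Gamma2=Gamma2, V1=V1, V2=V2,
                           rho1=rho, rho2=rho, Lambda1=Lambda1,
                           Lambda2=Lambda2, Eta1=Eta1, Eta2=Eta2,
                           sigma2=sigma2)


@dataclass
class SimulatedDataset:
    """Generated input tables plus the internal matrices and truth."""

    captures: CaptureTable
    covariates: SiteCovariateTable
    traits: TraitTable
    newick: str
    truth: SimulationTruth
    Y_occ: np.ndarray
    Y_cond: np.ndarray           # count - 1 where present, nan elsewhere
    cond_mask: np.ndarray
    sessions: pd.DataFrame
    site_index: np.ndarray

    @property
    def zero_fraction(self) -> float:
        return float(1.0 - self.Y_occ.mean())

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.captures.to_csv(out / "captures.csv")
        self.covariates.to_csv(out / "covariates.csv")
        self.traits.to_csv(out / "traits.csv")
        (out / "phylogeny.nwk").write_text(self.newick + "\n")


def simulate_dataset(truth: SimulationTruth) -> SimulatedDataset:
    """Generate the four input tables from a ground-truth parameter set.

    Session efforts, site covers, occurrences and counts are drawn from the
    generative model; all randomness derives from ``truth.seed`` (a distinct
    stream from the parameter draw, so the same truth can be re-used).
    """
    layout = truth.layout
    ss = np.random.SeedSequence(int(truth.seed))
    data_seed = int(ss.spawn(3)[2].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(data_seed)

    # covariates: cover per site x period
    cov_rows = []
    for r in layout.sites.itertuples(index=False):
        lo, hi = layout.cover_range[r.habitat]
        c1 = rng.uniform(lo, hi)
        c2 = min(c1 + layout.cover_period2_shift, 100.0)
        cov_rows.append((r.site_id, 1, r.habitat, round(c1, 2)))
        cov_rows.append((r.site_id, 2, r.habitat, round(c2, 2)))
    covars = SiteCovariateTable(pd.DataFrame(
        cov_rows, columns=["site_id", "period", "habitat", "sec_cover_500m"]))

    # sessions with lognormal effort
    extra = {}
    for site_id, period in layout.extra_sessions:
        extra[(site_id, period)] = extra.get((site_id, period), 0) + 1
    ses_rows = []
    for r in layout.sites.itertuples(index=False):
        for period in (1, 2):
            k = layout.sessions_per_site[(r.habitat, period)] + \
                extra.get((r.site_id, period), 0)
            for j in range(k):
                eff = layout.effort_median[r.habitat] * np.exp(
                    layout.effort_sdlog * rng.standard_normal())
                ses_rows.append((f"{r.site_id}-P{period}-{j + 1:02d}",
                                 r.site_id, period, round(float(eff), 1)))
    sessions = pd.DataFrame(
        ses_rows, columns=["session_id", "site_id", "period", "effort_mnh"])
    sessions = sessions.sort_values("session_id").reset_index(drop=True)

    X = build_design_matrix(sessions, covars)
    site_ids = sorted(layout.sites["site_id"])
    smap = {s: i for i, s in enumerate(site_ids)}
    site_index = sessions["site_id"].map(smap).to_numpy(dtype=int)

    g1 = X @ truth.B1 + truth.Eta1[site_index] @ truth.Lambda1.T
    occ = (rng.random(g1.shape) < ndtr(g1)).astype(np.int8)
    g2 = X @ truth.B2 + truth.Eta2[site_index] @ truth.Lambda2.T
    L = g2 + rng.standard_normal(g2.shape) * np.sqrt(truth.sigma2)[None, :]
    y_cond = rng.poisson(np.exp(np.clip(L, None, 30.0)))
    mask = occ.astype(bool)
    counts = np.where(mask, y_cond + 1, 0)

    rec_rows = []
    for j, row in enumerate(sessions.itertuples(index=False)):
        for i in np.flatnonzero(counts[j]):
            rec_rows.append((row.site_id, row.session_id, row.period, "",
                             truth.species_ids[i], int(counts[j, i]),
                             row.effort_mnh))
    records = pd.DataFrame(rec_rows, columns=[
        "site_id", "session_id", "period", "date", "species_id",
        "individuals", "effort_mnh"])
    captures = CaptureTable(records=records, sessions=sessions)
    return SimulatedDataset(
        captures=captures, covariates=covars, traits=truth.traits,
        newick=truth.newick, truth=truth, Y_occ=occ,
        Y_cond=np.where(mask, y_cond.astype(float), np.nan),
        cond_mask=mask, sessions=sessions, site_index=site_index)
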