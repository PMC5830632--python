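"""Model specification and posterior containers for the hurdle JSDM.

The joint model has two submodels sharing one architecture:

* model 1 (occurrence): probit regression on the session design, i.e.
  ``Y_occ[j,i] = 1[Z_ji > 0]`` with ``Z_ji = x_j' b_i + eta_{s(j)}' l_i + e``,
  ``e ~ N(0, 1)``;
* model 2 (abundance conditional on presence): overdispersed Poisson with a
  log link, ``Y_cond[j,i] ~ Poisson(exp(L_ji))`` with
  ``L_ji ~ N(x_j' b_i + eta_{s(j)}' l_i, sigma_i^2)``, fitted only on cells
  where the species was present.

At the community level each submodel's coefficient matrix B (p x S) is
matrix-normal around the trait regression Gamma T', with row covariance V
(among covariates) and column covariance ``W(rho) = rho C + (1-rho) I``
mixing the phylogenetic correlation C with independence.  Site random
effects use the latent-factor construction: sites carry factor scores eta
(standard normal prior) and species carry loadings lambda under a
multiplicative-gamma shrinkage prior.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["PriorSet", "ModelSpec", "PosteriorSamples"]


@dataclass
class PriorSet:
    """Hyperparameters of the (weakly informative) default priors.

    gamma_var
        Prior variance of each entry of the trait-effect matrix Gamma.
    v_df, v_scale
        Inverse-Wishart degrees of freedom and scale for V; ``None`` means
        ``p + 2`` and the identity, resolved at fit time.
    shrink_a1, shrink_a2, shrink_nu
        Multiplicative-gamma process parameters for the factor loadings:
        delta_1 ~ Ga(a1, 1), delta_h ~ Ga(a2, 1) for h >= 2, and local
        precisions phi ~ Ga(nu/2, nu/2).
    sigma2_shape, sigma2_rate
        Inverse-gamma prior for the species overdispersion variances.
    """

    gamma_var: float = 10.0
    v_df: float | None = None
    v_scale: np.ndarray | None = None
    shrink_a1: float = 2.0
    shrink_a2: float = 3.0
    shrink_nu: float = 3.0
    sigma2_shape: float = 1.0
    sigma2_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in ("gamma_var", "shrink_a1", "shrink_a2", "shrink_nu",
                     "sigma2_shape", "sigma2_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")
        if self.v_df is not None and self.v_scale is not None:
            p = np.asarray(self.v_scale).shape[0]
            if self.v_df < p + 2:
                raise ValueError("v_df must be at least p + 2")

    def resolved(self, p: int) -> tuple[float, np.ndarray]:
        df = self.v_df if self.v_df is not None else p + 2
        scale = (np.asarray(self.v_scale, float) if self.v_scale is not None
                 else np.eye(p))
        if scale.shape != (p, p):
            raise ValueError("v_scale has wrong shape")
        return float(df), scale


def _default_rho_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 51)


@dataclass
class ModelSpec:
    """MCMC and structural settings for one fit.

    Defaults follow the analysis this package reproduces: 50,000 Gibbs
    sweeps with the first 15,000 discarded as transient (thinned by 10 for
    memory), a fixed number of latent factors with shrinkage, and a uniform
    prior for the phylogenetic weight rho on a 51-point grid on [0, 1].

    ``fix_*`` entries pin community-level blocks instead of sampling them
    (used for oracle comparisons and prior-sensitivity runs); ``None`` means
    the block is sampled.
    """

    n_iter: int = 50_000
    n_burnin: int = 15_000
    thin: int = 10
    seed: int = 0
    n_factors: int = 3
    rho_grid: np.ndarray = field(default_factory=_default_rho_grid)
    priors: PriorSet = field(default_factory=PriorSet)
    fix_gamma: np.ndarray | None = None
    fix_V: np.ndarray | None = None
    fix_rho: float | None = None
    fix_sigma2: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho_grid = np.sort(np.asarray(self.rho_grid, dtype=float))
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if not np.any(self.rho_grid == 0.0):
            raise ValueError("rho_grid must contain 0")
        if np.any(self.rho_grid < 0) or np.any(self.rho_grid > 1):
            raise ValueError("rho_grid must lie in [0, 1]")
        if self.fix_rho is not None and not np.any(
                np.isclose(self.rho_grid, self.fix_rho)):
            raise ValueError("fix_rho must be a rho_grid member")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        pri = d["priors"]
        for k, v in list(pri.items()):
            if isinstance(v, np.ndarray):
                pri[k] = v.tolist()
        return d

    def spec_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PosteriorSamples:
    """Retained draws of every model parameter, for both submodels.

    ``draws`` maps parameter names to arrays whose leading axis indexes the
    retained draw: ``B1``/``B2`` (d, p, S), ``Gamma1``/``Gamma2`` (d, p, q),
    ``V1``/``V2`` (d, p, p), ``rho1``/``rho2`` (d,), ``Lambda1``/``Lambda2``
    (d, S, H), ``Eta1``/``Eta2`` (d, n_sites, H) and ``sigma2`` (d, S).
    """

    draws: dict[str, np.ndarray]
    species_ids: list[str]
    site_ids: list[str]
    design_columns: list[str]
    seed: int
    spec_hash: str
    spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {k: v.shape[0] for k, v in self.draws.items()}
        if len(set(counts.values())) > 1:
            raise ValueError(f"inconsistent draw counts: {counts}")
        for k, v in self.draws.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in posterior draws {k!r}")

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def __getitem__(self, key: str) -> np.ndarray:
        return self.draws[key]

    def save(self, npz_path, meta_path=None) -> None:
        np.savez_compressed(npz_path, **self.draws)
        meta = {
            "species_ids": self.species_ids,
            "site_ids": self.site_ids,
            "design_columns": list(self.design_columns),
            "seed": int(self.seed),
            "spec_hash": self.spec_hash,
            "spec": self.spec,
            "n_draws": int(self.n_draws),
        }
        if meta_path is None:
            meta_path = str(npz_path) + ".json"
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, npz_path, meta_path=None) -> "PosteriorSamples":
        if meta_path is None:
            meta_path = str(npz_path) + ".json"
        with np.load(npz_path) as arch:
            draws = {k: arch[k] for k in arch.files}
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(draws=draws, species_ids=meta["species_ids"],
                   site_ids=meta["site_ids"],
                   design_columns=meta["design_columns"],
                   seed=meta["seed"], spec_hash=meta["spec_hash"],
                   spec=meta.get("spec", {}))
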