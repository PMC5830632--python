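"""Blocked Gibbs sampler for the two-part hierarchical JSDM.

Both hurdle submodels reduce to the same linear-Gaussian core once their
latent variables are in place: the probit part via truncated-normal data
augmentation (latent matrix Z), the overdispersed-Poisson part via the
per-cell latent log rate L, updated by slice sampling.  Conditional on
those latents every remaining block — species coefficients B, trait
effects Gamma, covariance V, phylogenetic weight rho, latent factors
(eta, lambda) with their multiplicative-gamma shrinkage locals, and the
overdispersion variances sigma_i^2 — has a standard conjugate or gridded
full conditional.

The sampler is deterministic given the seed: all randomness flows through
one ``numpy.random.Generator`` and every update consumes draws in a fixed
order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import log_ndtr, ndtri_exp
from scipy.stats import invwishart

from .core_data import ModelData
from .model import ModelSpec, PosteriorSamples

__all__ = ["GibbsSampler", "SubState", "fit",
           "sample_truncnorm_lower", "slice_update_lograte"]


# --------------------------------------------------------------------------
# primitive draws


def sample_truncnorm_lower(rng: np.random.Generator,
                           a: np.ndarray) -> np.ndarray:
    """Draw standard normals conditioned on X > a, elementwise.

    Uses the inverse survival function in log space, which stays accurate
    arbitrarily far into the tail (a >> 0) where the naive inverse-CDF
    construction loses all precision.
    """
    u = np.clip(rng.random(np.shape(a)), 1e-300, None)
    return -ndtri_exp(np.log(u) + log_ndtr(-np.asarray(a)))


def slice_update_lograte(rng: np.random.Generator, L: np.ndarray,
                         y: np.ndarray, g: np.ndarray, sig2: np.ndarray,
                         width: float = 1.0) -> np.ndarray:
    """One slice-sampling sweep of the latent log rates of model 2.

    Each cell targets ``Poisson(y | exp(L)) * Normal(L | g, sig2)`` (the
    residual e = L - g has the N(0, sigma_i^2) overdispersion prior).  The
    stepping-out procedure uses a fixed width and unlimited steps; the
    target is log-concave so both loops terminate quickly.
    """
    L = np.asarray(L, float).copy()
    if L.size == 0:
        return L

    def logf(x, i=None):
        yy, gg, ss = (y, g, sig2) if i is None else (y[i], g[i], sig2[i])
        with np.errstate(over="ignore"):
            return yy * x - np.exp(x) - 0.5 * (x - gg) ** 2 / ss

    logy = logf(L) - rng.exponential(size=L.shape)
    lo = L - width * rng.random(L.shape)
    hi = lo + width
    idx = np.flatnonzero(logf(lo) > logy)
    while idx.size:
        lo[idx] -= width
        idx = idx[logf(lo[idx], idx) > logy[idx]]
    idx = np.flatnonzero(logf(hi) > logy)
    while idx.size:
        hi[idx] += width
        idx = idx[logf(hi[idx], idx) > logy[idx]]

    out = L.copy()
    idx = np.arange(L.size)
    while idx.size:
        prop = lo[idx] + rng.random(idx.size) * (hi[idx] - lo[idx])
        ok = logf(prop, idx) >= logy[idx]
        out[idx[ok]] = prop[ok]
        bad = idx[~ok]
        pb = prop[~ok]
        shrink_lo = pb < L[bad]
        lo[bad[shrink_lo]] = pb[shrink_lo]
        hi[bad[~shrink_lo]] = pb[~shrink_lo]
        idx = bad
    return out


def _sample_mvn_from_precision(rng, prec, rhs):
    """Draw from N(prec^-1 rhs, prec^-1) via one Cholesky factorisation."""
    cf = cho_factor(prec, lower=True)
    mean = cho_solve(cf, rhs)
    z = rng.standard_normal(rhs.shape[0])
    dev = solve_triangular(cf[0].T, z, lower=False)
    return mean + dev


# --------------------------------------------------------------------------
# chain state


@dataclass
class SubState:
    """Parameters of one hurdle submodel (shared architecture)."""

    B: np.ndarray          # p x S
    Gamma: np.ndarray      # p x q
    V: np.ndarray          # p x p
    rho: float
    Lambda: np.ndarray     # S x H
    Eta: np.ndarray        # n_sites x H
    phi: np.ndarray        # S x H  local shrinkage precisions
    delta: np.ndarray      # H      multiplicative gamma increments

    @property
    def tau(self) -> np.ndarray:
        return np.cumprod(self.delta) if self.delta.size else self.delta


class GibbsSampler:
    """Drives the blocked Gibbs updates for both submodels.

    Public update methods (``update_probit_latents``, ``update_coefficients``,
    ``update_rho``, ``update_factors``, ``update_overdispersion``) operate on
    the stored state, so tests can exercise single full conditionals; ``fit``
    below wraps the whole schedule.
    """

    def __init__(self, data: ModelData, spec: ModelSpec,
                 rng: np.random.Generator | None = None):
        if np.linalg.matrix_rank(data.X) < data.X.shape[1]:
            raise ValueError("design matrix X is rank deficient")
        self.data = data
        self.spec = spec
        self.rng = rng if rng is not None else np.random.default_rng(spec.seed)
        self.n, self.p = data.X.shape
        self.S = data.n_species
        self.q = data.T.shape[1]
        self.H = spec.n_factors
        self.n_sites = data.n_sites
        self.v_df, self.v_scale = spec.priors.resolved(self.p)

        C = data.C.C
        d, Q = np.linalg.eigh(C)
        self._C_eigval = np.clip(d, 0.0, None)
        self._C_eigvec = Q
        self._XtX_full = data.X.T @ data.X
        self._site_rows = [np.flatnonzero(data.site_index == s)
                           for s in range(self.n_sites)]
        self._refresh_mask()
        self._init_state()

    # -- data-dependent caches --------------------------------------------

    def _refresh_mask(self) -> None:
        """Recompute per-species present-cell caches (mask can change only
        when data are re-simulated, e.g. in joint-distribution testing)."""
        mask = self.data.cond_mask
        self._rows_i = [np.flatnonzero(mask[:, i]) for i in range(self.S)]
        self._XtX_i = [self.data.X[r].T @ self.data.X[r] if r.size else
                       np.zeros((self.p, self.p)) for r in self._rows_i]
        self._n_i = np.array([r.size for r in self._rows_i])

    def _init_state(self) -> None:
        p, S, q, H = self.p, self.S, self.q, self.H
        mk = lambda: SubState(B=np.zeros((p, S)), Gamma=np.zeros((p, q)),
                              V=np.eye(p), rho=0.0, Lambda=np.zeros((S, H)),
                              Eta=np.zeros((self.n_sites, H)),
                              phi=np.ones((S, H)), delta=np.ones(H))
        self.m1 = mk()
        self.m2 = mk()
        if self.spec.fix_gamma is not None:
            self.m1.Gamma = np.array(self.spec.fix_gamma, float)
            self.m2.Gamma = np.array(self.spec.fix_gamma, float)
        if self.spec.fix_V is not None:
            self.m1.V = np.array(self.spec.fix_V, float)
            self.m2.V = np.array(self.spec.fix_V, float)
        if self.spec.fix_rho is not None:
            self.m1.rho = float(self.spec.fix_rho)
            self.m2.rho = float(self.spec.fix_rho)
        self.Z = np.where(self.data.Y_occ > 0, 0.5, -0.5).astype(float)
        self.L = np.where(self.data.cond_mask,
                          np.log(np.nan_to_num(self.data.Y_cond) + 1.0), 0.0)
        if self.spec.fix_sigma2 is not None:
            self.sigma2 = np.broadcast_to(
                np.asarray(self.spec.fix_sigma2, float), (S,)).copy()
        else:
            self.sigma2 = np.ones(S)

    # -- linear predictors -------------------------------------------------

    def _site_effect(self, st: SubState) -> np.ndarray:
        if self.H == 0:
            return np.zeros((self.n, self.S))
        return st.Eta[self.data.site_index] @ st.Lambda.T

    def linear_predictor(self, which: int) -> np.ndarray:
        st = self.m1 if which == 1 else self.m2
        return self.data.X @ st.B + self._site_effect(st)

    # -- W(rho) helpers ----------------------------------------------------

    def _Winv_logdet(self, rho: float) -> tuple[np.ndarray, float]:
        w = rho * self._C_eigval + (1.0 - rho)
        if np.any(w <= 1e-12):
            raise np.linalg.LinAlgError(
                f"W(rho) not positive definite at rho={rho:.3f}, "
                f"min eigenvalue {w.min():.3e}")
        Q = self._C_eigvec
        Winv = (Q / w) @ Q.T
        return Winv, float(np.sum(np.log(w)))

    # -- full-conditional updates ------------------------------------------

    def update_probit_latents(self) -> None:
        """Truncated-normal refresh of Z given its linear predictor."""
        m = self.linear_predictor(1)
        y = self.data.Y_occ
        a = np.where(y > 0, -m, m)
        t = sample_truncnorm_lower(self.rng, a)
        self.Z = np.where(y > 0, m + t, m - t)

    def update_lograte_latents(self) -> None:
        """Slice-sampling refresh of the model-2 latent log rates."""
        mask = self.data.cond_mask
        if not mask.any():
            return
        g = self.linear_predictor(2)[mask]
        rows, cols = np.nonzero(mask)
        sig2 = self.sigma2[cols]
        y = self.data.Y_cond[mask]
        self.L[mask] = slice_update_lograte(self.rng, self.L[mask], y, g, sig2)

    def _pseudo_data(self, which: int):
        """(pseudo-obs matrix, per-species noise variance, mask or None)."""
        if which == 1:
            return self.Z, np.ones(self.S), None
        return self.L, self.sigma2, self.data.cond_mask

    def update_coefficients(self, which: int) -> None:
        """Joint conjugate draw of B, then Gamma, then V for one submodel."""
        st = self.m1 if which == 1 else self.m2
        Zt, noise, mask = self._pseudo_data(which)
        resid = Zt - self._site_effect(st)
        Winv, _ = self._Winv_logdet(st.rho)
        Vinv = np.linalg.inv(st.V)
        p, S = self.p, self.S

        # --- B | rest : N over the stacked species blocks [b_1; ...; b_S]
        prec = np.kron(Winv, Vinv)
        M0 = st.Gamma @ self.data.T.T                      # p x S prior mean
        rhs = (Vinv @ M0 @ Winv).T.reshape(-1)             # prior part
        if mask is None:
            data_rhs = (self.data.X.T @ resid) / noise     # p x S
            for i in range(S):
                prec[i * p:(i + 1) * p, i * p:(i + 1) * p] += \
                    self._XtX_full / noise[i]
                rhs[i * p:(i + 1) * p] += data_rhs[:, i]
        else:
            for i in range(S):
                r = self._rows_i[i]
                if r.size:
                    prec[i * p:(i + 1) * p, i * p:(i + 1) * p] += \
                        self._XtX_i[i] / noise[i]
                    rhs[i * p:(i + 1) * p] += \
                        self.data.X[r].T @ resid[r, i] / noise[i]
        b = _sample_mvn_from_precision(self.rng, prec, rhs)
        st.B = b.reshape(S, p).T

        # --- Gamma | B, V, rho : conjugate normal (unless pinned)
        T = self.data.T
        if self.spec.fix_gamma is None:
            TWT = T.T @ Winv @ T
            gprec = np.kron(TWT, Vinv) + \
                np.eye(p * self.q) / self.spec.priors.gamma_var
            grhs = (Vinv @ st.B @ Winv @ T).T.reshape(-1)
            g = _sample_mvn_from_precision(self.rng, gprec, grhs)
            st.Gamma = g.reshape(self.q, p).T

        # --- V | B, Gamma, rho : inverse-Wishart (unless pinned)
        if self.spec.fix_V is None:
            E = st.B - st.Gamma @ T.T
            scale = self.v_scale + E @ Winv @ E.T
            scale = 0.5 * (scale + scale.T)
            st.V = invwishart.rvs(df=self.v_df + S, scale=scale,
                                  random_state=self.rng)
            st.V = np.atleast_2d(st.V)

    def update_rho(self, which: int) -> None:
        """Gridded draw of the phylogenetic weight rho for one submodel."""
        if self.spec.fix_rho is not None:
            return
        st = self.m1 if which == 1 else self.m2
        E = st.B - st.Gamma @ self.data.T.T
        Vinv = np.linalg.inv(st.V)
        A = E.T @ Vinv @ E                # S x S, only diag in eigenbasis used
        Q = self._C_eigvec
        u = np.einsum("ij,ji->i", Q.T @ A, Q)     # quadratic forms per eigvec
        grid = self.spec.rho_grid
        logp = np.empty(grid.size)
        for k, rho in enumerate(grid):
            w = rho * self._C_eigval + (1.0 - rho)
            if np.any(w <= 1e-12):
                logp[k] = -np.inf
                continue
            logp[k] = -0.5 * self.p * np.sum(np.log(w)) - 0.5 * np.sum(u / w)
        m = logp.max()
        if not np.isfinite(m):
            raise FloatingPointError("all rho grid log-densities are -inf")
        prob = np.exp(logp - m)
        prob /= prob.sum()
        k = int(np.searchsorted(np.cumsum(prob), self.rng.random()))
        st.rho = float(grid[min(k, grid.size - 1)])

    def update_factors(self, which: int) -> None:
        """Conjugate refresh of site scores, species loadings and the
        multiplicative-gamma shrinkage locals for one submodel."""
        if self.H == 0:
            return
        st = self.m1 if which == 1 else self.m2
        Zt, noise, mask = self._pseudo_data(which)
        R = Zt - self.data.X @ st.B
        H, S = self.H, self.S
        if mask is None:
            wts = np.broadcast_to(1.0 / noise, (self.n, self.S))
        else:
            wts = mask / noise
        R0 = np.where(mask, R, 0.0) if mask is not None else R

        # eta rows (sites), prior N(0, I_H)
        for s in range(self.n_sites):
            rows = self._site_rows[s]
            wsum = wts[rows].sum(axis=0)                       # per species
            prec = np.eye(H) + (st.Lambda * wsum[:, None]).T @ st.Lambda
            rhs = st.Lambda.T @ (wts[rows] * R0[rows]).sum(axis=0)
            st.Eta[s] = _sample_mvn_from_precision(self.rng, prec, rhs)

        # lambda rows (species), prior N(0, diag(1/(phi_ih tau_h)))
        E = st.Eta[self.data.site_index]                       # n x H
        tau = st.tau
        for i in range(S):
            wi = wts[:, i]
            Ew = E * wi[:, None]
            prec = np.diag(st.phi[i] * tau) + Ew.T @ E
            rhs = Ew.T @ R[:, i] if mask is None else Ew.T @ R0[:, i]
            st.Lambda[i] = _sample_mvn_from_precision(self.rng, prec, rhs)

        # shrinkage locals
        nu = self.spec.priors.shrink_nu
        lam2 = st.Lambda ** 2
        st.phi = self.rng.gamma(0.5 * (nu + 1.0),
                                2.0 / (nu + lam2 * tau[None, :]))
        m = np.sum(st.phi * lam2, axis=0)                      # per factor
        a1, a2 = self.spec.priors.shrink_a1, self.spec.priors.shrink_a2
        for h in range(H):
            tau_excl = np.cumprod(np.where(np.arange(H) == h, 1.0, st.delta))
            shape = (a1 if h == 0 else a2) + 0.5 * S * (H - h)
            rate = 1.0 + 0.5 * np.sum(tau_excl[h:] * m[h:])
            st.delta[h] = self.rng.gamma(shape, 1.0 / rate)

    def update_overdispersion(self) -> None:
        """Inverse-gamma refresh of each species' overdispersion variance."""
        if self.spec.fix_sigma2 is not None:
            return
        g = self.linear_predictor(2)
        mask = self.data.cond_mask
        e2 = np.where(mask, (self.L - g) ** 2, 0.0).sum(axis=0)
        shape = self.spec.priors.sigma2_shape + 0.5 * self._n_i
        rate = self.spec.priors.sigma2_rate + 0.5 * e2
        self.sigma2 = rate / self.rng.gamma(shape, 1.0)

    # -- schedule ----------------------------------------------------------

    def sweep(self) -> None:
        """One full Gibbs sweep over both submodels."""
        self.update_probit_latents()
        self.update_coefficients(1)
        self.update_rho(1)
        self.update_factors(1)
        self.update_lograte_latents()
        self.update_coefficients(2)
        self.update_rho(2)
        self.update_factors(2)
        self.update_overdispersion()

    # -- prior simulation (generative direction) ---------------------------

    def draw_state_from_prior(self) -> None:
        """Replace the whole parameter state by a draw from the prior."""
        rng = self.rng
        for st in (self.m1, self.m2):
            if self.spec.fix_gamma is None:
                st.Gamma = rng.normal(
                    0.0, np.sqrt(self.spec.priors.gamma_var),
                    size=(self.p, self.q))
            if self.spec.fix_V is None:
                st.V = np.atleast_2d(invwishart.rvs(
                    df=self.v_df, scale=self.v_scale, random_state=rng))
            if self.spec.fix_rho is None:
                st.rho = float(rng.choice(self.spec.rho_grid))
            if self.H:
                a1, a2 = self.spec.priors.shrink_a1, self.spec.priors.shrink_a2
                nu = self.spec.priors.shrink_nu
                st.delta = rng.gamma(
                    np.where(np.arange(self.H) == 0, a1, a2), 1.0)
                st.phi = rng.gamma(0.5 * nu, 2.0 / nu,
                                   size=(self.S, self.H))
                sd = 1.0 / np.sqrt(st.phi * st.tau[None, :])
                st.Lambda = rng.normal(0.0, sd)
                st.Eta = rng.standard_normal((self.n_sites, self.H))
            Winv, _ = self._Winv_logdet(st.rho)     # validates rho
            w = st.rho * self._C_eigval + (1.0 - st.rho)
            rootW = (self._C_eigvec * np.sqrt(w)) @ self._C_eigvec.T
            rootV = cholesky(st.V, lower=True)
            st.B = st.Gamma @ self.data.T.T + \
                rootV @ rng.standard_normal((self.p, self.S)) @ rootW.T
        if self.spec.fix_sigma2 is None:
            self.sigma2 = self.spec.priors.sigma2_rate / rng.gamma(
                self.spec.priors.sigma2_shape, 1.0, size=self.S)

    def resimulate_data(self) -> None:
        """Redraw (Z, Y_occ) and (L, Y_cond) from the current parameters.

        Together with ``sweep`` this forms the successive-conditional
        transition used in joint-distribution (Geweke-style) validation.
        """
        rng = self.rng
        m1 = self.linear_predictor(1)
        self.Z = m1 + rng.standard_normal(m1.shape)
        y_occ = (self.Z > 0).astype(np.int8)
        m2 = self.linear_predictor(2)
        L = m2 + rng.standard_normal(m2.shape) * np.sqrt(self.sigma2)[None, :]
        with np.errstate(over="raise"):
            lam = np.exp(L)
        counts = rng.poisson(lam)
        mask = y_occ.astype(bool)
        self.L = np.where(mask, L, 0.0)
        self.data.Y_occ = y_occ
        self.data.cond_mask = mask
        self.data.Y_cond = np.where(mask, counts.astype(float), np.nan)
        self._refresh_mask()

    def check_finite(self, iteration: int) -> None:
        for name, arr in (("B1", self.m1.B), ("B2", self.m2.B),
                          ("sigma2", self.sigma2)):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite {name} at iteration {iteration}")

    def snapshot(self) -> dict[str, np.ndarray]:
        return {
            "B1": self.m1.B.copy(), "Gamma1": self.m1.Gamma.copy(),
            "V1": self.m1.V.copy(), "rho1": np.float64(self.m1.rho),
            "Lambda1": self.m1.Lambda.copy(), "Eta1": self.m1.Eta.copy(),
            "B2": self.m2.B.copy(), "Gamma2": self.m2.Gamma.copy(),
            "V2": self.m2.V.copy(), "rho2": np.float64(self.m2.rho),
            "Lambda2": self.m2.Lambda.copy(), "Eta2": self.m2.Eta.copy(),
            "sigma2": self.sigma2.copy(),
        }


def fit(data: ModelData, spec: ModelSpec,
        progress: "callable | None" = None) -> PosteriorSamples:
    """Run the full Gibbs schedule and return retained posterior draws.

    ``progress``, if given, is called every 100 sweeps with
    ``(iteration, info_dict)`` — used by the CLI for chain logging.
    Identical data, spec and seed give bit-identical output.
    """
    sampler = GibbsSampler(data, spec)
    keep = []
    for it in range(spec.n_iter):
        sampler.sweep()
        if (it + 1) % 200 == 0 or it == spec.n_iter - 1:
            sampler.check_finite(it + 1)
        if progress is not None and (it + 1) % 100 == 0:
            progress(it + 1, {
                "rho1": sampler.m1.rho, "rho2": sampler.m2.rho,
                "lambda1_norm": float(np.linalg.norm(sampler.m1.Lambda)),
                "lambda2_norm": float(np.linalg.norm(sampler.m2.Lambda)),
            })
        if it >= spec.n_burnin and (it - spec.n_burnin) % spec.thin == 0:
            keep.append(sampler.snapshot())
    draws = {k: np.stack([snap[k] for snap in keep])
             for k in keep[0]}
    return PosteriorSamples(draws=draws, species_ids=list(data.species_ids),
                            site_ids=list(data.site_ids),
                            design_columns=list(data.design_columns),
                            seed=spec.seed, spec_hash=spec.spec_hash(),
                            spec=spec.to_jsonable())
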