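"""Bivariate single-step animal model.

Two breed-traits y1, y2 are modelled jointly:

    y_t = X_t beta_t + Z_t a_t + e_t,      t = 1, 2
    (a_1, a_2) ~ N(0, G0 (x) H),           e_t ~ N(0, I sigma2_e_t)

where G0 is the 2x2 additive-genetic (co)variance matrix, H the combined
pedigree-genomic relationship matrix, and the two residual vectors are
independent (the breeds are phenotyped in disjoint herds, so there is no
residual covariance).  Every animal carries breeding values for *both*
traits; the trait it has no records for is informed only through H and the
genetic covariance — this is the channel by which the other breed's
reference animals contribute.

Variance components and breeding values are drawn by a single-site
systematic-scan Gibbs sampler: location parameters from their univariate
normal full conditionals (flat priors on fixed effects), the genetic matrix
from an inverted-Wishart with the a' H^-1 a quadratic form in its scale, and
each residual variance from a scaled inverse chi-square over that trait's
observed records.  A direct dense solve of the mixed-model equations
(``solve_mme``) is provided as the fixed-variance oracle.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import linalg
from sklearn.base import BaseEstimator

DEFAULT_FACTORS = ("farm", "year_class", "season", "parity")


@dataclass
class VarianceComponents:
    """Genetic 2x2 matrix and per-trait residual variances."""

    genetic: np.ndarray
    residual: np.ndarray

    def __post_init__(self):
        self.genetic = np.asarray(self.genetic, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.genetic.shape != (2, 2):
            raise ValueError("genetic matrix must be 2x2")
        if not np.allclose(self.genetic, self.genetic.T):
            raise ValueError("genetic matrix must be symmetric")
        if (self.residual <= 0).any():
            raise ValueError("residual variances must be positive")

    @property
    def sigma_a2(self) -> np.ndarray:
        return np.diag(self.genetic)

    @property
    def sigma_a12(self) -> float:
        return float(self.genetic[0, 1])

    def genetic_correlation(self) -> float:
        d = np.sqrt(self.genetic[0, 0] * self.genetic[1, 1])
        return float(self.genetic[0, 1] / d) if d > 0 else np.nan

    def h2(self) -> np.ndarray:
        return self.sigma_a2 / (self.sigma_a2 + self.residual)

    def is_pd(self) -> bool:
        return bool(np.all(np.linalg.eigvalsh(self.genetic) > 0))


@dataclass
class GibbsConfig:
    """Chain settings; the classical defaults are 100,000 / 10,000 / 50."""

    chain_length: int = 100_000
    burn_in: int = 10_000
    thin: int = 50
    seed: int | None = None
    n_location_scans: int = 1
    nu_genetic: float = 4.0
    genetic_scale_frac: float = 0.3
    nu_residual: float = 4.0
    residual_scale_frac: float = 0.5

    def __post_init__(self):
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be < chain_length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.chain_length - self.burn_in) // self.thin


@dataclass
class ModelSpec:
    """Trait pair and fixed-effect factors of the bivariate model."""

    traits: tuple
    fixed_factors: tuple = DEFAULT_FACTORS

    def __post_init__(self):
        if len(self.traits) != 2:
            raise ValueError("the model is bivariate: exactly two traits")


@dataclass
class DesignMatrices:
    """Per-trait design: y, full-rank X (intercept + drop-first dummies), record->animal."""

    y: list
    X: list
    rec_animal: list
    x_columns: list
    n_animals: int


def build_design(phenotypes: pd.DataFrame, spec: ModelSpec, animal_ids) -> DesignMatrices:
    """Build (y, X, Z) per trait with first-level-reference dummy coding.

    ``animal_ids`` fixes the global animal ordering; Z is returned as the
    record -> animal index vector (each record maps to the breeding value of
    its own trait).  A record naming an animal outside ``animal_ids`` is an
    error.
    """
    pos = {a: i for i, a in enumerate(animal_ids)}
    ys, Xs, recs, cols = [], [], [], []
    for trait in spec.traits:
        sub = phenotypes[phenotypes["trait"] == trait].reset_index(drop=True)
        unknown = [a for a in sub["animal"] if a not in pos]
        if unknown:
            raise ValueError(f"phenotype records reference unknown animals: {unknown[:5]}")
        y = sub["value"].to_numpy(dtype=float)
        blocks = [np.ones((len(sub), 1))]
        names = ["intercept"]
        for factor in spec.fixed_factors:
            dummies = pd.get_dummies(sub[factor].astype("category"), prefix=factor,
                                     drop_first=True, dtype=float)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy())
                names.extend(dummies.columns)
        X = np.hstack(blocks)
        # rank guard: confounded level patterns (e.g. year classes that are an
        # exact function of other factors on the observed support) are dropped
        if X.shape[1] > 1:
            _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps
            rank = int((diag > tol).sum())
            if rank < X.shape[1]:
                keep = np.sort(piv[:rank])
                dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep)]
                warnings.warn(f"dropping collinear fixed-effect columns for trait "
                              f"{trait}: {dropped}", stacklevel=2)
                X = X[:, keep]
                names = [names[j] for j in keep]
        Xs.append(X)
        ys.append(y)
        recs.append(np.array([pos[a] for a in sub["animal"]], dtype=np.int64))
        cols.append(names)
    return DesignMatrices(y=ys, X=Xs, rec_animal=recs, x_columns=cols,
                          n_animals=len(animal_ids))


def solve_mme(design: DesignMatrices, H_inv: np.ndarray, vc: VarianceComponents):
    """Direct dense solve of the two-trait mixed-model equations.

    Returns (betas, a) with ``a`` of shape (2, n_animals): BLUP breeding
    values for every animal on both traits.
    """
    if not vc.is_pd():
        raise ValueError("genetic matrix must be positive definite")
    n = design.n_animals
    p1, p2 = design.X[0].shape[1], design.X[1].shape[1]
    size = p1 + p2 + 2 * n
    off = [0, p1, p1 + p2, p1 + p2 + n]
    C = np.zeros((size, size))
    rhs = np.zeros(size)
    G0inv = np.linalg.inv(vc.genetic)
    for t in range(2):
        X = design.X[t]
        y = design.y[t]
        ra = design.rec_animal[t]
        se = vc.residual[t]
        ob, oa = off[t], off[2 + t]
        C[ob:ob + X.shape[1], ob:ob + X.shape[1]] += X.T @ X / se
        rhs[ob:ob + X.shape[1]] += X.T @ y / se
        # Z'Z is diagonal in record counts; X'Z scatters columns to animals
        np.add.at(C, (np.arange(oa, oa + n), np.arange(oa, oa + n)),
                  np.bincount(ra, minlength=n) / se)
        XtZ = np.zeros((X.shape[1], n))
        np.add.at(XtZ.T, ra, X / se)
        C[ob:ob + X.shape[1], oa:oa + n] += XtZ
        C[oa:oa + n, ob:ob + X.shape[1]] += XtZ.T
        zy = np.bincount(ra, weights=y, minlength=n)
        rhs[oa:oa + n] += zy / se
    for t in range(2):
        for s in range(2):
            C[off[2 + t]:off[2 + t] + n, off[2 + s]:off[2 + s] + n] += G0inv[t, s] * H_inv
    try:
        sol = linalg.solve(C, rhs, assume_a="sym")
    except linalg.LinAlgError as err:
        rank = np.linalg.matrix_rank(C)
        raise np.linalg.LinAlgError(
            f"singular mixed-model equations: rank {rank} < size {size}") from err
    betas = [sol[off[0]:off[0] + p1], sol[off[1]:off[1] + p2]]
    a = np.vstack([sol[off[2]:off[2] + n], sol[off[3]:off[3] + n]])
    return betas, a


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_scan(X1, X2, xtx1, xtx2, e1, e2, beta1, beta2,
                indptr1, recs1, indptr2, recs2,
                a, Hinv, G0inv, se1, se2, rnd):
    """One systematic scan over all location parameters (in place)."""
    p1 = beta1.shape[0]
    p2 = beta2.shape[0]
    n = a.shape[1]
    for k in range(p1):
        lhs = xtx1[k] / se1
        if lhs <= 0.0:
            continue
        rhs = 0.0
        for r in range(e1.shape[0]):
            rhs += X1[r, k] * e1[r]
        rhs = rhs / se1 + lhs * beta1[k]
        new = rhs / lhs + rnd[k] / np.sqrt(lhs)
        diff = new - beta1[k]
        for r in range(e1.shape[0]):
            e1[r] -= X1[r, k] * diff
        beta1[k] = new
    for k in range(p2):
        lhs = xtx2[k] / se2
        if lhs <= 0.0:
            continue
        rhs = 0.0
        for r in range(e2.shape[0]):
            rhs += X2[r, k] * e2[r]
        rhs = rhs / se2 + lhs * beta2[k]
        new = rhs / lhs + rnd[p1 + k] / np.sqrt(lhs)
        diff = new - beta2[k]
        for r in range(e2.shape[0]):
            e2[r] -= X2[r, k] * diff
        beta2[k] = new
    for i in range(n):
        for t in range(2):
            h0 = 0.0
            h1 = 0.0
            for j in range(n):
                h0 += Hinv[i, j] * a[0, j]
                h1 += Hinv[i, j] * a[1, j]
            ct = G0inv[t, 0] * h0 + G0inv[t, 1] * h1
            prior_prec = G0inv[t, t] * Hinv[i, i]
            prior_rhs = -(ct - prior_prec * a[t, i])
            if t == 0:
                indptr, recs, e, se = indptr1, recs1, e1, se1
            else:
                indptr, recs, e, se = indptr2, recs2, e2, se2
            nrec = indptr[i + 1] - indptr[i]
            drhs = 0.0
            for q in range(indptr[i], indptr[i + 1]):
                drhs += e[recs[q]]
            drhs = drhs / se + nrec * a[t, i] / se
            lhs = nrec / se + prior_prec
            new = (drhs + prior_rhs) / lhs + rnd[p1 + p2 + 2 * i + t] / np.sqrt(lhs)
            diff = new - a[t, i]
            for q in range(indptr[i], indptr[i + 1]):
                e[recs[q]] -= diff
            a[t, i] = new


def _records_csr(rec_animal: np.ndarray, n: int):
    order = np.argsort(rec_animal, kind="stable")
    counts = np.bincount(rec_animal, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    return indptr, order.astype(np.int64)


def _sample_inv_wishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale) via a Bartlett-decomposed Wishart of the inverse scale."""
    p = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.normal()
    W = L @ A @ A.T @ L.T
    return np.linalg.inv(W)


@dataclass
class GibbsResult:
    """Posterior summaries from the retained Gibbs samples."""

    vc_chain: pd.DataFrame
    beta_mean: list
    beta_sd: list
    a_mean: np.ndarray
    a_sd: np.ndarray
    n_retained: int
    vc_mean: VarianceComponents = None
    geweke: dict = field(default_factory=dict)
    a_batch_means: np.ndarray = None  # (n_batches, 2, n)

    def mc_se_a(self) -> np.ndarray:
        """Monte-Carlo SE of the posterior-mean breeding values.

        Uses batch means over the retained draws, which stays honest when
        thinned draws are still autocorrelated; falls back to the naive
        sd/sqrt(n) when batches are unavailable.
        """
        if self.a_batch_means is not None and self.a_batch_means.shape[0] >= 2:
            b = self.a_batch_means.shape[0]
            return self.a_batch_means.std(axis=0, ddof=1) / np.sqrt(b)
        return self.a_sd / np.sqrt(self.n_retained)


def gibbs_sample(design: DesignMatrices, H_inv: np.ndarray, config: GibbsConfig,
                 fixed_vc: VarianceComponents | None = None,
                 vc_init: VarianceComponents | None = None) -> GibbsResult:
    """Run the bivariate Gibbs sampler.

    ``fixed_vc`` freezes the (co)variances (location-only sampling, used for
    the BLUP-equivalence oracle check).  Same config + seed gives identical
    chains.
    """
    rng = np.random.default_rng(config.seed)
    n = design.n_animals
    p1, p2 = design.X[0].shape[1], design.X[1].shape[1]
    X1, X2 = np.ascontiguousarray(design.X[0]), np.ascontiguousarray(design.X[1])
    xtx1 = (X1 * X1).sum(axis=0)
    xtx2 = (X2 * X2).sum(axis=0)
    indptr1, recs1 = _records_csr(design.rec_animal[0], n)
    indptr2, recs2 = _records_csr(design.rec_animal[1], n)
    nrec = [len(design.y[0]), len(design.y[1])]
    vp = [float(np.var(design.y[t])) if nrec[t] > 1 else 1.0 for t in range(2)]
    vp = [v if v > 0 else 1.0 for v in vp]

    # priors: IW(nu, S0) genetic, scaled-inv-chi2(nu, s0) residual
    nu_g = config.nu_genetic
    S0 = np.diag([config.genetic_scale_frac * v for v in vp])
    nu_e = config.nu_residual
    s0_e = [config.residual_scale_frac * v for v in vp]

    if fixed_vc is not None:
        vc = fixed_vc
    elif vc_init is not None:
        vc = vc_init
    else:
        vc = VarianceComponents(genetic=S0.copy(), residual=np.array(s0_e))
    G0 = vc.genetic.copy()
    se = vc.residual.copy()

    beta1 = np.zeros(p1)
    beta2 = np.zeros(p2)
    a = np.zeros((2, n))
    e1 = design.y[0].copy()
    e2 = design.y[1].copy()
    Hinv = np.ascontiguousarray(H_inv)

    n_keep = config.n_retained
    vc_rows = np.empty((n_keep, 5))
    beta_sum = [np.zeros(p1), np.zeros(p2)]
    beta_ssq = [np.zeros(p1), np.zeros(p2)]
    a_sum = np.zeros((2, n))
    a_ssq = np.zeros((2, n))
    n_batches = min(25, n_keep)
    batch_sums = np.zeros((n_batches, 2, n))
    batch_counts = np.zeros(n_batches, dtype=int)
    kept = 0

    n_rnd = p1 + p2 + 2 * n
    for it in range(1, config.chain_length + 1):
        G0inv = np.linalg.inv(G0)
        # extra location scans per iteration decorrelate a from the variance
        # draws and shorten the autocorrelation time of the VC chain
        for _ in range(max(1, config.n_location_scans)):
            rnd = rng.standard_normal(n_rnd)
            _gibbs_scan(X1, X2, xtx1, xtx2, e1, e2, beta1, beta2,
                        indptr1, recs1, indptr2, recs2,
                        a, Hinv, G0inv, se[0], se[1], rnd)
        if fixed_vc is None:
            Sa = a @ Hinv @ a.T
            Sa = (Sa + Sa.T) / 2.0
            for attempt in range(10):
                G0_new = _sample_inv_wishart(rng, nu_g + n, S0 + Sa)
                if np.all(np.linalg.eigvalsh(G0_new) > 0):
                    break
                Sa = Sa + np.eye(2) * (1e-8 * (10 ** attempt) * np.trace(Sa))
            else:  # pragma: no cover - jitter always succeeds in practice
                raise RuntimeError("could not draw a positive-definite genetic matrix")
            G0 = G0_new
            for t, (e, nr) in enumerate(((e1, nrec[0]), (e2, nrec[1]))):
                sse = float(e @ e)
                se[t] = (nu_e * s0_e[t] + sse) / rng.chisquare(nu_e + nr)
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            vc_rows[kept] = (G0[0, 0], G0[0, 1], G0[1, 1], se[0], se[1])
            for t, b in enumerate((beta1, beta2)):
                beta_sum[t] += b
                beta_ssq[t] += b * b
            a_sum += a
            a_ssq += a * a
            bi = min(kept * n_batches // n_keep, n_batches - 1)
            batch_sums[bi] += a
            batch_counts[bi] += 1
            kept += 1

    vc_chain = pd.DataFrame(vc_rows[:kept], columns=[
        "sigma_a2_1", "sigma_a12", "sigma_a2_2", "sigma_e2_1", "sigma_e2_2"])
    beta_mean = [s / kept for s in beta_sum]
    beta_sd = [np.sqrt(np.maximum(q / kept - m**2, 0.0))
               for q, m in zip(beta_ssq, beta_mean)]
    a_mean = a_sum / kept
    a_sd = np.sqrt(np.maximum(a_ssq / kept - a_mean**2, 0.0))
    if fixed_vc is None:
        gm = vc_chain.mean()
        vc_mean = VarianceComponents(
            genetic=np.array([[gm.sigma_a2_1, gm.sigma_a12],
                              [gm.sigma_a12, gm.sigma_a2_2]]),
            residual=np.array([gm.sigma_e2_1, gm.sigma_e2_2]))
    else:
        vc_mean = fixed_vc
    geweke = {}
    if kept >= 20:
        for c in vc_chain.columns:
            geweke[c] = geweke_z(vc_chain[c].to_numpy())
    ok = batch_counts > 0
    batch_means = batch_sums[ok] / batch_counts[ok, None, None]
    return GibbsResult(vc_chain=vc_chain, beta_mean=beta_mean, beta_sd=beta_sd,
                       a_mean=a_mean, a_sd=a_sd, n_retained=kept,
                       vc_mean=vc_mean, geweke=geweke, a_batch_means=batch_means)


# ---------------------------------------------------------------------------
# Heritability and diagnostics
# ---------------------------------------------------------------------------

def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """h2 = sigma_a2 / (sigma_a2 + sigma_e2)."""
    if sigma_e2 <= 0:
        raise ValueError("residual variance must be positive")
    if sigma_a2 < 0:
        raise ValueError("additive variance must be non-negative")
    return sigma_a2 / (sigma_a2 + sigma_e2)


def heritability_se(sigma_a2_draws, sigma_p2_draws, method: str = "empirical") -> float:
    """Standard error of h2 from posterior draws.

    ``empirical`` (default, headline value): sample SD of the per-draw
    ratios sigma_a2/sigma_p2.  ``delta_printed``: the first-order propagation
    formula SE^2 = (sa/sp) [Var(sa)/sa^2 + Var(sp)/sp^2 - Cov(sa,sp)/(sa sp)]
    evaluated at the posterior means — note this variant omits the squared-
    heritability factor and the factor 2 on the covariance term that the
    standard delta method carries; both are reported so the two can be
    compared.
    """
    sa = np.asarray(sigma_a2_draws, dtype=float)
    sp = np.asarray(sigma_p2_draws, dtype=float)
    if sa.size < 2 or sp.size < 2:
        raise ValueError("need at least two posterior draws")
    if method == "empirical":
        return float(np.std(sa / sp, ddof=1))
    if method == "delta_printed":
        ma, mp = sa.mean(), sp.mean()
        va, vp_ = sa.var(ddof=1), sp.var(ddof=1)
        cov = float(np.cov(sa, sp, ddof=1)[0, 1])
        se2 = (ma / mp) * (va / ma**2 + vp_ / mp**2 - cov / (ma * mp))
        return float(np.sqrt(max(se2, 0.0)))
    raise ValueError(f"unknown method {method!r}")


def _long_run_variance(x: np.ndarray) -> float:
    """Bartlett-kernel (Newey-West) estimate of the spectral density at frequency zero."""
    n = x.size
    xc = x - x.mean()
    lag = min(n - 1, max(1, int(4 * (n / 100.0) ** (2.0 / 9.0))))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for l in range(1, lag + 1):
        g = float(xc[l:] @ xc[:-l]) / n
        s += 2.0 * (1.0 - l / (lag + 1.0)) * g
    return max(s, 0.0)


def geweke_z(chain, first: float = 0.10, last: float = 0.50) -> float:
    """Geweke convergence z: early-vs-late segment means over spectral SEs.

    Returns NaN when either segment is degenerate (zero variance).
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 20:
        raise ValueError("chain too short for the Geweke diagnostic (need >= 20)")
    na = int(np.floor(first * x.size))
    nb = int(np.floor(last * x.size))
    xa, xb = x[:na], x[x.size - nb:]
    if xa.std() == 0 or xb.std() == 0:
        return float("nan")
    va = _long_run_variance(xa) / na
    vb = _long_run_variance(xb) / nb
    if va + vb == 0:
        return float("nan")
    return float((xa.mean() - xb.mean()) / np.sqrt(va + vb))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class SingleStepGBLUP(BaseEstimator):
    """Bivariate single-step GBLUP estimator.

    Blends pedigree and genomic relationships into H and fits the two-trait
    animal model by Gibbs sampling.  ``fit`` takes the three linked inputs of
    a genetic evaluation — a phenotype table, a pedigree table and a genotype
    matrix — rather than a plain (X, y) pair.

    Parameters
    ----------
    traits : tuple of str or None
        The two trait labels (order defines trait 1 / trait 2); default is
        their order of first appearance in the phenotype table.
    fixed_factors : tuple of str
        Fixed-effect columns of the phenotype table.
    blend_weight : float
        Weight of A22 in the blended G (guards invertibility).
    chain_length, burn_in, thin : int
        Gibbs chain settings.
    random_state : int or None
        Seed for the sampler.

    Attributes
    ----------
    ids_ : list — global animal ordering (pedigree topological order).
    gebv_ : DataFrame — posterior-mean GEBV per animal for both traits.
    variance_components_ : VarianceComponents — posterior means.
    h2_, h2_se_ : ndarray — per-trait heritability and its empirical SE.
    genetic_correlation_ : float.
    posterior_ : GibbsResult — full chain summaries.
    geweke_ : dict — Geweke z per variance parameter.
    """

    def __init__(self, traits=None, fixed_factors=DEFAULT_FACTORS,
                 blend_weight: float = 0.05, chain_length: int = 5000,
                 burn_in: int = 1000, thin: int = 5, n_location_scans: int = 1,
                 nu_genetic: float = 4.0,
                 genetic_scale_frac: float = 0.3, nu_residual: float = 4.0,
                 residual_scale_frac: float = 0.5, random_state=None):
        self.traits = traits
        self.fixed_factors = fixed_factors
        self.blend_weight = blend_weight
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.thin = thin
        self.n_location_scans = n_location_scans
        self.nu_genetic = nu_genetic
        self.genetic_scale_frac = genetic_scale_frac
        self.nu_residual = nu_residual
        self.residual_scale_frac = residual_scale_frac
        self.random_state = random_state

    def _gibbs_config(self) -> GibbsConfig:
        return GibbsConfig(chain_length=self.chain_length, burn_in=self.burn_in,
                           thin=self.thin, seed=self.random_state,
                           n_location_scans=self.n_location_scans,
                           nu_genetic=self.nu_genetic,
                           genetic_scale_frac=self.genetic_scale_frac,
                           nu_residual=self.nu_residual,
                           residual_scale_frac=self.residual_scale_frac)

    def fit(self, phenotypes: pd.DataFrame, pedigree: pd.DataFrame = None,
            genotypes=None, genotyped_ids=None, H_inv=None, ids=None,
            fixed_vc: VarianceComponents | None = None):
        """Fit from a phenotype table plus either (pedigree, genotypes) or a
        prebuilt (H_inv, ids) pair.

        ``genotypes`` is a :class:`~ssgblup.genio.GenotypeMatrix`;
        ``genotyped_ids`` defaults to all its animals.  ``fixed_vc`` freezes
        the variance components (location-only chain).
        """
        from .relmat import build_relationships

        traits = tuple(self.traits) if self.traits is not None else tuple(
            dict.fromkeys(phenotypes["trait"]))
        spec = ModelSpec(traits=traits, fixed_factors=tuple(self.fixed_factors))
        if H_inv is None:
            if pedigree is None or genotypes is None:
                raise ValueError("provide pedigree + genotypes, or H_inv + ids")
            if genotyped_ids is None:
                genotyped_ids = list(genotypes.animal_ids)
            gsub = genotypes.subset_ids(genotyped_ids)
            # a SNP monomorphic within this genotyped subset adds 0 to both the
            # numerator and the scale of G, so dropping it leaves G unchanged
            freqs = gsub.dosages.mean(axis=0) / 2.0
            poly = (freqs > 0) & (freqs < 1)
            rel = build_relationships(pedigree, gsub.dosages[:, poly], genotyped_ids,
                                      blend_weight=self.blend_weight)
            H_inv, ids = rel.H_inv, rel.ids
        elif ids is None:
            raise ValueError("ids must accompany a prebuilt H_inv")
        design = build_design(phenotypes, spec, ids)
        result = gibbs_sample(design, H_inv, self._gibbs_config(), fixed_vc=fixed_vc)
        self.spec_ = spec
        self.ids_ = list(ids)
        self.posterior_ = result
        self.gebv_ = pd.DataFrame({"animal": self.ids_,
                                   traits[0]: result.a_mean[0],
                                   traits[1]: result.a_mean[1]})
        self.variance_components_ = result.vc_mean
        self.h2_ = result.vc_mean.h2()
        if result.n_retained >= 2 and fixed_vc is None:
            ch = result.vc_chain
            self.h2_se_ = np.array([
                heritability_se(ch["sigma_a2_1"], ch["sigma_a2_1"] + ch["sigma_e2_1"]),
                heritability_se(ch["sigma_a2_2"], ch["sigma_a2_2"] + ch["sigma_e2_2"]),
            ])
        else:
            self.h2_se_ = np.array([np.nan, np.nan])
        self.genetic_correlation_ = result.vc_mean.genetic_correlation()
        self.geweke_ = result.geweke
        self.n_retained_ = result.n_retained
        return self

    def predict(self, animal_ids, trait: int = 0) -> np.ndarray:
        """Posterior-mean GEBVs for ``animal_ids`` on trait index 0 or 1."""
        if not hasattr(self, "gebv_"):
            raise ValueError("estimator is not fitted")
        pos = {a: i for i, a in enumerate(self.ids_)}
        idx = np.array([pos[a] for a in animal_ids])
        return self.posterior_.a_mean[trait, idx]
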