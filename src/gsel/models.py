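"""GBLUP and Bayesian marker-effect models fitted by Gibbs sampling.

Two model families share the same fixed-effect structure
(overall mean + contemporary group + dam age):

* GBLUP: ``y = Xb + Zg + e`` with ``g ~ N(0, G σg²)`` — sampled via the
  eigendecomposition of G so every animal-effect update is diagonal; a
  deterministic :func:`solve_mme` solves the mixed model equations exactly
  for given variance components.
* Marker regression: ``y = Xb + Wm + e`` with W the 2p-centered dosage
  matrix and the prior on each effect chosen by method — per-SNP
  scaled-inv-χ² variance (BayesA), the same with a point mass at zero with
  probability π (BayesB), one shared variance with a point mass (BayesC),
  or the normal–exponential (double-exponential) hierarchy of the Bayesian
  Lasso (BL). π is fixed (0.95 by default for BayesB/C, 0 for BayesA/BL).

Both report posterior-mean fixed effects, GEBVs, variance components and
heritability ``h² = σg²/(σg² + σe²)`` (computed per posterior draw). For
marker models σg² is the realized genomic variance var(Wm) of the draw.
Centering by 2p rather than standardizing keeps the GBLUP↔ridge
equivalence exact when G is built from the same markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from ._samplers import snp_sweep
from .kinship import RelationshipMatrix, blend

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "ModelSpec",
    "DesignSpec",
    "ModelFit",
    "solve_mme",
    "fit_gblup",
    "fit_bayes",
    "predict",
]

METHODS = ("GBLUP", "BayesA", "BayesB", "BayesC", "BL")


@dataclass
class ModelSpec:
    """Method choice, priors and chain settings.

    Prior scales left ``None`` are set automatically so the prior splits the
    phenotypic variance with an expected marker-explained proportion
    ``r2_prior`` (0.5 by default). ``fix_sigma_e2`` pins the residual
    variance (used by prior-recovery diagnostics only).
    """

    method: str = "GBLUP"
    pi: float | None = None  # default: 0.95 for BayesB/C, 0 otherwise
    prior_df_marker: float = 5.0
    prior_scale_marker: float | None = None
    prior_df_resid: float = 5.0
    prior_scale_resid: float | None = None
    lasso_shape: float = 1.1
    lasso_rate: float | None = None
    r2_prior: float = 0.5
    chain_length: int = 20000
    burn_in: int = 5000
    thin: int = 10
    seed: int = 0
    fix_sigma_e2: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.pi is not None and not 0.0 <= self.pi < 1.0:
            raise ValueError("pi must be in [0, 1); pi = 1 is degenerate")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.prior_df_marker <= 0 or self.prior_df_resid <= 0:
            raise ValueError("prior degrees of freedom must be positive")

    @property
    def resolved_pi(self) -> float:
        if self.pi is not None:
            return float(self.pi)
        return 0.95 if self.method in ("BayesB", "BayesC") else 0.0

    def kept_iterations(self) -> np.ndarray:
        return np.arange(self.burn_in, self.chain_length, self.thin)


@dataclass
class DesignSpec:
    """Response vector and fixed-effect incidence matrix.

    Reference-level dummy coding with an explicit intercept; factor levels
    are recorded so validation rows are encoded against the same columns
    (unseen levels map to the reference with a logged warning).
    """

    y: np.ndarray
    X: np.ndarray
    animal_ids: list
    coef_names: list
    factors: tuple
    levels: dict = field(default_factory=dict)

    @classmethod
    def from_phenotypes(
        cls,
        pheno: pd.DataFrame,
        trait: str,
        factors: Sequence[str] = ("cg", "dam_age"),
        id_col: str = "animal_id",
    ) -> "DesignSpec":
        df = pheno.dropna(subset=[trait]).reset_index(drop=True)
        levels = {f: sorted(map(str, df[f].unique())) for f in factors}
        spec = cls(
            y=df[trait].to_numpy(dtype=float),
            X=np.empty((len(df), 0)),
            animal_ids=[str(a) for a in df[id_col]],
            coef_names=[],
            factors=tuple(factors),
            levels=levels,
        )
        spec.X, spec.coef_names = spec._encode(df)
        rank = np.linalg.matrix_rank(spec.X)
        if rank < spec.X.shape[1]:
            logger.warning(
                "design matrix rank %d < %d columns (empty factor level?)",
                rank, spec.X.shape[1],
            )
        return spec

    def _encode(self, df: pd.DataFrame) -> tuple[np.ndarray, list]:
        n = len(df)
        cols = [np.ones(n)]
        names = ["intercept"]
        for f in self.factors:
            vals = df[f].astype(str).to_numpy()
            known = set(self.levels[f])
            unseen = sorted(set(vals) - known)
            if unseen:
                logger.warning(
                    "factor %r: unseen level(s) %s mapped to reference %r",
                    f, unseen, self.levels[f][0],
                )
            for lev in self.levels[f][1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{f}[{lev}]")
        return np.column_stack(cols), names

    def encode(self, pheno_rows: pd.DataFrame) -> np.ndarray:
        """Incidence matrix for new rows using the training factor levels."""
        X, _ = self._encode(pheno_rows.reset_index(drop=True))
        return X

    def subset(self, idx: np.ndarray) -> "DesignSpec":
        idx = np.asarray(idx)
        return DesignSpec(
            y=self.y[idx],
            X=self.X[idx],
            animal_ids=[self.animal_ids[i] for i in idx],
            coef_names=list(self.coef_names),
            factors=self.factors,
            levels=dict(self.levels),
        )

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class ModelFit:
    """Posterior summaries of one fitted model."""

    method: str
    spec: ModelSpec
    animal_ids: list
    coef_names: list
    b_mean: np.ndarray
    b_sd: np.ndarray
    gebv: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    traces: dict
    marker_effects: np.ndarray | None = None
    inclusion_prob: np.ndarray | None = None
    snp_freq: np.ndarray | None = None
    _G_train: np.ndarray | None = None
    _alpha: np.ndarray | None = None

    def gebv_series(self) -> pd.Series:
        return pd.Series(self.gebv, index=[str(a) for a in self.animal_ids])


def _check_finite(step: int, **values) -> None:
    for name, v in values.items():
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"chain diverged: non-finite {name} at iteration {step}"
            )


def _scaled_inv_chi2(rng, df: float, scale_times_df: float) -> float:
    return scale_times_df / rng.chisquare(df)


def _auto_scale(var_y: float, r2: float, df: float) -> float:
    # match the prior mean of a scaled-inv-chi2(df, S), df*S/(df-2), to the
    # targeted variance share; fall back to the share itself for small df
    target = var_y * r2
    return target * (df - 2.0) / df if df > 2.0 else target


def _sample_b(rng, X, XtX, r_full, sigma_e2, var_b_prior):
    q = X.shape[1]
    A = XtX + (sigma_e2 / var_b_prior) * np.eye(q)
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, X.T @ r_full)
    z = rng.standard_normal(q)
    return mean + np.sqrt(sigma_e2) * scipy.linalg.solve_triangular(
        L.T, z, lower=False
    )


def solve_mme(
    X: np.ndarray,
    y: np.ndarray,
    G: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    Z: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mixed-model-equation solve for given variance components.

    Solves ``[XᵀX, XᵀZ; ZᵀX, ZᵀZ + G⁻¹ σe²/σg²] [b; g] = [Xᵀy; Zᵀy]``.
    """
    n = len(y)
    Z = np.eye(n) if Z is None else Z
    lam = sigma_e2 / sigma_g2
    Ginv = np.linalg.inv(G)
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + Ginv * lam])
    C = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(C, rhs)
    q = X.shape[1]
    return sol[:q], sol[q:]


def fit_gblup(
    design: DesignSpec,
    G: RelationshipMatrix | np.ndarray,
    spec: ModelSpec,
    blend_weight: float = 0.01,
) -> ModelFit:
    """Gibbs sampler for the GBLUP animal model.

    G is blended toward the identity (``blend_weight``) and
    eigendecomposed once; in the rotated basis the animal-effect update is
    diagonal. Variance components get scaled-inv-χ² priors.
    """
    if isinstance(G, RelationshipMatrix):
        Gm = G.submatrix(design.animal_ids).values
    else:
        Gm = np.asarray(G, dtype=float)
        if Gm.shape != (design.n, design.n):
            raise ValueError("G dimension does not match design")
    Gb = blend(Gm, blend_weight)
    lam_eig, U = np.linalg.eigh(Gb)
    if lam_eig.min() <= 1e-10:
        raise np.linalg.LinAlgError(
            f"G not positive definite after blending (min eigenvalue "
            f"{lam_eig.min():.2e})"
        )

    y, X = design.y, design.X
    n = design.n
    rng = np.random.default_rng(spec.seed)
    var_y = float(np.var(y))
    r2 = spec.r2_prior
    nu_g, nu_e = spec.prior_df_marker, spec.prior_df_resid
    Sg = spec.prior_scale_marker or _auto_scale(var_y, r2, nu_g)
    Se = spec.prior_scale_resid or _auto_scale(var_y, 1.0 - r2, nu_e)
    var_b_prior = 1e6 * max(var_y, 1e-12)

    XtX = X.T @ X
    sigma_g2 = max(var_y * r2, 1e-12)
    sigma_e2 = spec.fix_sigma_e2 or max(var_y * (1.0 - r2), 1e-12)
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    a = np.zeros(n)

    kept = spec.kept_iterations()
    n_keep = len(kept)
    tr = {k: np.empty(n_keep) for k in ("sigma_g2", "sigma_e2", "h2")}
    g_sum = np.zeros(n)
    b_sum = np.zeros(X.shape[1])
    b_sumsq = np.zeros(X.shape[1])
    keep_ptr = 0

    for it in range(spec.chain_length):
        Uty = U.T @ (y - X @ b)
        d = 1.0 / (1.0 / sigma_e2 + 1.0 / (sigma_g2 * lam_eig))
        a = d * Uty / sigma_e2 + np.sqrt(d) * rng.standard_normal(n)
        g = U @ a
        b = _sample_b(rng, X, XtX, y - g, sigma_e2, var_b_prior)
        sigma_g2 = _scaled_inv_chi2(
            rng, nu_g + n, nu_g * Sg + float(np.sum(a * a / lam_eig))
        )
        resid = y - X @ b - g
        if spec.fix_sigma_e2 is None:
            sigma_e2 = _scaled_inv_chi2(
                rng, nu_e + n, nu_e * Se + float(resid @ resid)
            )
        _check_finite(it, sigma_g2=sigma_g2, sigma_e2=sigma_e2, b=b)
        if keep_ptr < n_keep and it == kept[keep_ptr]:
            tr["sigma_g2"][keep_ptr] = sigma_g2
            tr["sigma_e2"][keep_ptr] = sigma_e2
            tr["h2"][keep_ptr] = sigma_g2 / (sigma_g2 + sigma_e2)
            g_sum += g
            b_sum += b
            b_sumsq += b * b
            keep_ptr += 1

    gebv = g_sum / n_keep
    b_mean = b_sum / n_keep
    b_sd = np.sqrt(np.maximum(b_sumsq / n_keep - b_mean**2, 0.0))
    return ModelFit(
        method="GBLUP",
        spec=spec,
        animal_ids=list(design.animal_ids),
        coef_names=list(design.coef_names),
        b_mean=b_mean,
        b_sd=b_sd,
        gebv=gebv,
        sigma_g2=float(tr["sigma_g2"].mean()),
        sigma_e2=float(tr["sigma_e2"].mean()),
        h2=float(tr["h2"].mean()),
        traces=tr,
        _G_train=Gb,
        _alpha=np.linalg.solve(Gb, gebv),
    )


def fit_bayes(
    design: DesignSpec,
    markers: np.ndarray,
    spec: ModelSpec,
    freqs: np.ndarray | None = None,
) -> ModelFit:
    """Single-site Gibbs sampler for BayesA/B/C and the Bayesian Lasso.

    ``markers`` is the raw dosage matrix for the design's animals; columns
    are centered by twice the allele frequency (recomputed from the
    training animals unless ``freqs`` is given, and retained so validation
    GEBVs use the same centering).
    """
    if spec.method == "GBLUP":
        raise ValueError("use fit_gblup for the GBLUP method")
    M = np.asarray(markers, dtype=float)
    if M.shape[0] != design.n:
        raise ValueError("marker rows do not match design animals")
    if np.isnan(M).any():
        raise ValueError("marker matrix contains missing values; impute first")
    y, X = design.y, design.X
    n, p = M.shape
    pi = spec.resolved_pi
    freqs = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    W = M - 2.0 * freqs
    Wt = np.ascontiguousarray(W.T)
    wtw = np.einsum("ij,ij->j", W, W)

    rng = np.random.default_rng(spec.seed)
    var_y = float(np.var(y))
    nu, nu_e = spec.prior_df_marker, spec.prior_df_resid
    msx = float(wtw.sum()) / n  # Σ_j var(w_j): per-unit-m genomic variance
    if spec.prior_scale_marker is not None:
        S = spec.prior_scale_marker
    else:
        share = var_y * spec.r2_prior / max((1.0 - pi) * msx, 1e-12)
        S = share * (nu - 2.0) / nu if nu > 2.0 else share
    Se = spec.prior_scale_resid or _auto_scale(var_y, 1.0 - spec.r2_prior, nu_e)
    var_b_prior = 1e6 * max(var_y, 1e-12)

    is_bl = spec.method == "BL"
    if is_bl:
        sigma_e2_0 = spec.fix_sigma_e2 or var_y * (1.0 - spec.r2_prior)
        lam2_0 = 2.0 * sigma_e2_0 * msx / max(var_y * spec.r2_prior, 1e-12)
        shape = spec.lasso_shape
        rate = spec.lasso_rate or shape / lam2_0
        lam2 = lam2_0
        tau2 = np.full(p, 2.0 / lam2)

    XtX = X.T @ X
    sigma_e2 = spec.fix_sigma_e2 or max(var_y * (1.0 - spec.r2_prior), 1e-12)
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    m = np.zeros(p)
    delta = np.zeros(p, dtype=np.uint8) if pi > 0 else np.ones(p, dtype=np.uint8)
    var_m = np.full(p, S)
    sigma2_m = S  # BayesC shared variance
    r = y - X @ b

    kept = spec.kept_iterations()
    n_keep = len(kept)
    tr_keys = ["sigma_g2", "sigma_e2", "h2", "marker_var0"]
    if is_bl:
        tr_keys.append("lambda2")
    tr = {k: np.empty(n_keep) for k in tr_keys}
    m_sum = np.zeros(p)
    delta_sum = np.zeros(p)
    g_sum = np.zeros(n)
    b_sum = np.zeros(X.shape[1])
    b_sumsq = np.zeros(X.shape[1])
    keep_ptr = 0

    for it in range(spec.chain_length):
        # fixed effects
        r_full = r + X @ b
        b_new = _sample_b(rng, X, XtX, r_full, sigma_e2, var_b_prior)
        r = r_full - X @ b_new
        b = b_new

        # marker sweep
        if spec.method == "BayesC":
            var_eff = np.full(p, sigma2_m)
        elif is_bl:
            var_eff = tau2 * sigma_e2
        else:
            var_eff = var_m
        z = rng.standard_normal(p)
        u = rng.random(p)
        snp_sweep(Wt, wtw, r, m, delta, var_eff, sigma_e2, pi, z, u)

        # marker-variance updates
        if spec.method == "BayesA":
            var_m = (nu * S + m * m) / rng.chisquare(nu + 1.0, size=p)
        elif spec.method == "BayesB":
            inc = delta == 1
            chi_inc = rng.chisquare(nu + 1.0, size=p)
            chi_exc = rng.chisquare(nu, size=p)
            var_m = np.where(
                inc, (nu * S + m * m) / chi_inc, (nu * S) / chi_exc
            )
        elif spec.method == "BayesC":
            inc = delta == 1
            q_inc = int(inc.sum())
            sigma2_m = _scaled_inv_chi2(
                rng, nu + q_inc, nu * S + float(np.sum(m[inc] ** 2))
            )
        else:  # BL
            m2 = m * m
            tiny = m2 < 1e-12 * sigma_e2
            mu_ig = np.sqrt(lam2 * sigma_e2 / np.where(tiny, 1.0, m2))
            inv_tau2 = rng.wald(mu_ig, lam2)
            tau2 = 1.0 / inv_tau2
            if tiny.any():
                tau2[tiny] = rng.exponential(2.0 / lam2, size=int(tiny.sum()))
            lam2 = rng.gamma(shape + p, 1.0 / (rate + float(tau2.sum()) / 2.0))

        # residual variance
        if spec.fix_sigma_e2 is None:
            ss = float(r @ r)
            df = nu_e + n
            if is_bl:
                ss += float(np.sum(m * m / tau2))
                df += p
            sigma_e2 = _scaled_inv_chi2(rng, df, nu_e * Se + ss)
        _check_finite(it, sigma_e2=sigma_e2, m=m, b=b)

        if keep_ptr < n_keep and it == kept[keep_ptr]:
            gvec = y - r - X @ b  # = W (m ⊙ δ)
            var_g = float(np.var(gvec))
            tr["sigma_g2"][keep_ptr] = var_g
            tr["sigma_e2"][keep_ptr] = sigma_e2
            tr["h2"][keep_ptr] = var_g / (var_g + sigma_e2)
            tr["marker_var0"][keep_ptr] = (
                sigma2_m if spec.method == "BayesC"
                else (tau2[0] * sigma_e2 if is_bl else var_m[0])
            )
            if is_bl:
                tr["lambda2"][keep_ptr] = lam2
            m_sum += m
            delta_sum += delta
            g_sum += gvec
            b_sum += b
            b_sumsq += b * b
            keep_ptr += 1

    b_mean = b_sum / n_keep
    b_sd = np.sqrt(np.maximum(b_sumsq / n_keep - b_mean**2, 0.0))
    return ModelFit(
        method=spec.method,
        spec=spec,
        animal_ids=list(design.animal_ids),
        coef_names=list(design.coef_names),
        b_mean=b_mean,
        b_sd=b_sd,
        gebv=g_sum / n_keep,
        sigma_g2=float(tr["sigma_g2"].mean()),
        sigma_e2=float(tr["sigma_e2"].mean()),
        h2=float(tr["h2"].mean()),
        traces=tr,
        marker_effects=m_sum / n_keep,
        inclusion_prob=delta_sum / n_keep,
        snp_freq=freqs,
    )


def predict(
    fit: ModelFit,
    X_new: np.ndarray,
    markers_new: np.ndarray | None = None,
    g_cross: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted phenotypes and GEBVs for new animals.

    Marker models back-solve ``GEBV = W_new m̂`` with W_new centered by the
    training allele frequencies; GBLUP uses the conditional expectation
    ``G_vt G_tt⁻¹ ĝ`` through the cross-relationship block ``g_cross``.
    ``ŷ = X_new b̂ + GEBV``.
    """
    if fit.method == "GBLUP":
        if g_cross is None:
            raise ValueError("GBLUP prediction needs the g_cross block")
        g_cross = np.asarray(g_cross, dtype=float)
        if g_cross.shape[1] != len(fit.gebv):
            raise ValueError(
                f"g_cross has {g_cross.shape[1]} columns, expected "
                f"{len(fit.gebv)} training animals"
            )
        gebv_new = g_cross @ fit._alpha
    else:
        if markers_new is None:
            raise ValueError("marker-model prediction needs marker rows")
        M_new = np.asarray(markers_new, dtype=float)
        if M_new.shape[1] != len(fit.marker_effects):
            raise ValueError(
                f"marker rows have {M_new.shape[1]} SNPs, expected "
                f"{len(fit.marker_effects)}"
            )
        gebv_new = (M_new - 2.0 * fit.snp_freq) @ fit.marker_effects
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape != (len(gebv_new), len(fit.b_mean)):
        raise ValueError("X_new dimensions do not match fit")
    return X_new @ fit.b_mean + gebv_new, gebv_new
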