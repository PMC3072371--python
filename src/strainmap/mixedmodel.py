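"""Kinship estimation and REML linear-mixed-model association testing.

The model is the classic inbred-panel mixed model

    y = X beta + Z u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with y replicate-level phenotypes, Z the animal -> strain incidence matrix
and K a strain x strain identity-by-state kinship matrix. Writing
delta = sigma_e^2 / sigma_g^2, the restricted likelihood is a 1-D function
of delta once H = Z K Z' has been eigendecomposed, so the REML fit reduces
to a grid search over log10(delta) refined by Brent's method, and a
standard F test (Wald on the marker coefficient under the fitted
covariance) scores each marker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import GenotypePanel, PhenotypeTable

log = logging.getLogger("strainmap.mixedmodel")

LOG10_DELTA_RANGE = (-5.0, 5.0)
N_GRID_INTERVALS = 100
BRENT_TOL = 1e-8


# ------------------------------------------------------------------ filters

@dataclass
class FilterResult:
    mask: np.ndarray
    n_total: int
    n_kept: int
    n_fail_maf: int
    n_fail_missing: int


def snp_filters(panel: GenotypePanel, maf_min: float = 0.05,
                missing_max: float = 0.20) -> FilterResult:
    """Keep SNPs with MAF >= maf_min and missing fraction < missing_max."""
    maf = panel.maf()
    miss = panel.missing_fraction()
    ok_maf = np.nan_to_num(maf, nan=0.0) >= maf_min
    ok_miss = miss < missing_max
    mask = ok_maf & ok_miss
    res = FilterResult(
        mask=mask,
        n_total=panel.n_snps,
        n_kept=int(mask.sum()),
        n_fail_maf=int((~ok_maf).sum()),
        n_fail_missing=int((~ok_miss).sum()),
    )
    log.info(
        "SNP filters: %d/%d kept (MAF>=%.3g fails: %d, missing<%.3g fails: %d)",
        res.n_kept, res.n_total, maf_min, res.n_fail_maf, missing_max,
        res.n_fail_missing,
    )
    return res


# ------------------------------------------------------------------ kinship

@dataclass
class KinshipMatrix:
    values: np.ndarray           # (s, s), IBS sharing + jitter on diagonal
    strain_ids: np.ndarray

    def subset(self, strain_ids) -> "KinshipMatrix":
        idx = [int(np.flatnonzero(self.strain_ids == s)[0]) for s in strain_ids]
        return KinshipMatrix(self.values[np.ix_(idx, idx)],
                             np.asarray(strain_ids, dtype=object))


def ibs_kinship(panel: GenotypePanel, snp_mask: Optional[np.ndarray] = None,
                jitter: float = 1e-6) -> KinshipMatrix:
    """Pairwise-complete identity-by-state allele sharing between strains.

    Each cell averages allele agreement over SNPs non-missing in both
    strains; ``jitter * I`` is added to keep the matrix positive
    semi-definite under downstream factorizations.
    """
    G = panel.calls
    if snp_mask is not None:
        G = G[:, snp_mask]
    typed = ~np.isnan(G)
    A1 = np.where(typed, np.nan_to_num(G), 0.0)          # alt indicator
    A0 = np.where(typed, 1.0 - np.nan_to_num(G), 0.0)    # ref indicator
    matches = A1 @ A1.T + A0 @ A0.T
    counts = typed.astype(float) @ typed.astype(float).T
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"strains {panel.strain_ids[i]!r} and {panel.strain_ids[j]!r} "
            "share no jointly typed SNPs"
        )
    K = matches / counts
    K = 0.5 * (K + K.T) + jitter * np.eye(len(K))
    return KinshipMatrix(values=K, strain_ids=panel.strain_ids.copy())


# ------------------------------------------------------------------ REML

@dataclass
class EigenContext:
    """Cached eigendecomposition of H = Z K Z' for one (Z, K) pair."""

    lam: np.ndarray              # (n,) eigenvalues of H
    U: np.ndarray                # (n, n) eigenvectors
    UtZ: np.ndarray              # (n, s) U' Z, for cheap strain-level regressors

    @classmethod
    def build(cls, Z: np.ndarray, K: np.ndarray) -> "EigenContext":
        H = Z @ K @ Z.T
        lam, U = np.linalg.eigh(H)
        lam = np.maximum(lam, 0.0)
        return cls(lam=lam, U=U, UtZ=U.T @ Z)

    def transform(self, v: np.ndarray) -> np.ndarray:
        return self.U.T @ v


@dataclass
class MixedModelFit:
    delta: float
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    beta_hat: np.ndarray
    beta_cov: np.ndarray         # sigma_g2 * (X' V0^-1 X)^-1
    n: int
    rank_x: int
    boundary: bool = False       # delta hit the search-grid edge

    def wald_f(self, j: int) -> tuple[float, float]:
        """F statistic and P-value for fixed-effect coefficient j."""
        F = float(self.beta_hat[j] ** 2 / self.beta_cov[j, j])
        P = float(stats.f.sf(F, 1, self.n - self.rank_x))
        return F, P


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(j)
        raise ValueError(f"X_fixed is rank deficient; collinear column(s): {bad}")


class _RemlProblem:
    """Restricted log-likelihood of delta for fixed (y, X) given eigen(H).

    Cross-products are precomputed per eigen-coordinate so that both the
    scalar likelihood (Brent refinement) and the whole delta grid
    (batched linear algebra) are O(n q^2) per evaluation.
    """

    def __init__(self, yt: np.ndarray, Xt: np.ndarray, lam: np.ndarray,
                 logdet_xx: float):
        self.yt = yt
        self.Xt = Xt
        self.lam = lam
        self.logdet_xx = logdet_xx
        self.n, self.q = Xt.shape
        self._PX = Xt[:, :, None] * Xt[:, None, :]     # (n, q, q)
        self._Py = Xt * yt[:, None]                    # (n, q)
        self._pyy = yt * yt                            # (n,)

    def components(self, delta: float):
        w = 1.0 / (self.lam + delta)
        XtWX = np.einsum("n,nqr->qr", w, self._PX)
        XtWy = w @ self._Py
        yWy = float(w @ self._pyy)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = yWy - float(XtWy @ beta)
        return XtWX, beta, max(rss, 1e-300)

    def loglik(self, delta: float) -> float:
        nq = self.n - self.q
        XtWX, _, rss = self.components(delta)
        sigma_g2 = rss / nq
        logdet_v = float(np.sum(np.log(self.lam + delta)))
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return -np.inf
        return -0.5 * (
            nq * (math.log(2.0 * math.pi * sigma_g2) + 1.0)
            + logdet_v + logdet_xwx - self.logdet_xx
        )

    def grid_logliks(self, deltas: np.ndarray) -> np.ndarray:
        """Restricted log-likelihood at every delta, batched."""
        nq = self.n - self.q
        W = 1.0 / (self.lam[None, :] + deltas[:, None])      # (G, n)
        XtWX = np.einsum("gn,nqr->gqr", W, self._PX)
        XtWy = W @ self._Py
        yWy = W @ self._pyy
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        rss = np.maximum(yWy - np.einsum("gq,gq->g", XtWy, beta), 1e-300)
        sigma_g2 = rss / nq
        logdet_v = np.log(self.lam[None, :] + deltas[:, None]).sum(axis=1)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        out = -0.5 * (nq * (np.log(2.0 * np.pi * sigma_g2) + 1.0)
                      + logdet_v + logdet_xwx - self.logdet_xx)
        out[sign <= 0] = -np.inf
        return out

    def maximize(self) -> tuple[float, float, bool]:
        """Grid over log10(delta) then Brent refinement. Returns
        (delta, loglik, boundary_flag)."""
        lo, hi = LOG10_DELTA_RANGE
        grid = np.linspace(lo, hi, N_GRID_INTERVALS + 1)
        vals = self.grid_logliks(10.0 ** grid)
        i = int(np.argmax(vals))
        if i == 0 or i == len(grid) - 1:
            return 10.0 ** grid[i], float(vals[i]), True
        res = optimize.minimize_scalar(
            lambda g: -self.loglik(10.0 ** g),
            bounds=(grid[i - 1], grid[i + 1]),
            method="bounded",
            options={"xatol": BRENT_TOL},
        )
        best_ll = -float(res.fun)
        # the refined optimum can never fall below the best grid point
        if best_ll < vals[i]:
            return 10.0 ** grid[i], float(vals[i]), False
        return 10.0 ** float(res.x), best_ll, False


def reml_fit(y: np.ndarray, X: np.ndarray, Z: Optional[np.ndarray] = None,
             K: Optional[np.ndarray] = None,
             eig: Optional[EigenContext] = None,
             yt: Optional[np.ndarray] = None,
             Xt: Optional[np.ndarray] = None) -> MixedModelFit:
    """REML variance components for y = X beta + Z u + e.

    Either an :class:`EigenContext` or (Z, K) must be supplied; the
    eigendecomposition is computed once and the restricted likelihood
    maximized over delta = sigma_e^2/sigma_g^2 on a log grid refined by
    Brent's method. ``yt``/``Xt`` may carry pre-rotated (U'y, U'X) to
    avoid repeated transforms in scans.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    _check_full_rank(X)
    if eig is None:
        if Z is None or K is None:
            raise ValueError("supply either eig or both Z and K")
        eig = EigenContext.build(np.asarray(Z, float), np.asarray(K, float))
    if yt is None:
        yt = eig.transform(y)
    if Xt is None:
        Xt = eig.transform(X)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    prob = _RemlProblem(yt, Xt, eig.lam, logdet_xx)
    delta, ll, boundary = prob.maximize()
    XtWX, beta, rss = prob.components(delta)
    n, q = Xt.shape
    sigma_g2 = rss / (n - q)
    sigma_e2 = delta * sigma_g2
    beta_cov = sigma_g2 * np.linalg.inv(XtWX)
    if boundary:
        log.debug("REML delta hit search boundary (delta=%g)", delta)
    return MixedModelFit(
        delta=float(delta), sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2),
        reml_loglik=float(ll), beta_hat=beta, beta_cov=beta_cov,
        n=n, rank_x=q, boundary=boundary,
    )


# ------------------------------------------------------------ marker tests

@dataclass
class AssocTest:
    F: float
    P: float
    fit: Optional[MixedModelFit]
    monomorphic: bool = False


def association_test(y: np.ndarray, snp_strain: np.ndarray, Z: np.ndarray,
                     K: np.ndarray, mode: str = "exact",
                     covariates: Optional[np.ndarray] = None,
                     eig: Optional[EigenContext] = None,
                     null_fit: Optional[MixedModelFit] = None,
                     _pre: Optional[dict] = None) -> AssocTest:
    """Mixed-model F test of one marker.

    Fixed effects are an intercept (plus optional covariates) and the
    strain-level SNP dosage expanded through Z. ``exact`` re-estimates
    delta with the marker in the model; ``approx`` reuses the null-model
    delta (one REML fit per trait), which is the standard speed/accuracy
    trade-off for scans over many molecular traits.
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    snp_strain = np.asarray(snp_strain, dtype=float).ravel()
    if np.isnan(snp_strain).any():
        raise ValueError("snp_strain contains missing calls; subset first")
    if np.nanstd(snp_strain) == 0:
        return AssocTest(F=np.nan, P=np.nan, fit=None, monomorphic=True)
    n = y.size
    g_animal = Z @ snp_strain
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols + [g_animal])
    if eig is None:
        eig = EigenContext.build(Z, np.asarray(K, float))
    if _pre is not None:
        yt = _pre["yt"]
        Xt = np.column_stack([_pre["Ut_base"], eig.UtZ @ snp_strain])
    else:
        yt, Xt = None, None

    if mode == "exact":
        fit = reml_fit(y, X, eig=eig, yt=yt, Xt=Xt)
    elif mode == "approx":
        if null_fit is None:
            null_fit = reml_fit(y, np.column_stack(cols), eig=eig)
        fit = _gls_at_delta(y, X, eig, null_fit.delta, yt=yt, Xt=Xt)
    else:
        raise ValueError(f"unknown mode: {mode}")
    F, P = fit.wald_f(X.shape[1] - 1)
    return AssocTest(F=F, P=P, fit=fit)


def _gls_at_delta(y: np.ndarray, X: np.ndarray, eig: EigenContext,
                  delta: float, yt: Optional[np.ndarray] = None,
                  Xt: Optional[np.ndarray] = None) -> MixedModelFit:
    """Generalized least squares at a fixed delta (EMMAX-style)."""
    _check_full_rank(X)
    if yt is None:
        yt = eig.transform(y)
    if Xt is None:
        Xt = eig.transform(X)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    prob = _RemlProblem(yt, Xt, eig.lam, logdet_xx)
    XtWX, beta, rss = prob.components(delta)
    n, q = Xt.shape
    sigma_g2 = rss / (n - q)
    return MixedModelFit(
        delta=float(delta), sigma_g2=float(sigma_g2),
        sigma_e2=float(delta * sigma_g2), reml_loglik=prob.loglik(delta),
        beta_hat=beta, beta_cov=sigma_g2 * np.linalg.inv(XtWX),
        n=n, rank_x=q,
    )


# ------------------------------------------------------------ genome scan

@dataclass
class AssociationResult:
    table: pd.DataFrame          # snp_id, chrom, pos, maf, n_used, F, P, neglog10P
    trait: str
    metadata: dict = field(default_factory=dict)


def incidence_matrix(strain_of_animal: np.ndarray,
                     strain_ids: np.ndarray) -> np.ndarray:
    """Animals x strains 0/1 incidence (Z)."""
    index = {s: i for i, s in enumerate(strain_ids)}
    Z = np.zeros((len(strain_of_animal), len(strain_ids)))
    for a, s in enumerate(strain_of_animal):
        Z[a, index[s]] = 1.0
    return Z


def genome_scan(pheno: PhenotypeTable, panel: GenotypePanel,
                K: Optional[KinshipMatrix], trait: str, maf_min: float = 0.05,
                missing_max: float = 0.20, mode: str = "exact",
                loco: bool = True,
                snp_mask: Optional[np.ndarray] = None) -> AssociationResult:
    """Filter SNPs and run the mixed-model F test across the genome.

    With ``loco`` (default), markers on each chromosome are tested against
    a kinship built from the *other* chromosomes (leave-one-chromosome-out),
    which prevents the tested marker and its LD block from being absorbed
    into the structure covariance; with few chromosomes each one is a large
    fraction of the genome, so this proximal contamination is otherwise
    severe. Pass ``loco=False`` to use the supplied whole-genome K.
    """
    tf = pheno.trait_frame(trait)
    strains_present = [s for s in panel.strain_ids if s in set(tf["strain_id"])]
    unknown = set(tf["strain_id"]) - set(panel.strain_ids)
    if unknown:
        raise ValueError(f"phenotyped strains absent from panel: {sorted(unknown)[:5]}")
    tf = tf[tf["strain_id"].isin(strains_present)]
    y = tf["value"].to_numpy(float)
    Z = incidence_matrix(tf["strain_id"].to_numpy(object),
                         np.asarray(strains_present, dtype=object))
    filt = snp_filters(panel, maf_min=maf_min, missing_max=missing_max)
    mask = filt.mask if snp_mask is None else (filt.mask & snp_mask)
    strain_idx = [panel.strain_index(s) for s in strains_present]
    G = panel.calls[strain_idx, :]
    if not loco and K is None:
        raise ValueError("supply K when loco=False")

    def context_for(chrom: Optional[str]):
        if loco:
            kin = ibs_kinship(panel, snp_mask=(filt.mask & (panel.chrom != chrom)))
        else:
            kin = K
        Ksub = kin.subset(strains_present)
        eig = EigenContext.build(Z, Ksub.values)
        null = reml_fit(y, np.ones((y.size, 1)), eig=eig) if mode == "approx" else None
        pre = {"yt": eig.transform(y),
               "Ut_base": eig.transform(np.ones((y.size, 1)))}
        return Ksub, eig, null, pre

    contexts: dict = {}
    rows = []
    sub_cache: dict[tuple, tuple] = {}
    maf_all = panel.maf()
    for j in np.flatnonzero(mask):
        chrom_key = str(panel.chrom[j]) if loco else None
        if chrom_key not in contexts:
            contexts[chrom_key] = context_for(chrom_key)
        Ksub, eig, null_fit, pre = contexts[chrom_key]
        g = G[:, j]
        typed = ~np.isnan(g)
        if typed.all():
            res = association_test(y, g, Z, Ksub.values, mode=mode, eig=eig,
                                   null_fit=null_fit, _pre=pre)
            n_used = y.size
        else:
            key = (chrom_key, tuple(np.flatnonzero(typed)))
            if key not in sub_cache:
                keep_animals = typed[np.argmax(Z, axis=1)]
                Zs = Z[np.ix_(keep_animals, typed)]
                Ks = Ksub.values[np.ix_(typed, typed)]
                sub_cache[key] = (keep_animals, Zs, Ks,
                                  EigenContext.build(Zs, Ks))
            keep_animals, Zs, Ks, eig_s = sub_cache[key]
            nf = (reml_fit(y[keep_animals], np.ones((int(keep_animals.sum()), 1)),
                           eig=eig_s) if mode == "approx" else None)
            res = association_test(y[keep_animals], g[typed], Zs, Ks,
                                   mode=mode, eig=eig_s, null_fit=nf)
            n_used = int(keep_animals.sum())
        with np.errstate(divide="ignore"):
            nlp = -np.log10(res.P) if np.isfinite(res.P) and res.P > 0 else np.nan
        rows.append((panel.snp_ids[j], panel.chrom[j], int(panel.pos[j]),
                     float(maf_all[j]), n_used, res.F, res.P, nlp,
                     res.monomorphic))
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf",
                                        "n_used", "F", "P", "neglog10P",
                                        "monomorphic"])
    return AssociationResult(
        table=table, trait=trait,
        metadata={"mode": mode, "maf_min": maf_min, "missing_max": missing_max,
                  "loco": loco, "n_snps_tested": len(table)},
    )


def genomic_inflation(p_values: np.ndarray) -> float:
    """Median-based inflation factor lambda from a vector of P-values."""
    p = np.asarray(p_values, float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
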