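"""Single-population mixed-model association scan.

Implements the classic quantitative-genetics workhorse: for a residualized
phenotype y and genotype dosages x (0/1/2 copies of the minor allele), fit

    y = x * beta + u + e,   u ~ MVN(0, sigma_a2 * G),   e ~ MVN(0, sigma_e2 * I)

where G is the genomic relationship matrix.  Variance components are
estimated once under the null by REML profiled over delta = sigma_e2 /
sigma_a2 via a single spectral decomposition of G (EMMA-style); the scan
then either reuses the null components for every SNP (EMMAX-style, the
default) or re-optimizes delta per SNP.  Per-SNP effects and standard
errors come from generalized least squares, p-values from a Wald
chi-square(1) test.

Also houses genotype QC, fixed-effect residualization, the two
variance-explained estimators, and lead/sentinel SNP calling with
novel/enhanced classification against a reference lead set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EmptyResultError
from .simulate import PhasedPopulation

__all__ = [
    "GenotypeMatrix", "ResidualPhenotype", "GRM", "VarianceComponents",
    "qc_filter", "residualize", "compute_grm", "reml_fit", "lmm_scan",
    "variance_explained_residual", "variance_explained_formula",
    "call_lead_snps", "sentinel_merge", "classify_vs_reference",
    "classify_leads",
]

GENOME_WIDE_P = 5e-8
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class GenotypeMatrix:
    """n x m dosage matrix coded as minor-allele copies (0/1/2, NaN missing).

    The effect allele is always the minor allele; sites where the VCF ALT
    allele is the major one are flipped on construction.
    """

    dosages: np.ndarray           # (n, m) float64, NaN for missing
    chrom: np.ndarray             # (m,) str
    pos: np.ndarray               # (m,) int64
    effect_allele: np.ndarray     # (m,) str, the minor allele
    other_allele: np.ndarray      # (m,) str
    sample_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosages.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("dosage shape does not match metadata")

    @classmethod
    def from_phased(cls, pop: PhasedPopulation) -> "GenotypeMatrix":
        dos = pop.dosages()
        freq = dos.mean(axis=0) / 2.0  # alt-allele frequency
        flip = freq > 0.5
        dos[:, flip] = 2.0 - dos[:, flip]
        eff = np.where(flip, pop.ref, pop.alt).astype(object)
        oth = np.where(flip, pop.alt, pop.ref).astype(object)
        return cls(dosages=dos, chrom=pop.chrom.copy(),
                   pos=pop.positions.copy(), effect_allele=eff,
                   other_allele=oth, sample_ids=list(pop.sample_ids))

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, mask], self.chrom[mask],
                              self.pos[mask], self.effect_allele[mask],
                              self.other_allele[mask], self.sample_ids)

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeMatrix(self.dosages[mask], self.chrom, self.pos,
                              self.effect_allele, self.other_allele, ids)


@dataclass
class ResidualPhenotype:
    """Phenotype vector after removal of fixed effects."""

    values: np.ndarray
    note: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("residual phenotype contains non-finite values")


@dataclass
class GRM:
    """Genomic relationship matrix with its spectral decomposition cached."""

    matrix: np.ndarray
    n_markers: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @cached_property
    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues clipped at 0, eigenvectors)."""
        lam, U = np.linalg.eigh(self.matrix)
        return np.clip(lam, 0.0, None), U


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    delta: float        # sigma_e2 / sigma_a2
    h2: float
    loglik: float       # restricted log-likelihood at the optimum
    boundary: bool = False


def qc_filter(geno: GenotypeMatrix, min_snp_call: float = 0.9,
              min_ind_call: float = 0.9,
              min_maf: float = 0.05) -> GenotypeMatrix:
    """Apply call-rate and MAF filters with strict `>` comparisons.

    Individuals are filtered first; SNP statistics are recomputed on the
    retained individuals.  A threshold of exactly 0 disables that filter.
    Raises EmptyResultError when nothing survives.
    """
    for t in (min_snp_call, min_ind_call, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    g = geno
    if min_ind_call > 0:
        keep_ind = g.sample_call_rate() > min_ind_call
        if not keep_ind.any():
            raise EmptyResultError(
                f"all {g.n} individuals removed at call rate > {min_ind_call}")
        if not keep_ind.all():
            g = g.take_samples(keep_ind)
    keep = np.ones(g.m, dtype=bool)
    if min_snp_call > 0:
        keep &= g.snp_call_rate() > min_snp_call
    if min_maf > 0:
        keep &= g.maf() > min_maf
    if not keep.any():
        raise EmptyResultError(
            f"all {g.m} SNPs removed (call rate > {min_snp_call}, "
            f"MAF > {min_maf}); individuals retained: {g.n}")
    if keep.all() and g is geno:
        return geno
    return g.take_snps(keep)


def residualize(raw: np.ndarray | pd.Series,
                covariates: pd.DataFrame) -> ResidualPhenotype:
    """Remove sex/batch (categorical) fixed effects by least squares.

    The returned vector is the raw phenotype minus its projection onto the
    intercept + indicator design, hence orthogonal to it.  A rank-deficient
    (confounded) design triggers a warning and a pseudoinverse fit.
    """
    y = np.asarray(raw, dtype=np.float64)
    parts = [np.ones((len(y), 1))]
    for col in covariates.columns:
        d = pd.get_dummies(pd.Categorical(covariates[col]), drop_first=True)
        if d.shape[1]:
            parts.append(d.to_numpy(dtype=np.float64))
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("confounded covariate design; using pseudoinverse fit")
    resid = y - X @ (np.linalg.pinv(X) @ y)
    return ResidualPhenotype(
        values=resid,
        note=f"least-squares residual on {list(covariates.columns)}")


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """Centered-and-scaled GRM: G = (1/m) sum_k z_k z_k^T with
    z_k = (x_k - 2 p_k) / sqrt(2 p_k (1 - p_k)).

    Missing dosages are mean-imputed per SNP; monomorphic SNPs are ignored.
    """
    X = geno.dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(mean, np.where(nan_mask)[1])
    p = mean / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        poly = (p > 0) & (p < 1) & (np.nanvar(X, axis=0) > 0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs; cannot compute a GRM")
    Xp = X[:, poly]
    pp = p[poly]
    Z = (Xp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    m = Z.shape[1]
    G = (Z @ Z.T) / m
    G = (G + G.T) / 2.0
    return GRM(matrix=G, n_markers=m)


def _restricted_negloglik(log10_delta: float, lam: np.ndarray,
                          yt: np.ndarray, Xt: np.ndarray,
                          ld_xtx: float) -> float:
    """-2*... no: negative restricted log-likelihood profiled over sigma_a2."""
    delta = 10.0 ** log10_delta
    d = lam + delta
    w = 1.0 / d
    XtWX = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    R = float(np.sum(w * r * r))
    nq = len(yt) - Xt.shape[1]
    sigma_a2 = R / nq
    _, ld1 = np.linalg.slogdet(XtWX)
    ll = -0.5 * (nq * np.log(2.0 * np.pi * sigma_a2) + np.sum(np.log(d))
                 + ld1 - ld_xtx + nq)
    return -ll


_LOG10_DELTA_BOUNDS = (-5.0, 5.0)
_GRID_POINTS = 64


def reml_fit(y: ResidualPhenotype | np.ndarray, G: GRM,
             X: np.ndarray | None = None) -> VarianceComponents:
    """REML variance components by spectral decomposition of G.

    delta = sigma_e2/sigma_a2 is profiled on a 64-point log grid over
    [1e-5, 1e5] and refined by bounded scalar minimization around the best
    grid point; sigma_a2 is then the profiled GLS residual mean square.
    The `boundary` flag marks optima pinned at the search limits.
    """
    yv = y.values if isinstance(y, ResidualPhenotype) else np.asarray(y, float)
    if not np.all(np.isfinite(yv)):
        raise ValueError("phenotype contains non-finite values")
    n = len(yv)
    if n < 10:
        raise ValueError("need at least 10 individuals for REML")
    if X is None:
        X = np.ones((n, 1))
    lam, U = G.eig
    yt = U.T @ yv
    Xt = U.T @ X
    _, ld_xtx = np.linalg.slogdet(X.T @ X)

    lo, hi = _LOG10_DELTA_BOUNDS
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([_restricted_negloglik(g, lam, yt, Xt, ld_xtx)
                     for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _restricted_negloglik, bounds=(a, b), method="bounded",
        args=(lam, yt, Xt, ld_xtx), options={"xatol": 1e-10})
    best_log10 = res.x if res.fun <= vals[i] else grid[i]
    best_nll = min(float(res.fun), float(vals[i]))

    delta = 10.0 ** float(best_log10)
    d = lam + delta
    w = 1.0 / d
    XtWX = Xt.T @ (w[:, None] * Xt)
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sigma_a2 = float(np.sum(w * r * r)) / (n - X.shape[1])
    boundary = bool(best_log10 <= lo + 1e-3 or best_log10 >= hi - 1e-3)
    return VarianceComponents(
        sigma_a2=sigma_a2, sigma_e2=delta * sigma_a2, delta=delta,
        h2=1.0 / (1.0 + delta), loglik=-best_nll, boundary=boundary)


def lmm_scan(y: ResidualPhenotype | np.ndarray, geno: GenotypeMatrix,
             G: GRM, vc: VarianceComponents | None = None,
             vc_mode: str = "null_reuse") -> pd.DataFrame:
    """Per-SNP mixed-model association scan.

    For each SNP the GLS estimate beta = (x' V^-1 x)^-1 x' V^-1 y with
    V = sigma_a2 G + sigma_e2 I (intercept included), standard error from
    the GLS information, and a two-sided Wald chi-square(1) p-value.
    `vc_mode='null_reuse'` (default) evaluates V at the null-model variance
    components; `'per_snp'` re-optimizes delta for every SNP.

    Monomorphic SNPs are skipped with a warning.  Returns a table with
    columns chrom, pos, effect_allele, other_allele, maf, n, beta, se, p.
    """
    if vc_mode not in ("null_reuse", "per_snp"):
        raise ValueError(f"unknown vc_mode {vc_mode!r}")
    yv = y.values if isinstance(y, ResidualPhenotype) else np.asarray(y, float)
    if len(yv) != geno.n:
        raise ValueError("phenotype and genotypes are not sample-aligned")
    n = len(yv)
    lam, U = G.eig

    maf = geno.maf()
    n_obs = (~np.isnan(geno.dosages)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        poly = (maf > 0) & (np.nanvar(geno.dosages, axis=0) > 0)
    if not poly.all():
        warnings.warn(f"skipping {int((~poly).sum())} monomorphic SNPs")

    X = geno.dosages[:, poly].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    yt = U.T @ yv
    ot = U.T @ np.ones(n)
    Xt = U.T @ X

    if vc_mode == "null_reuse":
        if vc is None:
            vc = reml_fit(yv, G)
        w = 1.0 / (vc.sigma_a2 * lam + vc.sigma_e2)
        S11 = float(np.sum(w * ot * ot))
        S1y = float(np.sum(w * ot * yt))
        S1x = (w * ot) @ Xt
        Sxx = w @ (Xt * Xt)
        Sxy = (w * yt) @ Xt
        det = S11 * Sxx - S1x ** 2
        beta = (S11 * Sxy - S1x * S1y) / det
        se = np.sqrt(S11 / det)
    else:
        beta = np.empty(Xt.shape[1])
        se = np.empty(Xt.shape[1])
        for j in range(Xt.shape[1]):
            Xd = np.column_stack([np.ones(n), X[:, j]])
            vc_j = reml_fit(yv, G, X=Xd)
            wj = 1.0 / (vc_j.sigma_a2 * lam + vc_j.sigma_e2)
            Xtj = np.column_stack([ot, Xt[:, j]])
            info = Xtj.T @ (wj[:, None] * Xtj)
            cov = np.linalg.inv(info)
            bj = cov @ (Xtj.T @ (wj * yt))
            beta[j] = bj[1]
            se[j] = np.sqrt(cov[1, 1])

    chi2 = (beta / se) ** 2
    p = np.maximum(stats.chi2.sf(chi2, df=1), _TINY_P)
    return pd.DataFrame({
        "chrom": geno.chrom[poly],
        "pos": geno.pos[poly],
        "effect_allele": geno.effect_allele[poly],
        "other_allele": geno.other_allele[poly],
        "maf": maf[poly],
        "n": n_obs[poly],
        "beta": beta,
        "se": se,
        "p": p,
    })


def variance_explained_residual(y: np.ndarray, x: np.ndarray) -> float:
    """(V_reduce - V_full)/V_reduce from ordinary linear models without and
    with the SNP dosage as a covariate."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    v_reduce = float(np.var(y - y.mean()))
    if v_reduce <= 0:
        raise ValueError("phenotype is constant")
    if float(np.var(x)) == 0.0:
        return 0.0
    X = np.column_stack([np.ones_like(x), x])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    v_full = float(np.var(resid))
    return (v_reduce - v_full) / v_reduce


def variance_explained_formula(p: float, a: float, sigma_p2: float) -> float:
    """Closed-form proportion of phenotypic variance: 2 p (1-p) a^2 / sigma_p2."""
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    if sigma_p2 <= 0:
        raise ValueError("phenotypic variance must be positive")
    return 2.0 * p * (1.0 - p) * a * a / sigma_p2


def call_lead_snps(records: pd.DataFrame, trait: str = "trait",
                   threshold: float = GENOME_WIDE_P,
                   population: str | None = None) -> pd.DataFrame:
    """One lead SNP per chromosome: the minimum-p SNP among those below the
    genome-wide threshold; ties broken by smaller position."""
    sig = records[records["p"] < threshold]
    if sig.empty:
        out = records.iloc[0:0].copy()
    else:
        sig = sig.sort_values(["chrom", "p", "pos"], kind="mergesort")
        out = sig.groupby("chrom", sort=False).head(1).copy()
    out["trait"] = trait
    if population is not None:
        out["population"] = population
    return out.reset_index(drop=True)


def sentinel_merge(leads: pd.DataFrame,
                   window_bp: int = 1_000_000) -> pd.DataFrame:
    """Merge lead SNPs within `window_bp` on a chromosome (single linkage)
    into regions; each region is represented by its strongest lead.

    Adds `n_merged` (cluster size) and keeps one row per sentinel.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if leads.empty:
        out = leads.copy()
        out["n_merged"] = pd.Series(dtype=int)
        return out
    rows = []
    for chrom, grp in leads.groupby("chrom", sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        gap = grp["pos"].diff() > window_bp
        cluster = gap.cumsum()
        for _, sub in grp.groupby(cluster, sort=False):
            best = sub.sort_values(["p", "pos"], kind="mergesort").iloc[0]
            rec = best.to_dict()
            rec["n_merged"] = len(sub)
            rows.append(rec)
    return pd.DataFrame(rows).reset_index(drop=True)


def classify_vs_reference(chrom: str, pos: int, p: float,
                          reference_leads: pd.DataFrame,
                          novel_distance_bp: int = 1_000_000,
                          enhanced_gain: float = 2.0) -> str:
    """Classify a lead against a reference lead set for the same trait domain.

    novel: nearest same-chromosome reference lead farther than
    `novel_distance_bp` (or no reference on the chromosome); enhanced: at
    least `enhanced_gain` units of -log10 p over that nearest reference;
    otherwise known.
    """
    ref = reference_leads[reference_leads["chrom"].astype(str) == str(chrom)]
    if ref.empty:
        return "novel"
    dist = (ref["pos"] - pos).abs()
    i = dist.idxmin()
    if dist.loc[i] > novel_distance_bp:
        return "novel"
    gain = -np.log10(p) - (-np.log10(ref.loc[i, "p"]))
    return "enhanced" if gain >= enhanced_gain else "known"


def classify_leads(leads: pd.DataFrame, reference_leads: pd.DataFrame,
                   novel_distance_bp: int = 1_000_000,
                   enhanced_gain: float = 2.0) -> pd.DataFrame:
    """Vectorized wrapper: adds a `classification` column."""
    out = leads.copy()
    out["classification"] = [
        classify_vs_reference(r["chrom"], r["pos"], r["p"], reference_leads,
                              novel_distance_bp, enhanced_gain)
        for _, r in leads.iterrows()]
    return out
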