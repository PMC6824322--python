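"""Haplotype-level dissection of an association locus.

Around a lead SNP a window of 2k+1 phased SNPs is extracted (k = 20 by
default, i.e. the classic 41-SNP window), distinct haplotypes are
enumerated with per-population frequencies, and per-copy haplotype effects
are estimated under the same mixed model as the single-SNP scan:

    y = H beta + u + e,  u ~ MVN(0, sigma_a2 G),  e ~ MVN(0, sigma_e2 I)

where H is the n x p haplotype incidence (copy-count) matrix.  Both sides
are whitened with W^-1 = V^-1/2 (V = sigma_a2 G + sigma_e2 I, via
eigendecomposition), after which ordinary least squares applies.  Because
rows of H sum to 2, the most frequent haplotype is dropped as the
reference and an intercept added; effects are per-copy deviations from the
reference haplotype.

Cross-population structure is probed by the maximal shared segment (the
longest run of window positions at which selected haplotypes from several
populations carry identical alleles), a shared/specific/absent frequency
classification, and a neighbor-joining tree of haplotypes under Hamming
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import GRM, ResidualPhenotype, VarianceComponents
from .simulate import PhasedPopulation

__all__ = [
    "HaplotypeSet", "HaplotypeIncidence",
    "extract_window", "build_incidence", "estimate_haplotype_effects",
    "whitener", "shared_segment", "classify_sharing",
    "hamming_distance_matrix", "neighbor_joining",
]


@dataclass
class HaplotypeSet:
    """Distinct haplotypes over a SNP window in one population."""

    population: str
    chrom: str
    positions: np.ndarray        # (w,) bp of the window SNPs
    lead_index: int              # index of the lead SNP within the window
    haplotypes: list[str]        # distinct allele strings, frequency-sorted
    frequencies: np.ndarray      # (p,) frequencies, sum to 1
    diplotypes: np.ndarray       # (n, 2) haplotype ids per individual

    @property
    def n(self) -> int:
        return self.diplotypes.shape[0]

    def frequency_of(self, hap: str) -> float:
        try:
            return float(self.frequencies[self.haplotypes.index(hap)])
        except ValueError:
            return 0.0


@dataclass
class HaplotypeIncidence:
    """n x p haplotype copy-count matrix H; rare haplotypes pooled."""

    H: np.ndarray                 # (n, p [+1]) counts in {0,1,2}
    haplotypes: list[str]         # retained haplotype strings, column order
    frequencies: np.ndarray       # frequencies of retained haplotypes
    has_rare_column: bool         # last column pools haplotypes <= min_freq

    def __post_init__(self):
        if not np.all(self.H.sum(axis=1) == 2):
            raise ValueError("every individual must carry exactly 2 copies")


def extract_window(pop: PhasedPopulation, lead: tuple[str, int],
                   k: int = 20) -> HaplotypeSet:
    """Extract haplotypes of up to 2k+1 SNPs centered on the lead SNP.

    At chromosome ends the window is truncated (with a warning) rather
    than erroring.  The lead variant must exist in the population.
    """
    chrom, pos = lead
    on = np.where((pop.chrom == str(chrom)) & (pop.positions == int(pos)))[0]
    if on.size == 0:
        raise KeyError(f"lead variant {chrom}:{pos} not found")
    j = int(on[0])
    chrom_idx = np.where(pop.chrom == str(chrom))[0]
    lo_chrom, hi_chrom = chrom_idx.min(), chrom_idx.max()
    lo = max(j - k, lo_chrom)
    hi = min(j + k, hi_chrom)
    if hi - lo + 1 < 2 * k + 1:
        warnings.warn(
            f"window truncated to {hi - lo + 1} SNPs at a chromosome end")
    idx = np.arange(lo, hi + 1)
    sub = pop.haplotypes[:, idx]
    strings = ["".join(map(str, row)) for row in sub]
    uniq, inverse, counts = np.unique(strings, return_inverse=True,
                                      return_counts=True)
    order = np.argsort(-counts, kind="mergesort")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    ids = rank[inverse]
    return HaplotypeSet(
        population=pop.name,
        chrom=str(chrom),
        positions=pop.positions[idx].copy(),
        lead_index=j - lo,
        haplotypes=[str(uniq[i]) for i in order],
        frequencies=counts[order] / counts.sum(),
        diplotypes=ids.reshape(-1, 2),
    )


def build_incidence(hset: HaplotypeSet,
                    min_freq: float = 0.05) -> HaplotypeIncidence:
    """Copy-count matrix with haplotypes of frequency > min_freq retained
    as columns and all others pooled into one rare column (strict >, so a
    haplotype at exactly min_freq is pooled)."""
    if not 0.0 <= min_freq <= 0.5:
        raise ValueError("min_freq must lie in [0, 0.5]")
    retained = [i for i, f in enumerate(hset.frequencies) if f > min_freq]
    rare = [i for i in range(len(hset.haplotypes)) if i not in retained]
    n = hset.n
    p = len(retained) + (1 if rare else 0)
    H = np.zeros((n, p), dtype=np.int64)
    col_of = {h: c for c, h in enumerate(retained)}
    for i in range(n):
        for h in hset.diplotypes[i]:
            if h in col_of:
                H[i, col_of[h]] += 1
            else:
                H[i, -1] += 1
    return HaplotypeIncidence(
        H=H,
        haplotypes=[hset.haplotypes[i] for i in retained],
        frequencies=hset.frequencies[list(retained)]
        if retained else np.empty(0),
        has_rare_column=bool(rare),
    )


def whitener(vc: VarianceComponents, G: GRM) -> np.ndarray:
    """W^-1 = V^-1/2 for V = sigma_a2 G + sigma_e2 I via eigendecomposition.

    V shares eigenvectors with G, so W^-1 = U diag((sigma_a2 lam +
    sigma_e2)^-1/2) U'.  Pre-multiplying the model by W^-1 turns the
    correlated residual Zu + e into white noise.
    """
    lam, U = G.eig
    dv = vc.sigma_a2 * lam + vc.sigma_e2
    if (dv <= 0).any():
        raise ValueError("V is not positive definite")
    return (U * (1.0 / np.sqrt(dv))) @ U.T


def estimate_haplotype_effects(y: ResidualPhenotype | np.ndarray,
                               H: HaplotypeIncidence,
                               vc: VarianceComponents,
                               G: GRM) -> pd.DataFrame:
    """Per-copy haplotype effects versus the most frequent (reference)
    haplotype, by whitened ordinary least squares.

    Both y and the design [intercept | H without the reference column] are
    pre-multiplied by W^-1; OLS then yields GLS estimates.  Standard errors
    use the OLS information of the whitened design; p-values are two-sided
    t-tests with n - #columns degrees of freedom.  Collinear columns are
    dropped with a warning.  The reference row is reported with beta 0 and
    NaN se/p.

    Because the reference choice is arbitrary, the table also carries
    `beta_centered`/`se_centered`/`p_centered`: each haplotype's deviation
    from the frequency-weighted population mean effect, whose polarity is
    comparable across populations even when they pick different reference
    haplotypes.  The reference row has a valid centered test.
    """
    yv = y.values if isinstance(y, ResidualPhenotype) else np.asarray(y, float)
    n, p = H.H.shape
    if len(yv) != n:
        raise ValueError("phenotype and incidence matrix are not aligned")
    labels = list(H.haplotypes) + (["<rare>"] if H.has_rare_column else [])
    ref = 0  # most frequent haplotype: first retained column
    keep = [c for c in range(p) if c != ref]

    Winv = whitener(vc, G)
    X = np.column_stack([np.ones(n)] + [H.H[:, c] for c in keep])
    Xw = Winv @ X
    yw = Winv @ yv

    # drop collinear columns (beyond the intercept) via rank-revealing QR
    q, r = np.linalg.qr(Xw)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps
    bad = [i for i in range(1, Xw.shape[1]) if diag[i] < tol]
    if bad:
        warnings.warn(f"dropping {len(bad)} collinear haplotype column(s)")
        good = [i for i in range(Xw.shape[1]) if i not in bad]
        Xw = Xw[:, good]
        keep = [keep[i - 1] for i in good[1:]]

    XtX = Xw.T @ Xw
    coef = np.linalg.solve(XtX, Xw.T @ yw)
    df_resid = n - Xw.shape[1]
    resid = yw - Xw @ coef
    s2 = float(resid @ resid) / df_resid
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)

    freq_all = list(H.frequencies) + (
        [1.0 - float(np.sum(H.frequencies))] if H.has_rare_column else [])

    # centered parametrization: deviations from the frequency-weighted
    # mean effect, reference included (its beta is the constant 0)
    cols = [ref] + keep                      # column ids in report order
    w = np.array([freq_all[c] for c in cols])
    w = w / w.sum()
    b_all = np.concatenate([[0.0], coef[1:]])          # aligned to cols
    cov_b = np.zeros((len(cols), len(cols)))
    cov_b[1:, 1:] = cov[1:, 1:]
    centered = b_all - w @ b_all
    contrasts = np.eye(len(cols)) - w[None, :].repeat(len(cols), axis=0)
    var_c = np.einsum("ij,jk,ik->i", contrasts, cov_b, contrasts)
    se_c = np.sqrt(np.maximum(var_c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_c = centered / se_c
    p_c = 2.0 * stats.t.sf(np.abs(t_c), df=df_resid)

    rows = [{
        "haplotype": labels[ref], "frequency": freq_all[ref],
        "beta": 0.0, "se": np.nan, "p": np.nan, "is_reference": True,
        "beta_centered": float(centered[0]), "se_centered": float(se_c[0]),
        "p_centered": float(p_c[0]),
    }]
    for i, c in enumerate(keep, start=1):
        rows.append({
            "haplotype": labels[c], "frequency": freq_all[c],
            "beta": float(coef[i]), "se": float(se[i]),
            "p": float(pvals[i]), "is_reference": False,
            "beta_centered": float(centered[i]),
            "se_centered": float(se_c[i]), "p_centered": float(p_c[i]),
        })
    return pd.DataFrame(rows)


def shared_segment(haplotypes: list[str],
                   positions: np.ndarray) -> tuple[int, int] | None:
    """Longest run of consecutive window positions at which all given
    haplotypes carry identical alleles, as a 1-based inclusive bp interval.

    Ties are broken by the leftmost run; returns None when no position
    agrees.  All haplotypes must span the same ordered position list.
    """
    if not haplotypes:
        raise ValueError("empty haplotype selection")
    L = len(haplotypes[0])
    if any(len(h) != L for h in haplotypes):
        raise ValueError("haplotypes must have equal length")
    positions = np.asarray(positions)
    if positions.shape[0] != L:
        raise ValueError("positions must match haplotype length")
    agree = np.ones(L, dtype=bool)
    first = haplotypes[0]
    for h in haplotypes[1:]:
        agree &= np.fromiter((a == b for a, b in zip(first, h)),
                             dtype=bool, count=L)
    best_len, best_start = 0, -1
    run_start = None
    for i in range(L + 1):
        if i < L and agree[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                length = i - run_start
                if length > best_len:
                    best_len, best_start = length, run_start
                run_start = None
    if best_len == 0:
        return None
    return int(positions[best_start]), int(positions[best_start + best_len - 1])


def classify_sharing(frequencies: dict[str, float],
                     presence_freq: float = 0.05,
                     absence_freq: float = 0.01) -> str:
    """Classify one haplotype from its per-population frequencies.

    specific: present (>= presence_freq) in exactly one population and
    below absence_freq everywhere else; shared: present in >= 2
    populations; absent: otherwise.
    """
    if presence_freq <= absence_freq:
        raise ValueError("presence_freq must exceed absence_freq")
    present = [p for p, f in frequencies.items() if f >= presence_freq]
    if len(present) >= 2:
        return "shared"
    if len(present) == 1:
        others = [f for p, f in frequencies.items() if p != present[0]]
        return "specific" if all(f < absence_freq for f in others) else "absent"
    return "absent"


def hamming_distance_matrix(haplotypes: list[str]) -> np.ndarray:
    """Pairwise count of mismatching positions between allele strings."""
    if not haplotypes:
        return np.zeros((0, 0))
    L = len(haplotypes[0])
    if any(len(h) != L for h in haplotypes):
        raise ValueError("haplotypes must have equal length")
    arr = np.array([[ord(c) for c in h] for h in haplotypes], dtype=np.int16)
    D = (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(np.float64)
    return D


def neighbor_joining(D: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in newick form.

    Pairs are joined by the minimum of the Q criterion, ties broken by the
    smallest (i, j) node-creation-order pair; branch lengths follow the
    standard NJ equations, with negative lengths clamped to zero (a
    warning is emitted).  Exact on additive distance matrices.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels are inconsistent")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(D, D.T) or (np.diag(D) != 0).any() or (D < 0).any():
        raise ValueError("distance matrix must be symmetric, non-negative, "
                         "with zero diagonal")

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    clamped = False
    # each active node: (newick fragment, creation order index)
    nodes = [(str(lab), i) for i, lab in enumerate(labels)]
    order = n
    D = D.copy()
    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                key = (Q[i, j], min(nodes[i][1], nodes[j][1]),
                       max(nodes[i][1], nodes[j][1]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = dij / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        newick = (f"({nodes[i][0]}:{fmt(li)},{nodes[j][0]}:{fmt(lj)})")
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        Dn = np.empty((r - 1, r - 1))
        Dn[:-1, :-1] = D[np.ix_(keep, keep)]
        Dn[-1, :-1] = dnew[keep]
        Dn[:-1, -1] = dnew[keep]
        Dn[-1, -1] = 0.0
        D = Dn
        nodes = [nodes[k] for k in keep] + [(newick, order)]
        order += 1

    if len(nodes) == 2:
        d = D[0, 1]
        out = (f"({nodes[0][0]}:{fmt(d / 2)},{nodes[1][0]}:{fmt(d / 2)});")
    else:
        la = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
        lb = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
        lc = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
        ls = [la, lb, lc]
        if any(l < 0 for l in ls):
            clamped = True
            ls = [max(l, 0.0) for l in ls]
        out = (f"({nodes[0][0]}:{fmt(ls[0])},{nodes[1][0]}:{fmt(ls[1])},"
               f"{nodes[2][0]}:{fmt(ls[2])});")
    if clamped:
        warnings.warn("negative branch length(s) clamped to 0")
    return out
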