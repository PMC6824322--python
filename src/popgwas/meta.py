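"""Sample-size-weighted z-score meta-analysis across populations.

Per-population association statistics are converted to signed z-scores
z_i = sign(beta_i) * Phi^-1(1 - p_i/2), harmonized to a common effect
allele, and combined as

    Z = sum_i sqrt(N_i) z_i / sqrt(sum_i N_i),   p = 2 (1 - Phi(|Z|)),

the weighting scheme popularized by METAL.  An inverse-variance scheme on
betas/SEs is available as an alternative.  Variants absent from some
populations are combined over those available; a per-population direction
string ('+', '-', '?') is carried with every combined record.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import gwas

__all__ = ["align_alleles", "meta_z", "meta_scan"]

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})
_TINY_P = np.nextafter(0.0, 1.0)


def _zscore(beta: np.ndarray, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if (p <= 0).any():
        warnings.warn("p-values at or below 0 clamped to the smallest "
                      "positive representable value")
        p = np.maximum(p, _TINY_P)
    return np.sign(beta) * stats.norm.isf(p / 2.0)


def align_alleles(tables: dict[str, pd.DataFrame],
                  reference: pd.DataFrame | None = None,
                  keep_ambiguous: bool = True) -> pd.DataFrame:
    """Harmonize per-population records to one effect allele per variant.

    The reference effect/other alleles for each chrom:pos key come from
    `reference` (columns chrom, pos, effect_allele, other_allele) or, by
    default, from the first population carrying the variant.  Records whose
    alleles are swapped relative to the reference have their z-score
    negated; records with incompatible alleles are excluded and flagged.
    Strand-ambiguous pairs (A/T, C/G) are flagged and, by default, kept.

    Returns a long table: population, chrom, pos, effect_allele,
    other_allele, z, n, direction, flag.
    """
    ref_map: dict[tuple, tuple] = {}
    if reference is not None:
        for _, r in reference.iterrows():
            ref_map[(str(r["chrom"]), int(r["pos"]))] = (
                r["effect_allele"], r["other_allele"])
    rows = []
    for pop, df in tables.items():
        z = _zscore(df["beta"].to_numpy(), df["p"].to_numpy())
        for (_, r), zi in zip(df.iterrows(), z):
            key = (str(r["chrom"]), int(r["pos"]))
            ea, oa = r["effect_allele"], r["other_allele"]
            if key not in ref_map:
                ref_map[key] = (ea, oa)
            ref_ea, ref_oa = ref_map[key]
            flag = "ok"
            if {ea, oa} in _AMBIGUOUS:
                flag = "strand_ambiguous"
                if not keep_ambiguous:
                    flag = "excluded_ambiguous"
            if (ea, oa) == (ref_ea, ref_oa):
                pass
            elif (ea, oa) == (ref_oa, ref_ea):
                zi = -zi
            else:
                flag = "allele_mismatch"
            rows.append({
                "population": pop, "chrom": key[0], "pos": key[1],
                "effect_allele": ref_ea, "other_allele": ref_oa,
                "z": zi, "n": int(r["n"]),
                "direction": 1 if zi >= 0 else -1,
                "flag": flag,
            })
    return pd.DataFrame(rows)


def meta_z(z: np.ndarray, n: np.ndarray,
           populations: list[str] | None = None,
           present: np.ndarray | None = None) -> dict:
    """Combine signed z-scores with sqrt(N) weights for one variant.

    `present` (boolean, aligned to `populations`) controls the direction
    string; by default all entries are present.
    """
    z = np.asarray(z, dtype=np.float64)
    n = np.asarray(n, dtype=np.float64)
    if z.size == 0:
        raise ValueError("at least one population required")
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    Z = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    p = float(max(2.0 * stats.norm.sf(abs(Z)), _TINY_P))
    if populations is None:
        direction = "".join("+" if zi >= 0 else "-" for zi in z)
    else:
        direction = ""
        j = 0
        for i in range(len(populations)):
            if present is None or present[i]:
                direction += "+" if z[j] >= 0 else "-"
                j += 1
            else:
                direction += "?"
    return {"Z": Z, "p": p, "n_total": int(np.sum(n)),
            "direction": direction}


def meta_scan(tables: dict[str, pd.DataFrame],
              scheme: str = "samplesize", min_pops: int = 1,
              threshold: float = gwas.GENOME_WIDE_P,
              trait: str = "trait") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Meta-analyze per-population scans and call meta lead SNPs.

    Returns (meta table, meta leads).  The meta table has columns chrom,
    pos, effect_allele, other_allele, Z, p, n, direction,
    best_single_mlog10p (the strongest single-population -log10 p at the
    variant, for enhancement comparisons).  Leads reuse the one-per-
    chromosome rule at the genome-wide threshold.
    """
    if scheme not in ("samplesize", "invvar"):
        raise ValueError(f"unknown scheme {scheme!r}")
    pops = list(tables)
    aligned = align_alleles(tables)
    aligned = aligned[aligned["flag"] != "allele_mismatch"]
    aligned = aligned[aligned["flag"] != "excluded_ambiguous"]

    # per-population p at each variant, for the enhancement report
    pmap: dict[tuple, dict[str, float]] = {}
    for pop, df in tables.items():
        for _, r in df.iterrows():
            pmap.setdefault((str(r["chrom"]), int(r["pos"])), {})[pop] = r["p"]

    rows = []
    for (chrom, pos), grp in aligned.groupby(["chrom", "pos"], sort=False):
        if len(grp) < min_pops:
            continue
        present = np.array([p in set(grp["population"]) for p in pops])
        if scheme == "samplesize":
            res = meta_z(grp["z"].to_numpy(), grp["n"].to_numpy(),
                         populations=pops, present=present)
        else:
            # inverse-variance on betas requires se; recover from z and n is
            # not possible, so pull beta/se back from the source tables
            betas, ses = [], []
            for pop in grp["population"]:
                src = tables[pop]
                row = src[(src["chrom"].astype(str) == chrom)
                          & (src["pos"] == pos)].iloc[0]
                sign = grp.loc[grp["population"] == pop, "z"].iloc[0]
                b = row["beta"] if np.sign(row["beta"]) == np.sign(sign) or \
                    row["beta"] == 0 else -row["beta"]
                betas.append(b)
                ses.append(row["se"])
            w = 1.0 / np.asarray(ses, float) ** 2
            b = float(np.sum(w * np.asarray(betas)) / np.sum(w))
            se = float(1.0 / np.sqrt(np.sum(w)))
            Z = b / se
            res = {"Z": Z, "p": float(max(2.0 * stats.norm.sf(abs(Z)), _TINY_P)),
                   "n_total": int(grp["n"].sum())}
            res["direction"] = "".join(
                ("+" if grp[grp["population"] == p]["z"].iloc[0] >= 0
                 else "-") if pr else "?"
                for p, pr in zip(pops, present))
        best = max(-np.log10(max(v, _TINY_P))
                   for v in pmap[(chrom, pos)].values())
        first = grp.iloc[0]
        rows.append({
            "chrom": chrom, "pos": pos,
            "effect_allele": first["effect_allele"],
            "other_allele": first["other_allele"],
            "Z": res["Z"], "p": res["p"], "n": res["n_total"],
            "direction": res["direction"],
            "best_single_mlog10p": best,
        })
    meta = pd.DataFrame(rows)
    if meta.empty:
        return meta, meta
    leads = gwas.call_lead_snps(meta, trait=trait, threshold=threshold,
                                population="META")
    return meta, leads
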