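"""Synthetic multi-population genotype/phenotype generator.

Emulates a multi-breed quantitative-trait study design: several pig-like
populations of unequal size (a few hundred animals each) are drawn from a
common ancestral haplotype pool through population-specific drift
bottlenecks, so that one knob (the bottleneck size) controls both local
linkage disequilibrium and between-population differentiation.  A polygenic
trait is simulated on top of the realized genomic relationship matrix with a
chosen heritability, sex and slaughter-batch fixed offsets are added so the
residualization step of the association pipeline is exercised, and causal
haplotype segments can be planted at controlled carrier frequencies —
either shared by a subset of populations or private to a single one.

All randomness flows through explicit integer seeds; identical seeds and
specifications yield bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PlantingError

__all__ = [
    "AncestralPanel",
    "PopulationSpec",
    "PhasedPopulation",
    "TruthRecord",
    "simulate_panel",
    "sample_population",
    "concat_sites",
    "plant_causal_haplotype",
    "simulate_phenotypes",
    "write_fixture",
    "simulate_peaks",
    "simulate_genes",
]

# Non-strand-ambiguous REF/ALT pairs assigned to sites round-robin by a
# seeded draw, so meta-analysis allele harmonization is exercised without
# A/T / C/G ambiguity unless requested.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"))

# Rounds of random mating applied to the founder pool; enough to break up
# founder blocks at appreciable recombination rates while keeping strong
# local LD at low rates.
_MIXING_GENERATIONS = 4


@dataclass
class AncestralPanel:
    """A pool of phased ancestral haplotypes over one chromosome.

    Stands in for a sequenced reference panel: populations are sampled from
    it through drift bottlenecks.  Alleles are coded 0/1; `ref`/`alt` carry
    the nucleotide letters used when writing VCF.
    """

    haplotypes: np.ndarray  # (n_pool, L) uint8 in {0, 1}
    positions: np.ndarray   # (L,) int64, 1-based, strictly increasing
    chrom: str = "1"
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D array")
        if self.haplotypes.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match haplotype length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be coded 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class PopulationSpec:
    """Sampling specification for one population.

    `drift_parameter` is the bottleneck pool size: the number of founder
    haplotypes resampled (with replacement) to build the population; small
    values mean strong drift, long haplotype sharing and high LD.
    """

    name: str
    n_individuals: int
    drift_parameter: int
    carrier_frequency: dict[str, float] = field(default_factory=dict)
    sex_levels: int = 2
    batch_levels: int = 3
    # within-population mosaic structure: per-site crossover probability
    # and the chance a crossover segment comes from a random founder
    # rather than the copy's base lineage
    mosaic_recomb: float = 0.01
    admixture: float = 0.3

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.drift_parameter < 1:
            raise ValueError("drift_parameter must be >= 1")
        for hap, f in self.carrier_frequency.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"target frequency for {hap} outside [0, 1]")


@dataclass
class PhasedPopulation:
    """Phased biallelic genotypes plus covariates for one population.

    Haplotype rows 2i and 2i+1 belong to individual i.  `chrom` is per-site
    so populations spanning several simulated chromosomes can be held in one
    object after :func:`concat_sites`.
    """

    name: str
    haplotypes: np.ndarray          # (2n, L) uint8
    positions: np.ndarray           # (L,) int64
    chrom: np.ndarray               # (L,) str
    ref: np.ndarray                 # (L,) str
    alt: np.ndarray                 # (L,) str
    sample_ids: list[str]
    sex: np.ndarray | None = None   # (n,) int codes
    batch: np.ndarray | None = None
    lineage: np.ndarray | None = None  # (2n,) base founder lineage per copy
    local_ancestry: np.ndarray | None = None  # (2n, L) founder per site

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need exactly two haplotypes per individual")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """Alt-allele copy counts, shape (n, L)."""
        return (self.haplotypes[0::2].astype(np.int16)
                + self.haplotypes[1::2]).astype(np.float64)

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per site."""
        return self.haplotypes.mean(axis=0)

    def site_index(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites on `chrom` with start <= pos <= end (1-based)."""
        return np.where((self.chrom == chrom)
                        & (self.positions >= start)
                        & (self.positions <= end))[0]

    def subset_sites(self, mask: np.ndarray) -> "PhasedPopulation":
        """Same individuals restricted to the selected sites."""
        mask = np.asarray(mask)
        return PhasedPopulation(
            name=self.name,
            haplotypes=self.haplotypes[:, mask],
            positions=self.positions[mask],
            chrom=self.chrom[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            sample_ids=self.sample_ids,
            sex=self.sex,
            batch=self.batch,
            lineage=self.lineage,
            local_ancestry=(self.local_ancestry[:, mask]
                            if self.local_ancestry is not None else None),
        )


@dataclass
class TruthRecord:
    """Ground truth for one planted causal haplotype segment.

    Per population it records the per-copy allelic effect `a` (trait units),
    the polygenic heritability target, the additive/residual variances used
    for phenotype simulation, the carrier-frequency target and realization,
    and the exact carrier copy count of every individual.
    """

    chrom: str
    window_start: int
    window_end: int
    hap_string: str
    populations: dict[str, dict] = field(default_factory=dict)
    # each value: {effect, h2, sigma_a2, sigma_e2, target_freq,
    #             realized_freq, shared, carrier_copies (list[int])}

    def __post_init__(self):
        if self.window_end < self.window_start:
            raise ValueError("window end before start")
        for name, rec in self.populations.items():
            if not 0.0 <= rec.get("h2", 0.0) < 1.0:
                raise ValueError(f"h2 for {name} outside [0, 1)")
            if not np.isfinite(rec.get("effect", 0.0)):
                raise ValueError(f"effect for {name} not finite")

    def carrier_copies(self, pop: str) -> np.ndarray:
        return np.asarray(self.populations[pop]["carrier_copies"], dtype=np.int64)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "window_start": int(self.window_start),
            "window_end": int(self.window_end),
            "hap_string": self.hap_string,
            "populations": {
                name: {k: (list(map(int, v)) if k == "carrier_copies" else v)
                       for k, v in rec.items()}
                for name, rec in self.populations.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(chrom=d["chrom"], window_start=d["window_start"],
                   window_end=d["window_end"], hap_string=d["hap_string"],
                   populations=d["populations"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, TruthRecord):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def simulate_panel(L: int, n_pool: int, recomb_rate: float = 0.02,
                   mutation_density: float = 0.9, seed: int = 0, *,
                   chrom: str = "1", spacing_bp: int = 170,
                   start_bp: int = 1) -> AncestralPanel:
    """Build an ancestral haplotype pool of `n_pool` haplotypes over `L` sites.

    A fraction `mutation_density` of sites segregate; their allele
    frequencies are drawn from a U-shaped Beta(0.5, 0.5), giving a realistic
    excess of rare variants.  Founders are mixed by `_MIXING_GENERATIONS`
    rounds of random mating with per-site crossover probability
    `recomb_rate`, so low rates preserve long founder blocks (strong LD).
    Site positions are 1-based with mean spacing `spacing_bp` (about one SNP
    per 170 bp mimics whole-genome sequence density).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n_pool < 2:
        raise ValueError("n_pool must be >= 2")
    for nm, r in (("recomb_rate", recomb_rate), ("mutation_density", mutation_density)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{nm} must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    offsets = rng.integers(1, 2 * spacing_bp, size=L)
    positions = start_bp - 1 + np.cumsum(offsets)

    segregating = rng.random(L) < mutation_density
    haps = np.zeros((n_pool, L), dtype=np.uint8)
    if segregating.any():
        freq = rng.beta(0.5, 0.5, size=int(segregating.sum()))
        haps[:, segregating] = (
            rng.random((n_pool, int(segregating.sum()))) < freq
        ).astype(np.uint8)
    for _ in range(_MIXING_GENERATIONS):
        parents = rng.integers(0, n_pool, size=(n_pool, 2))
        cross = rng.random((n_pool, L)) < recomb_rate
        cross[:, 0] = False
        which = (rng.integers(0, 2, size=n_pool)[:, None]
                 + np.cumsum(cross, axis=1)) % 2
        a = haps[parents[:, 0]]
        b = haps[parents[:, 1]]
        haps = np.where(which == 0, a, b).astype(np.uint8)

    freq = haps.mean(axis=0)
    if mutation_density > 0 and not ((freq > 0) & (freq < 1)).any():
        # contract: at least one segregating site whenever density > 0
        site = int(rng.integers(L))
        haps[: n_pool // 2, site] = 1
        haps[n_pool // 2:, site] = 0

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=L)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    return AncestralPanel(haplotypes=haps, positions=positions, chrom=chrom,
                          ref=ref, alt=alt)


def draw_lineage_assignment(spec: PopulationSpec, seed: int = 0) -> np.ndarray:
    """Assign each of the 2n chromosome copies a founder lineage.

    Lineage contributions are Dirichlet-weighted, giving the skewed
    haplotype frequency spectra real populations show.  Passing the same
    assignment to :func:`sample_population` for several chromosomes makes
    relatedness consistent across the genome, as in a real pedigree.
    """
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.ones(spec.drift_parameter))
    return rng.choice(spec.drift_parameter, size=2 * spec.n_individuals,
                      replace=True, p=weights)


def sample_population(panel: AncestralPanel, spec: PopulationSpec,
                      seed: int = 0,
                      lineage_assignment: np.ndarray | None = None
                      ) -> PhasedPopulation:
    """Draw a population from `panel` through a drift bottleneck.

    `spec.drift_parameter` pool haplotypes are chosen without replacement
    as founder lineages.  Each of the population's 2n chromosome copies is
    a founder *mosaic*: crossovers occur at per-site probability
    `spec.mosaic_recomb`, and each segment comes from the copy's base
    lineage or, with probability `spec.admixture`, from a random founder.
    Local haplotype sharing is therefore much finer-grained than
    genome-wide relatedness, as in real populations.  When
    `lineage_assignment` is None a fresh Dirichlet-weighted base-lineage
    assignment is drawn; supplying one (see
    :func:`draw_lineage_assignment`) ties several chromosomes of the same
    individuals to common lineages so kinship is consistent across the
    genome.  Sex and slaughter-batch labels are assigned uniformly at
    random.
    """
    if panel.n_haplotypes == 0 or panel.n_sites == 0:
        raise ValueError("panel is empty")
    if spec.drift_parameter > panel.n_haplotypes:
        raise ValueError("drift_parameter exceeds panel size")
    rng = np.random.default_rng(seed)
    founders = rng.choice(panel.n_haplotypes, size=spec.drift_parameter,
                          replace=False)
    if lineage_assignment is None:
        weights = rng.dirichlet(np.ones(spec.drift_parameter))
        lineage_assignment = rng.choice(
            spec.drift_parameter, size=2 * spec.n_individuals,
            replace=True, p=weights)
    lineage_assignment = np.asarray(lineage_assignment)
    if lineage_assignment.shape != (2 * spec.n_individuals,):
        raise ValueError("lineage assignment must have length 2n")

    n2 = 2 * spec.n_individuals
    L = panel.n_sites
    K = spec.drift_parameter
    # segment labels: 0 at a crossover-free site, cumulative count otherwise
    cross = rng.random((n2, L)) < spec.mosaic_recomb
    cross[:, 0] = True  # first segment starts at the chromosome start
    seg_id = np.cumsum(cross, axis=1) - 1
    n_seg = seg_id.max() + 1
    # per-segment founder: base lineage unless an admixture draw replaces it
    base = np.repeat(lineage_assignment[:, None], n_seg, axis=1)
    foreign = rng.integers(0, K, size=(n2, n_seg))
    use_foreign = rng.random((n2, n_seg)) < spec.admixture
    seg_founder = np.where(use_foreign, foreign, base)
    local = np.take_along_axis(seg_founder, seg_id, axis=1)  # (2n, L)
    haps = panel.haplotypes[founders[local], np.arange(L)[None, :]].copy()
    n = spec.n_individuals
    return PhasedPopulation(
        name=spec.name,
        haplotypes=haps,
        positions=panel.positions.copy(),
        chrom=np.full(panel.n_sites, panel.chrom, dtype=object),
        ref=panel.ref.copy(),
        alt=panel.alt.copy(),
        sample_ids=[f"{spec.name}-{i + 1:04d}" for i in range(n)],
        sex=rng.integers(0, spec.sex_levels, size=n),
        batch=rng.integers(0, spec.batch_levels, size=n),
        lineage=lineage_assignment.copy(),
        local_ancestry=local.astype(np.int16),
    )


def concat_sites(*pops: PhasedPopulation) -> PhasedPopulation:
    """Merge per-chromosome samples of the same individuals into one object.

    All inputs must have the same sample count; ids, sex and batch are taken
    from the first.
    """
    first = pops[0]
    if any(p.n != first.n for p in pops):
        raise ValueError("all populations must have the same individuals")
    return PhasedPopulation(
        name=first.name,
        haplotypes=np.hstack([p.haplotypes for p in pops]),
        positions=np.concatenate([p.positions for p in pops]),
        chrom=np.concatenate([p.chrom for p in pops]),
        ref=np.concatenate([p.ref for p in pops]),
        alt=np.concatenate([p.alt for p in pops]),
        sample_ids=first.sample_ids,
        sex=first.sex,
        batch=first.batch,
        lineage=first.lineage,
        local_ancestry=(np.hstack([p.local_ancestry for p in pops])
                        if all(p.local_ancestry is not None for p in pops)
                        else None),
    )


def plant_causal_haplotype(populations: Sequence[PhasedPopulation],
                           window: tuple[str, int, int],
                           hap_string: str,
                           per_pop_frequency: Mapping[str, float],
                           seed: int = 0, *,
                           effect: float | Mapping[str, float] = 0.0,
                           h2: float | Mapping[str, float] = 0.46,
                           sigma_p2: float = 1.0,
                           tolerance: float = 0.05,
                           ) -> tuple[list[PhasedPopulation], TruthRecord]:
    """Plant a causal haplotype segment and return modified copies + truth.

    In every population with a positive target frequency, randomly chosen
    chromosomes have the window substring replaced by `hap_string` until the
    carrier haplotype frequency reaches the target (realized within
    ±1/(2n)).  Populations listed with frequency 0 are returned unchanged.

    `effect` is the per-copy allelic effect in trait units (scalar or
    per-population mapping); `h2` the polygenic heritability of the
    background; `sigma_p2` the target total phenotypic variance from which
    sigma_a2/sigma_e2 are derived after subtracting the planted-QTL
    variance 2f(1-f)a^2.
    """
    chrom, start, end = window
    rng = np.random.default_rng(seed)
    arr = np.array([int(c) for c in hap_string], dtype=np.uint8)
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError("hap_string must be over alphabet {0,1}")

    out: list[PhasedPopulation] = []
    truth = TruthRecord(chrom=chrom, window_start=start, window_end=end,
                        hap_string=hap_string)
    for pop in populations:
        on_chrom = np.where(pop.chrom == chrom)[0]
        if on_chrom.size == 0:
            raise IndexError(f"chromosome {chrom} absent from panel")
        cmin = pop.positions[on_chrom].min()
        cmax = pop.positions[on_chrom].max()
        if start < cmin or end > cmax:
            raise IndexError(
                f"window {chrom}:{start}-{end} outside panel bounds "
                f"{chrom}:{cmin}-{cmax}")
        idx = pop.site_index(chrom, start, end)
        if idx.size != arr.size:
            raise ValueError(
                f"hap_string length {arr.size} does not match the "
                f"{idx.size} sites in the window")

        target = float(per_pop_frequency.get(pop.name, 0.0))
        haps = pop.haplotypes.copy()
        matches = np.all(haps[:, idx] == arr, axis=1)
        n2 = haps.shape[0]
        if target > 0:
            cur = matches.mean()
            if cur > target + tolerance:
                raise PlantingError(
                    f"{pop.name}: background frequency {cur:.3f} already "
                    f"exceeds target {target:.3f}")
            target_count = int(round(target * n2))
            # carriers are filled by local ancestry at the window (in a
            # random founder order, the most common local founder last) so
            # that within a population they share flanking haplotype, as
            # carriers of a real old mutation do, while the major local
            # haplotype stays wild-type; without ancestry labels the
            # choice is plain random
            candidates = np.where(~matches)[0]
            if pop.local_ancestry is not None:
                win_anc = pop.local_ancestry[np.ix_(candidates, idx)]
                # majority founder over the window per chromosome copy
                lin = np.array([np.bincount(row).argmax()
                                for row in win_anc])
                uniq, counts = np.unique(lin, return_counts=True)
                # plant whole local groups in decreasing size starting from
                # the SECOND largest: carriers form a few common, coherent
                # window haplotypes while the major local haplotype stays
                # wild-type and remains the natural reference downstream
                by_size = uniq[np.argsort(-counts, kind="mergesort")]
                lin_order = list(by_size[1:]) + [by_size[0]]
                lin_rank = {l: i for i, l in enumerate(lin_order)}
                jitter = rng.random(candidates.size)
                order = np.lexsort((jitter, np.array([lin_rank[l]
                                                      for l in lin])))
            else:
                order = rng.permutation(candidates.size)
            queue = list(candidates[order])
            attempts = 0
            while matches.sum() < target_count:
                attempts += 1
                if attempts > 10 * n2 or not queue:
                    raise PlantingError(
                        f"{pop.name}: could not reach target frequency "
                        f"{target:.3f} after {attempts} attempts")
                cand = int(queue.pop(0))
                if matches[cand]:
                    continue
                haps[cand, idx] = arr
                matches[cand] = True
        planted = PhasedPopulation(
            name=pop.name, haplotypes=haps, positions=pop.positions,
            chrom=pop.chrom, ref=pop.ref, alt=pop.alt,
            sample_ids=pop.sample_ids, sex=pop.sex, batch=pop.batch,
            lineage=pop.lineage, local_ancestry=pop.local_ancestry)
        out.append(planted)

        a = float(effect[pop.name] if isinstance(effect, Mapping) else effect)
        h2_pop = float(h2[pop.name] if isinstance(h2, Mapping) else h2)
        realized = matches.mean() if target > 0 else float(
            np.all(pop.haplotypes[:, idx] == arr, axis=1).mean())
        var_qtl = 2.0 * realized * (1.0 - realized) * a * a
        resid = max(sigma_p2 - var_qtl, 0.0)
        copies = matches.reshape(-1, 2).sum(axis=1)
        truth.populations[pop.name] = {
            "effect": a,
            "h2": h2_pop,
            "sigma_a2": h2_pop * resid,
            "sigma_e2": (1.0 - h2_pop) * resid,
            "target_freq": target,
            "realized_freq": float(realized),
            "shared": target > 0,
            "carrier_copies": copies.tolist(),
        }
    return out, truth


def simulate_phenotypes(pop: PhasedPopulation,
                        truth: TruthRecord | Sequence[TruthRecord],
                        seed: int = 0, *, mean: float = 0.0) -> pd.DataFrame:
    """Simulate phenotypes y = mu + sex + batch + sum(a * copies) + u + e.

    The polygenic term u is drawn MVN(0, sigma_a2 * G) from the realized
    genomic relationship matrix of the population; e is iid N(0, sigma_e2).
    Sex and batch fixed offsets are multiples of the residual standard
    deviation (sex: 0/+1 sigma_e; batch: 0/+1/+2 sigma_e), large enough to
    require residualization but not to dominate the variance.  Variance
    parameters are taken from the first truth record; all records must
    agree on them.

    Returns a table with columns id, trait, sex, batch.
    """
    truths = [truth] if isinstance(truth, TruthRecord) else list(truth)
    if not truths:
        raise ValueError("at least one truth record required")
    recs = [t.populations[pop.name] for t in truths]
    h2_pop = recs[0]["h2"]
    if any(not np.isclose(r["h2"], h2_pop) for r in recs):
        raise ValueError("truth records disagree on polygenic heritability")

    def _var_qtl(r):
        f = r["realized_freq"]
        return 2.0 * f * (1.0 - f) * r["effect"] ** 2

    # total phenotypic variance implied by the first record; the polygenic
    # and residual parts shrink as more QTL variance is planted
    sigma_p2 = recs[0]["sigma_a2"] + recs[0]["sigma_e2"] + _var_qtl(recs[0])
    resid = max(sigma_p2 - sum(_var_qtl(r) for r in recs), 0.0)
    sigma_a2 = h2_pop * resid
    sigma_e2 = (1.0 - h2_pop) * resid
    if recs[0]["sigma_a2"] < 0 or recs[0]["sigma_e2"] < 0:
        raise ValueError("variance components must be non-negative")

    rng = np.random.default_rng(seed)
    n = pop.n
    y = np.full(n, mean, dtype=np.float64)

    sigma_e = np.sqrt(sigma_e2)
    if pop.sex is not None:
        y += (pop.sex % 2) * sigma_e           # offsets 0 / +1 sigma_e
    if pop.batch is not None:
        y += pop.batch * sigma_e               # offsets 0 / +1 / +2 sigma_e

    for t, r in zip(truths, recs):
        y += r["effect"] * t.carrier_copies(pop.name)

    if sigma_a2 > 0:
        freq = pop.allele_freq()
        poly = (freq > 0) & (freq < 1)
        if poly.any():
            from .gwas import GenotypeMatrix, compute_grm
            grm = compute_grm(GenotypeMatrix.from_phased(pop))
            lam, U = np.linalg.eigh(grm.matrix)
            lam = np.clip(lam, 0.0, None)
            y += U @ (np.sqrt(sigma_a2 * lam) * rng.standard_normal(n))
    if sigma_e2 > 0:
        y += sigma_e * rng.standard_normal(n)

    return pd.DataFrame({
        "id": pop.sample_ids,
        "trait": y,
        "sex": pop.sex if pop.sex is not None else np.zeros(n, dtype=int),
        "batch": pop.batch if pop.batch is not None else np.zeros(n, dtype=int),
    })


def write_fixture(pop: PhasedPopulation, phenotypes: pd.DataFrame,
                  truth: TruthRecord | Sequence[TruthRecord],
                  out_dir: str | Path) -> dict[str, Path]:
    """Write a population fixture (VCF + phenotype TSV + truth JSON)."""
    from . import io as pio
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / f"{pop.name}.vcf",
        "pheno": out / f"{pop.name}.pheno.tsv",
        "truth": out / f"{pop.name}.truth.json",
    }
    pio.write_vcf(pop, paths["vcf"])
    pio.write_phenotypes(phenotypes, paths["pheno"])
    truths = [truth] if isinstance(truth, TruthRecord) else list(truth)
    paths["truth"].write_text(
        json.dumps([t.to_dict() for t in truths], indent=1))
    return paths


def simulate_peaks(truths: Sequence[TruthRecord],
                   chrom_spans: Mapping[str, tuple[int, int]],
                   seed: int = 0, *, n_background: int = 12,
                   peak_width: int = 1000) -> pd.DataFrame:
    """Synthetic regulatory peak intervals (BED-style, 0-based half-open).

    One peak of each mark covers every planted causal window (so lead
    variants are enriched), plus uniform background peaks.  Intended for
    end-to-end runs of the enrichment stage on simulated data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for t in truths:
        for mark in ("H3K27ac", "H3K4me3"):
            rows.append((t.chrom, max(t.window_start - peak_width // 2, 0),
                         t.window_end + peak_width // 2, mark))
    chroms = list(chrom_spans)
    for _ in range(n_background):
        c = chroms[int(rng.integers(len(chroms)))]
        lo, hi = chrom_spans[c]
        s = int(rng.integers(lo, max(hi - peak_width, lo + 1)))
        mark = "H3K27ac" if rng.random() < 0.8 else "H3K4me3"
        rows.append((c, s, s + peak_width, mark))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mark"])


def simulate_genes(truths: Sequence[TruthRecord],
                   chrom_spans: Mapping[str, tuple[int, int]],
                   seed: int = 0, *, n_background: int = 10) -> pd.DataFrame:
    """Synthetic gene spans (GFF3-style, 1-based inclusive).

    One candidate gene is placed near every planted window plus background
    genes scattered over each chromosome.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for t in truths:
        k += 1
        s = max(t.window_end + 1000, 1)
        rows.append((t.chrom, s, s + 5000, f"CAND{k}"))
    chroms = list(chrom_spans)
    for i in range(n_background):
        c = chroms[int(rng.integers(len(chroms)))]
        lo, hi = chrom_spans[c]
        s = int(rng.integers(lo, max(hi - 5000, lo + 1)))
        rows.append((c, s, s + 4000, f"GENE{i + 1}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
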