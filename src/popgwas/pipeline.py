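"""End-to-end orchestration: simulate -> gwas -> meta -> haplo -> enrich.

A :class:`RunConfig` collects every threshold of the analysis (genome-wide
significance 5e-8, 1 Mb sentinel window, 1 Mb novelty distance, 2-unit
enhancement gain, 41-SNP haplotype windows, 0.05 haplotype frequency
cutoff, 500 kb candidate-gene distance) plus the simulation design: six
populations of unequal size sharing one ancestral panel, one causal
haplotype segment shared by three of them and one private to a single
population, polygenic heritability 0.46.  All randomness derives from one
mandatory seed; reruns with the same config reproduce association tables
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import gwas, haplotype as hap, io as pio, meta as meta_mod
from . import simulate as sim
from .errors import PopgwasError

__all__ = ["RunConfig", "run_full_pipeline", "summarize_run",
           "simulate_study"]

log = logging.getLogger("popgwas")


@dataclass
class RunConfig:
    """Flat, serializable configuration of a pipeline run."""

    # orchestration
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "gwas", "meta", "haplo", "enrich"])
    seed: int = 1
    trait: str = "trait"

    # simulation design
    n_chroms: int = 6
    l_sites: int = 150
    pool_size: int = 400
    recomb_rate: float = 0.02
    mutation_density: float = 0.9
    spacing_bp: int = 170
    pop_names: list[str] = field(default_factory=lambda: [
        "pop1", "pop2", "pop3", "pop4", "pop5", "pop6"])
    pop_sizes: list[int] = field(default_factory=lambda: [
        591, 296, 608, 305, 331, 315])
    drift: int = 20
    h2: float = 0.46
    sigma_p2: float = 1.0
    shared_window_bp: int = 3700
    private_window_bp: int = 3700
    shared_pops: list[str] = field(default_factory=lambda: [
        "pop1", "pop2", "pop3"])
    private_pop: str = "pop5"
    shared_freq: float = 0.3
    private_freq: float = 0.25
    shared_effect: float = -0.5
    private_effect: float = 0.8

    # QC and association thresholds
    min_snp_call: float = 0.9
    min_ind_call: float = 0.9
    min_maf: float = 0.05
    threshold: float = 5e-8
    vc_mode: str = "null_reuse"

    # meta / lead bookkeeping
    meta_scheme: str = "samplesize"
    sentinel_window_bp: int = 1_000_000
    novel_distance_bp: int = 1_000_000
    enhanced_gain: float = 2.0

    # haplotype stage
    flank: int = 20
    min_hap_freq: float = 0.05
    hap_alpha: float = 0.01

    # enrichment stage
    gene_distance_bp: int = 500_000

    # external inputs when not simulating
    input_dir: str = ""
    peaks_path: str = ""
    genes_path: str = ""

    def __post_init__(self):
        for name in ("threshold", "sentinel_window_bp", "novel_distance_bp",
                     "enhanced_gain", "flank", "gene_distance_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- flat key=value serialization -------------------------------------
    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, list):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name}={v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, overrides: dict | None = None) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        if overrides:
            raw.update({k: str(v) for k, v in overrides.items()})
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key not in types:
                raise PopgwasError(f"unknown config key: {key}")
            f = types[key]
            default = f.default_factory() if callable(
                getattr(f, "default_factory", None)) and \
                f.default_factory is not dataclasses.MISSING else f.default
            if isinstance(default, list):
                items = [x for x in val.split(",") if x]
                elem = int if default and isinstance(default[0], int) else str
                kwargs[key] = [elem(x) for x in items]
            elif isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _window_near_center(pop: sim.PhasedPopulation, chrom: str,
                        span_bp: int) -> tuple[int, int, np.ndarray]:
    """A window of roughly span_bp centered in the chromosome; returns
    (start, end, site indices)."""
    on = np.where(pop.chrom == chrom)[0]
    pos = pop.positions[on]
    center = pos[len(pos) // 2]
    lo, hi = center - span_bp // 2, center + span_bp // 2
    idx = on[(pos >= lo) & (pos <= hi)]
    return int(pop.positions[idx].min()), int(pop.positions[idx].max()), idx


def simulate_study(cfg: RunConfig):
    """Build the multi-population fixture with one shared and one private
    causal haplotype.

    Returns (pops: dict name->PhasedPopulation, truths: list[TruthRecord],
    phenos: dict name->DataFrame, peaks: DataFrame, genes: DataFrame).
    """
    n_pop = len(cfg.pop_names)
    seeds = _child_seeds(cfg.seed, cfg.n_chroms * (1 + n_pop) + 5 + 2 * n_pop)
    it = iter(seeds)

    specs = {name: sim.PopulationSpec(name=name, n_individuals=size,
                                      drift_parameter=cfg.drift)
             for name, size in zip(cfg.pop_names, cfg.pop_sizes)}
    # one founder-lineage assignment per population, shared by all
    # chromosomes, so relatedness is consistent across the genome
    lineages = {name: sim.draw_lineage_assignment(spec, seed=next(it))
                for name, spec in specs.items()}
    per_chrom_pops: dict[str, list[sim.PhasedPopulation]] = {
        name: [] for name in cfg.pop_names}
    for c in range(cfg.n_chroms):
        chrom = str(c + 1)
        panel = sim.simulate_panel(
            cfg.l_sites, cfg.pool_size, cfg.recomb_rate,
            cfg.mutation_density, seed=next(it), chrom=chrom,
            spacing_bp=cfg.spacing_bp)
        for name in cfg.pop_names:
            per_chrom_pops[name].append(
                sim.sample_population(panel, specs[name], seed=next(it),
                                      lineage_assignment=lineages[name]))
    pops = {name: sim.concat_sites(*chroms)
            for name, chroms in per_chrom_pops.items()}
    pop_list = list(pops.values())

    rng = np.random.default_rng(next(it))
    truths: list[sim.TruthRecord] = []

    s0, e0, idx0 = _window_near_center(pop_list[0], "1", cfg.shared_window_bp)
    hap_shared = "".join(str(b) for b in rng.integers(0, 2, size=idx0.size))
    pop_list, t_shared = sim.plant_causal_haplotype(
        pop_list, ("1", s0, e0), hap_shared,
        {p: cfg.shared_freq for p in cfg.shared_pops}, seed=next(it),
        effect={p: (cfg.shared_effect if p in cfg.shared_pops else 0.0)
                for p in cfg.pop_names},
        h2=cfg.h2, sigma_p2=cfg.sigma_p2)
    truths.append(t_shared)

    if cfg.n_chroms > 1 and cfg.private_pop:
        s1, e1, idx1 = _window_near_center(pop_list[0], "2",
                                           cfg.private_window_bp)
        hap_priv = "".join(str(b) for b in rng.integers(0, 2, size=idx1.size))
        pop_list, t_priv = sim.plant_causal_haplotype(
            pop_list, ("2", s1, e1), hap_priv,
            {cfg.private_pop: cfg.private_freq}, seed=next(it),
            effect={p: (cfg.private_effect if p == cfg.private_pop else 0.0)
                    for p in cfg.pop_names},
            h2=cfg.h2, sigma_p2=cfg.sigma_p2)
        truths.append(t_priv)

    pops = {p.name: p for p in pop_list}
    phenos = {name: sim.simulate_phenotypes(pop, truths, seed=next(it))
              for name, pop in pops.items()}

    spans = {}
    for pop in pop_list[:1]:
        for chrom in dict.fromkeys(pop.chrom):
            on = pop.chrom == chrom
            spans[chrom] = (int(pop.positions[on].min()),
                            int(pop.positions[on].max()))
    peaks = sim.simulate_peaks(truths, spans, seed=next(it))
    genes = sim.simulate_genes(truths, spans, seed=next(it))
    return pops, truths, phenos, peaks, genes


def _gwas_one(pop: sim.PhasedPopulation, pheno: pd.DataFrame,
              cfg: RunConfig):
    """QC + residualize + GRM + REML + scan for one population.

    Genomic heritability is estimated on the whole-genome GRM; the scan
    uses a leave-one-chromosome-out (LOCO) GRM per chromosome when more
    than one chromosome is present, so the tested locus never contributes
    to the relationship matrix it is tested against.
    """
    aligned = pio.attach_covariates(pop, pheno)
    resid = gwas.residualize(aligned["trait"].to_numpy(),
                             aligned[["sex", "batch"]])
    geno = gwas.qc_filter(gwas.GenotypeMatrix.from_phased(pop),
                          cfg.min_snp_call, cfg.min_ind_call, cfg.min_maf)
    grm = gwas.compute_grm(geno)
    vc = gwas.reml_fit(resid, grm)
    chroms = list(dict.fromkeys(geno.chrom))
    loco: dict[str, tuple[gwas.GRM, gwas.VarianceComponents]] = {}
    if len(chroms) > 1:
        pieces = []
        for chrom in chroms:
            g_scan = geno.take_snps(geno.chrom == chrom)
            g_rest = geno.take_snps(geno.chrom != chrom)
            grm_loco = gwas.compute_grm(g_rest)
            vc_loco = gwas.reml_fit(resid, grm_loco)
            loco[chrom] = (grm_loco, vc_loco)
            pieces.append(gwas.lmm_scan(resid, g_scan, grm_loco, vc=vc_loco,
                                        vc_mode=cfg.vc_mode))
        assoc = pd.concat(pieces, ignore_index=True)
    else:
        loco[chroms[0]] = (grm, vc)
        assoc = gwas.lmm_scan(resid, geno, grm, vc=vc, vc_mode=cfg.vc_mode)
    leads = gwas.call_lead_snps(assoc, trait=cfg.trait,
                                threshold=cfg.threshold, population=pop.name)
    ve = []
    for _, r in leads.iterrows():
        j = int(np.where((geno.chrom == r["chrom"])
                         & (geno.pos == r["pos"]))[0][0])
        x = geno.dosages[:, j]
        x = np.where(np.isnan(x), np.nanmean(x), x)
        ve.append(gwas.variance_explained_residual(resid.values, x))
    leads = leads.assign(var_explained=ve)
    return {"resid": resid, "geno": geno, "grm": grm, "vc": vc,
            "loco": loco, "assoc": assoc, "leads": leads, "pop": pop}


def run_full_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the selected stages, writing artifacts and a manifest.

    Stage outputs: data/ (VCF, phenotype TSV, truth, peaks, genes),
    <pop>.assoc.tsv, <pop>.leads.tsv, <pop>.vc.json, meta.tsv,
    meta.leads.tsv, sentinels.tsv, haplo_<chrom>_<pos>.{effects.tsv,
    segment.json,nwk}, enrichment.json, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "init"
    try:
        (out / "config.txt").write_text(cfg.to_text())
        data_dir = out / "data"
        pops: dict[str, sim.PhasedPopulation] = {}
        phenos: dict[str, pd.DataFrame] = {}
        truths: list[sim.TruthRecord] = []
        peaks_path = Path(cfg.peaks_path) if cfg.peaks_path else None
        genes_path = Path(cfg.genes_path) if cfg.genes_path else None

        if "simulate" in cfg.stages:
            stage = "simulate"
            log.info("stage simulate: %d populations", len(cfg.pop_names))
            pops, truths, phenos, peaks_df, genes_df = simulate_study(cfg)
            data_dir.mkdir(exist_ok=True)
            for name, pop in pops.items():
                sim.write_fixture(pop, phenos[name], truths, data_dir)
            peaks_path = data_dir / "peaks.bed"
            with open(peaks_path, "w") as fh:
                for _, r in peaks_df.iterrows():
                    fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t"
                             f"{r['mark']}\n")
            genes_path = data_dir / "genes.gff3"
            with open(genes_path, "w") as fh:
                fh.write("##gff-version 3\n")
                for i, r in genes_df.iterrows():
                    fh.write(f"{r['chrom']}\tpopgwas\tgene\t{r['start']}\t"
                             f"{r['end']}\t.\t+\t.\tID=gene{i};"
                             f"Name={r['name']}\n")
        else:
            src = Path(cfg.input_dir) if cfg.input_dir else data_dir
            for name in cfg.pop_names:
                vcf = src / f"{name}.vcf"
                pheno = src / f"{name}.pheno.tsv"
                if not vcf.exists():
                    raise PopgwasError(f"genotype file not found: {vcf}")
                if not pheno.exists():
                    raise PopgwasError(f"phenotype file not found: {pheno}")
                pops[name] = pio.read_vcf(vcf, name=name)
                phenos[name] = pio.read_phenotypes(pheno)
            tpath = src / f"{cfg.pop_names[0]}.truth.json"
            if tpath.exists():
                truths = pio.read_truth(tpath)

        results: dict[str, dict] = {}
        if "gwas" in cfg.stages:
            stage = "gwas"
            for name, pop in pops.items():
                log.info("stage gwas: population %s (n=%d)", name, pop.n)
                res = _gwas_one(pop, phenos[name], cfg)
                results[name] = res
                pio.write_assoc(res["assoc"], out / f"{name}.assoc.tsv")
                res["leads"].to_csv(out / f"{name}.leads.tsv", sep="\t",
                                    index=False)
                vc = res["vc"]
                (out / f"{name}.vc.json").write_text(json.dumps({
                    "sigma_a2": vc.sigma_a2, "sigma_e2": vc.sigma_e2,
                    "delta": vc.delta, "h2": vc.h2, "loglik": vc.loglik,
                    "boundary": vc.boundary}, indent=1))

        meta_df = pd.DataFrame()
        meta_leads = pd.DataFrame()
        all_leads = pd.DataFrame()
        if "meta" in cfg.stages:
            stage = "meta"
            log.info("stage meta: %d populations", len(results))
            tables = {name: res["assoc"] for name, res in results.items()}
            if not tables:
                tables = {p.stem.replace(".assoc", ""): pio.read_assoc(p)
                          for p in sorted(out.glob("*.assoc.tsv"))}
            meta_df, meta_leads = meta_mod.meta_scan(
                tables, scheme=cfg.meta_scheme, threshold=cfg.threshold,
                trait=cfg.trait)
            pio.write_assoc(meta_df, out / "meta.tsv") if not meta_df.empty \
                else (out / "meta.tsv").write_text("")
            single_leads = pd.concat(
                [res["leads"] for res in results.values()],
                ignore_index=True) if results else pd.DataFrame()
            if not meta_leads.empty and not single_leads.empty:
                meta_leads = gwas.classify_leads(
                    meta_leads, single_leads, cfg.novel_distance_bp,
                    cfg.enhanced_gain)
            if not meta_leads.empty and results:
                # MAF and variance explained of meta leads, taken from the
                # populations carrying the variant (largest-n MAF, max VE)
                mafs, ves = [], []
                for _, r in meta_leads.iterrows():
                    maf, best_n, ve = np.nan, -1, np.nan
                    for res in results.values():
                        geno = res["geno"]
                        j = np.where((geno.chrom == r["chrom"])
                                     & (geno.pos == r["pos"]))[0]
                        if j.size == 0:
                            continue
                        j = int(j[0])
                        if geno.n > best_n:
                            best_n = geno.n
                            maf = geno.maf()[j]
                        x = geno.dosages[:, j]
                        x = np.where(np.isnan(x), np.nanmean(x), x)
                        v = gwas.variance_explained_residual(
                            res["resid"].values, x)
                        ve = v if np.isnan(ve) else max(ve, v)
                    mafs.append(maf)
                    ves.append(ve)
                meta_leads = meta_leads.assign(maf=mafs, var_explained=ves)
            meta_leads.to_csv(out / "meta.leads.tsv", sep="\t", index=False)
            pieces = [df for df in (single_leads, meta_leads) if not df.empty]
            if pieces:
                common = ["chrom", "pos", "maf", "n", "p", "trait",
                          "population"]
                frames = []
                for df in pieces:
                    d = df.copy()
                    for c in common:
                        if c not in d.columns:
                            d[c] = np.nan
                    extra = [c for c in ("var_explained", "classification")
                             if c in d.columns]
                    frames.append(d[common + extra])
                all_leads = pd.concat(frames, ignore_index=True)
                sentinels = gwas.sentinel_merge(all_leads,
                                                cfg.sentinel_window_bp)
            else:
                sentinels = pd.DataFrame(columns=[
                    "chrom", "pos", "maf", "n", "p", "trait", "population",
                    "n_merged"])
            sentinels.to_csv(out / "sentinels.tsv", sep="\t", index=False)

        if "haplo" in cfg.stages:
            stage = "haplo"
            lead_rows = meta_leads if not meta_leads.empty else pd.concat(
                [res["leads"] for res in results.values()],
                ignore_index=True) if results else pd.DataFrame()
            for _, lead in lead_rows.iterrows():
                chrom, pos = str(lead["chrom"]), int(lead["pos"])
                log.info("stage haplo: locus %s:%d", chrom, pos)
                tag = f"haplo_{chrom}_{pos}"
                # haplotype selection is restricted to populations in which
                # the locus itself is detected (a lead SNP within the
                # sentinel window), as the segment comparison is only
                # meaningful where the association exists
                qualifying = set()
                for name, res in results.items():
                    lds = res["leads"]
                    near = lds[(lds["chrom"].astype(str) == chrom)
                               & ((lds["pos"] - pos).abs()
                                  <= cfg.sentinel_window_bp)]
                    if len(near):
                        qualifying.add(name)
                effects_rows = []
                sig_rows = []  # (pop, haplotype, beta, p) significant ones
                window_sets = {}
                for name, res in results.items():
                    pop = res["pop"]
                    try:
                        hset = hap.extract_window(pop, (chrom, pos),
                                                  k=cfg.flank)
                    except KeyError:
                        continue
                    window_sets[name] = hset
                    H = hap.build_incidence(hset, cfg.min_hap_freq)
                    # whiten against the LOCO covariance so the tested
                    # locus does not contribute to the matrix it is tested
                    # against
                    grm_h, vc_h = res["loco"].get(chrom,
                                                  (res["grm"], res["vc"]))
                    eff = hap.estimate_haplotype_effects(
                        res["resid"], H, vc_h, grm_h)
                    for _, e in eff.iterrows():
                        effects_rows.append({
                            "population": name, "haplotype": e["haplotype"],
                            "frequency": e["frequency"], "beta": e["beta"],
                            "se": e["se"], "p": e["p"],
                            "is_reference": e["is_reference"],
                            "beta_centered": e["beta_centered"],
                            "se_centered": e["se_centered"],
                            "p_centered": e["p_centered"]})
                    if name not in qualifying:
                        continue
                    # centered effects are polarity-comparable across
                    # populations even when reference haplotypes differ
                    sig = eff[(eff["haplotype"] != "<rare>")
                              & (eff["p_centered"] < cfg.hap_alpha)]
                    for _, e in sig.iterrows():
                        sig_rows.append((name, str(e["haplotype"]),
                                         float(e["beta_centered"]),
                                         float(e["p_centered"])))
                pd.DataFrame(effects_rows).to_csv(
                    out / f"{tag}.effects.tsv", sep="\t", index=False)
                # shared-segment input: significant haplotypes whose effect
                # sign matches the overall strongest one, drawn from >= 2
                # populations
                seg = None
                selected: list[str] = []
                if sig_rows:
                    lead_sign = np.sign(min(sig_rows,
                                            key=lambda r: r[3])[2])
                    chosen = [r for r in sig_rows
                              if np.sign(r[2]) == lead_sign]
                    if len({r[0] for r in chosen}) >= 2:
                        selected = [r[1] for r in chosen]
                        first = next(iter(window_sets.values()))
                        seg = hap.shared_segment(selected, first.positions)
                (out / f"{tag}.segment.json").write_text(json.dumps({
                    "chrom": chrom, "lead_pos": pos,
                    "n_selected_haplotypes": len(selected),
                    "segment": ({"start": seg[0], "end": seg[1],
                                 "length_bp": seg[1] - seg[0] + 1}
                                if seg else None)}, indent=1))
                labels, strings = [], []
                for name, hset in window_sets.items():
                    for i, (h, f) in enumerate(zip(hset.haplotypes,
                                                   hset.frequencies)):
                        if f > cfg.min_hap_freq:
                            labels.append(f"{name}-Hap{i + 1}")
                            strings.append(h)
                if len(strings) >= 2:
                    D = hap.hamming_distance_matrix(strings)
                    (out / f"{tag}.nwk").write_text(
                        hap.neighbor_joining(D, labels) + "\n")

        if "enrich" in cfg.stages:
            stage = "enrich"
            log.info("stage enrich")
            if peaks_path is None or not Path(peaks_path).exists():
                raise PopgwasError(f"peaks file not found: {peaks_path}")
            peaks = enr.read_peaks(peaks_path)
            if all_leads.empty and results:
                all_leads = pd.concat([res["leads"]
                                       for res in results.values()],
                                      ignore_index=True)
            background = pd.concat(
                [res["assoc"][["chrom", "pos"]]
                 for res in results.values()],
                ignore_index=True).drop_duplicates() if results else \
                pd.DataFrame()
            if not all_leads.empty and not background.empty:
                lead_pos = all_leads[["chrom", "pos"]].drop_duplicates()
                result = enr.fold_enrichment(lead_pos, background, peaks)
                payload = {
                    "lead_proportion": result.lead_proportion,
                    "background_proportion": result.background_proportion,
                    "fold": (None if result.fold_undefined
                             else result.fold),
                    "lead_count": result.lead_count,
                    "lead_total": result.lead_total,
                    "background_count": result.background_count,
                    "background_total": result.background_total,
                    "per_mark": result.per_mark,
                }
                (out / "enrichment.json").write_text(
                    json.dumps(payload, indent=1))
                if genes_path is not None and Path(genes_path).exists():
                    genes = enr.read_genes(genes_path)
                    gene_hits = enr.nearest_genes(lead_pos, genes,
                                                  cfg.gene_distance_bp)
                    rows = []
                    for (_, v), hits in zip(lead_pos.iterrows(), gene_hits):
                        rows.append({
                            "chrom": v["chrom"], "pos": v["pos"],
                            "genes": ";".join(
                                f"{g}({d})" for g, d in hits)})
                    pd.DataFrame(rows).to_csv(out / "candidate_genes.tsv",
                                              sep="\t", index=False)

        manifest = {
            "package": "popgwas 0.1.0",
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "stages": cfg.stages,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def summarize_run(run_dir: str | Path) -> pd.DataFrame:
    """One row per sentinel: locus, trait, population, p, MAF, variance
    explained, classification, candidate genes.

    Incomplete runs yield a partial summary with a warning.
    """
    import warnings

    run = Path(run_dir)
    cols = ["locus", "trait", "population", "p", "maf", "var_explained",
            "classification", "candidate_genes"]
    spath = run / "sentinels.tsv"
    if not spath.exists():
        warnings.warn(f"no sentinel table in {run}; summary is empty")
        return pd.DataFrame(columns=cols)
    sent = pd.read_csv(spath, sep="\t", dtype={"chrom": str})
    if sent.empty:
        return pd.DataFrame(columns=cols)
    genes = {}
    gpath = run / "candidate_genes.tsv"
    if gpath.exists():
        g = pd.read_csv(gpath, sep="\t", dtype={"chrom": str})
        genes = {(str(r["chrom"]), int(r["pos"])): r.get("genes", "")
                 for _, r in g.iterrows()}
    else:
        warnings.warn("candidate gene table missing; summary is partial")
    rows = []
    for _, r in sent.iterrows():
        key = (str(r["chrom"]), int(r["pos"]))
        rows.append({
            "locus": f"{r['chrom']}:{r['pos']}",
            "trait": r.get("trait", ""),
            "population": r.get("population", ""),
            "p": r["p"],
            "maf": r.get("maf", np.nan),
            "var_explained": r.get("var_explained", np.nan),
            "classification": r.get("classification", ""),
            "candidate_genes": genes.get(key, ""),
        })
    return pd.DataFrame(rows, columns=cols)
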