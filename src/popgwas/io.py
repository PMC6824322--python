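"""Readers and writers for the standard file formats used by the pipeline.

Phased genotypes travel as VCF 4.2 with pipe-separated GT; phenotypes and
association statistics as tab-separated tables; planted ground truth as
JSON.  Reading a VCF uses cyvcf2 and requires phased genotypes throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PhasedPopulation, TruthRecord

PHENO_COLUMNS = ["id", "trait", "sex", "batch"]
ASSOC_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele",
                 "maf", "n", "beta", "se", "p"]


def write_vcf(pop: PhasedPopulation, path: str | Path) -> Path:
    """Write a phased population as VCF 4.2 (GT only, '|' separator)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             "##source=popgwas-simulate"]
    for chrom in dict.fromkeys(pop.chrom):  # preserve order
        length = int(pop.positions[pop.chrom == chrom].max()) + 1000
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pop.sample_ids))
    a = pop.haplotypes[0::2]
    b = pop.haplotypes[1::2]
    for j in range(pop.n_sites):
        gts = "\t".join(f"{x}|{y}" for x, y in zip(a[:, j], b[:, j]))
        lines.append(f"{pop.chrom[j]}\t{pop.positions[j]}\t"
                     f"{pop.chrom[j]}_{pop.positions[j]}\t{pop.ref[j]}\t"
                     f"{pop.alt[j]}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path, name: str | None = None) -> PhasedPopulation:
    """Read a phased VCF into a :class:`PhasedPopulation`.

    Raises ValueError if any genotype is unphased (statistical phasing is
    out of scope; input must be phased upstream).
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    chroms, positions, refs, alts = [], [], [], []
    hap_cols = []
    for v in vcf:
        gts = v.genotypes  # list of [a0, a1, phased]
        col = np.empty(2 * n, dtype=np.uint8)
        for i, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} sample "
                    f"{samples[i]}; phase the input before analysis")
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        hap_cols.append(col)
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
    vcf.close()
    haps = (np.stack(hap_cols, axis=1) if hap_cols
            else np.empty((2 * n, 0), dtype=np.uint8))
    return PhasedPopulation(
        name=name or path.stem.replace(".vcf", ""),
        haplotypes=haps,
        positions=np.asarray(positions, dtype=np.int64),
        chrom=np.asarray(chroms, dtype=object),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        sample_ids=samples,
    )


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.loc[:, PHENO_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return df


def attach_covariates(pop: PhasedPopulation, pheno: pd.DataFrame) -> pd.DataFrame:
    """Align a phenotype table to a population's sample order.

    Sets pop.sex / pop.batch from the table and returns the reordered table.
    """
    indexed = pheno.set_index("id")
    missing = [s for s in pop.sample_ids if s not in indexed.index]
    if missing:
        raise ValueError(f"phenotypes missing for samples: {missing[:5]}...")
    aligned = indexed.loc[pop.sample_ids].reset_index()
    pop.sex = pd.Categorical(aligned["sex"]).codes.astype(np.int64)
    pop.batch = pd.Categorical(aligned["batch"]).codes.astype(np.int64)
    return aligned


def write_truth(truths, path: str | Path) -> Path:
    path = Path(path)
    items = truths if isinstance(truths, (list, tuple)) else [truths]
    path.write_text(json.dumps([t.to_dict() for t in items], indent=1))
    return path


def read_truth(path: str | Path) -> list[TruthRecord]:
    return [TruthRecord.from_dict(d)
            for d in json.loads(Path(path).read_text())]


def write_assoc(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_assoc(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ASSOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    return df
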