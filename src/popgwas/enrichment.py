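"""Overlap of lead variants with regulatory peaks and gene annotations.

Peak intervals (e.g. H3K27ac / H3K4me3 ChIP-seq peaks) arrive as BED
(0-based, half-open) and are stored 1-based inclusive; overlapping or
abutting intervals of the same mark are merged on read.  Enrichment of a
lead-variant set is reported as the fold ratio of its in-peak proportion
over that of the background of all tested SNPs, overall and per mark.
Candidate genes are looked up within a distance cutoff of each lead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import BedParseError

__all__ = ["PeakSet", "EnrichmentResult", "read_peaks", "peaks_from_frame",
           "overlap_proportion", "fold_enrichment", "nearest_genes",
           "read_genes"]


@dataclass
class PeakSet:
    """Merged, labeled genomic intervals, stored 1-based inclusive."""

    intervals: pd.DataFrame  # columns chrom, start, end, mark
    source: str = ""
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        df = self.intervals
        if len(df) and not (df["start"] <= df["end"]).all():
            raise ValueError("intervals must satisfy start <= end")
        for (chrom, mark), grp in df.groupby(["chrom", "mark"], sort=False):
            tree = IntervalTree()
            for _, r in grp.iterrows():
                # IntervalTree is half-open; +1 makes the end inclusive
                tree[int(r["start"]): int(r["end"]) + 1] = mark
            self._trees[(str(chrom), str(mark))] = tree

    @property
    def marks(self) -> list[str]:
        return sorted(set(self.intervals["mark"])) if len(self.intervals) else []

    def contains(self, chrom: str, pos: int,
                 marks: list[str] | None = None) -> bool:
        use = marks if marks is not None else self.marks
        return any(self._trees.get((str(chrom), m), IntervalTree())
                   .overlaps(int(pos)) for m in use)


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting 1-based inclusive intervals per
    (chrom, mark)."""
    rows = []
    for (chrom, mark), grp in df.groupby(["chrom", "mark"], sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for _, r in grp.iterrows():
            s, e = int(r["start"]), int(r["end"])
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:  # overlap or abutting
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e, mark))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, mark))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mark"])


def read_peaks(path: str | Path) -> PeakSet:
    """Read a 3+ column BED file of peaks.

    BED coordinates (0-based, half-open) are converted to 1-based
    inclusive; the 4th column, when present, is the mark label (default
    'peak').  Malformed lines raise :class:`BedParseError` with the line
    number.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise BedParseError(lineno, f"expected >= 3 columns, got "
                                f"{len(fields)}")
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError as exc:
            raise BedParseError(lineno, f"non-integer coordinate: {exc}")
        if end <= start:
            raise BedParseError(lineno, f"end {end} <= start {start}")
        mark = fields[3] if len(fields) > 3 else "peak"
        rows.append((fields[0], start + 1, end, mark))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mark"])
    return PeakSet(intervals=_merge_intervals(df), source=str(path))


def peaks_from_frame(df: pd.DataFrame, coords: str = "bed") -> PeakSet:
    """Build a PeakSet from an in-memory table.

    coords='bed' treats start/end as 0-based half-open (converted);
    coords='inclusive' takes them as already 1-based inclusive.
    """
    d = df.copy()
    if coords == "bed":
        d["start"] = d["start"].astype(int) + 1
        d["end"] = d["end"].astype(int)
    return PeakSet(intervals=_merge_intervals(d), source="<frame>")


def overlap_proportion(variants: pd.DataFrame, peaks: PeakSet,
                       marks: list[str] | None = None
                       ) -> tuple[float, int]:
    """Fraction (and count) of variants inside >= 1 selected-mark interval.

    A variant inside peaks of several marks counts once.  `variants` needs
    columns chrom and pos (1-based).
    """
    if len(variants) == 0:
        raise ValueError("empty variant set")
    count = sum(peaks.contains(r["chrom"], r["pos"], marks)
                for _, r in variants.iterrows())
    return count / len(variants), int(count)


@dataclass
class EnrichmentResult:
    lead_proportion: float
    background_proportion: float
    fold: float
    lead_count: int
    lead_total: int
    background_count: int
    background_total: int
    fold_undefined: bool
    per_mark: dict[str, dict]


def fold_enrichment(leads: pd.DataFrame, background: pd.DataFrame,
                    peaks: PeakSet,
                    marks: list[str] | None = None) -> EnrichmentResult:
    """Fold enrichment of leads over background in the selected peaks,
    with a per-mark breakdown."""
    lead_prop, lead_n = overlap_proportion(leads, peaks, marks)
    bg_prop, bg_n = overlap_proportion(background, peaks, marks)
    undefined = bg_prop == 0.0
    fold = np.nan if undefined else lead_prop / bg_prop
    per_mark = {}
    for mark in (marks if marks is not None else peaks.marks):
        lp, lc = overlap_proportion(leads, peaks, [mark])
        bp, bc = overlap_proportion(background, peaks, [mark])
        per_mark[mark] = {
            "lead_proportion": lp, "background_proportion": bp,
            "fold": np.nan if bp == 0 else lp / bp,
            "lead_count": lc, "background_count": bc,
        }
    return EnrichmentResult(
        lead_proportion=lead_prop, background_proportion=bg_prop,
        fold=fold, lead_count=lead_n, lead_total=len(leads),
        background_count=bg_n, background_total=len(background),
        fold_undefined=undefined, per_mark=per_mark)


def read_genes(path: str | Path) -> pd.DataFrame:
    """Gene features (chrom, start, end, name) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:",
                            merge_strategy="create_unique", force=True)
    rows = []
    for g in db.features_of_type("gene"):
        name = (g.attributes.get("Name") or g.attributes.get("ID")
                or [g.id])[0]
        rows.append((g.seqid, g.start, g.end, name))
    if not rows:
        warnings.warn("no gene features found in the annotation")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def nearest_genes(variants: pd.DataFrame, genes: pd.DataFrame,
                  max_dist: int = 500_000) -> list[list[tuple[str, int]]]:
    """Genes whose span lies within `max_dist` bp of each variant.

    Returns, per variant, a list of (gene name, distance) sorted by
    distance; distance 0 when the variant falls inside the gene span.
    The bound is inclusive (a gene exactly max_dist away is reported).
    """
    if len(genes) == 0:
        warnings.warn("empty gene annotation; returning empty lists")
        return [[] for _ in range(len(variants))]
    out = []
    for _, v in variants.iterrows():
        sub = genes[genes["chrom"].astype(str) == str(v["chrom"])]
        hits = []
        for _, g in sub.iterrows():
            if g["start"] <= v["pos"] <= g["end"]:
                d = 0
            else:
                d = int(min(abs(v["pos"] - g["start"]),
                            abs(v["pos"] - g["end"])))
            if d <= max_dist:
                hits.append((str(g["name"]), d))
        hits.sort(key=lambda t: (t[1], t[0]))
        out.append(hits)
    return out
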