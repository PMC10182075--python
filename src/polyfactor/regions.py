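"""Genomic-region definition and cross-GWAS merging.

A region starts from all variants below a seeding p-value (1e-6 by
default) on one chromosome; consecutive seeds further apart than a gap
threshold (250 kb, strict) split into separate regions. A region is
*significant* when at least one member reaches genome-wide significance
(5e-8). Regions from different GWAS that overlap are merged transitively,
with boundaries redefined as the min/max positions across all overlapping
regions. Regions touching the extended MHC window (chr6:25-35 Mb) can be
excluded wholesale.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

HLA_CHROM = 6
HLA_START = 25_000_000
HLA_END = 35_000_000


@dataclass
class GenomicRegion:
    chrom: int
    start: int
    end: int
    traits: set = field(default_factory=set)
    lead: dict = field(default_factory=dict)   # trait -> (rsid, p)
    significant: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must not exceed end")

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (self.chrom == other.chrom and self.start <= other.end
                and other.start <= self.end)

    @property
    def min_p(self) -> float:
        return min((p for _, p in self.lead.values()), default=1.0)

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def define_regions(gwas: pd.DataFrame, trait: str = "gwas",
                   p_seed: float = 1e-6, gap_kb: float = 250.0,
                   p_sig: float = 5e-8) -> list[GenomicRegion]:
    """Chain sub-threshold variants into regions, per chromosome.

    A gap strictly greater than ``gap_kb`` kilobases between consecutive
    seed variants splits the chain. Every chained region is returned; the
    ``significant`` flag marks those containing a variant with p < p_sig.
    """
    if gwas.empty:
        return []
    seeds = gwas[gwas["P"] < p_seed].sort_values(
        ["CHR", "BP"], kind="mergesort")
    if seeds.empty:
        return []
    gap_bp = int(gap_kb * 1000)
    regions = []
    for chrom, grp in seeds.groupby("CHR", sort=True):
        bp = grp["BP"].to_numpy()
        p = grp["P"].to_numpy()
        snp = grp["SNP"].to_numpy()
        start_i = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or bp[i] - bp[i - 1] > gap_bp:
                sl = slice(start_i, i)
                best = sl.start + int(p[sl].argmin())
                regions.append(GenomicRegion(
                    chrom=int(chrom), start=int(bp[sl.start]),
                    end=int(bp[i - 1]), traits={trait},
                    lead={trait: (str(snp[best]), float(p[best]))},
                    significant=bool((p[sl] < p_sig).any())))
                start_i = i
    return regions


def merge_regions(per_gwas: list[list[GenomicRegion]]) -> list[GenomicRegion]:
    """Merge overlapping regions across GWAS, transitively.

    A chain of pairwise overlaps collapses into a single region spanning
    the minimum and maximum positions; trait sets and per-trait leads are
    unioned, and the merged region is significant if any member was.
    """
    flat = sorted((r for regs in per_gwas for r in regs),
                  key=lambda r: (r.chrom, r.start, r.end))
    merged: list[GenomicRegion] = []
    for r in flat:
        if merged and merged[-1].overlaps(r):
            cur = merged[-1]
            cur.end = max(cur.end, r.end)
            cur.traits |= r.traits
            for t, (rsid, p) in r.lead.items():
                if t not in cur.lead or p < cur.lead[t][1]:
                    cur.lead[t] = (rsid, p)
            cur.significant = cur.significant or r.significant
        else:
            merged.append(GenomicRegion(
                chrom=r.chrom, start=r.start, end=r.end,
                traits=set(r.traits), lead=dict(r.lead),
                significant=r.significant))
    return merged


def exclude_hla(regions: list[GenomicRegion], chrom: int = HLA_CHROM,
                start: int = HLA_START, end: int = HLA_END):
    """Drop regions with any overlap of the extended MHC window."""
    window = GenomicRegion(chrom=chrom, start=start, end=end)
    return [r for r in regions if not r.overlaps(window)]


def regions_to_frame(regions: list[GenomicRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({"CHR": r.chrom, "START": r.start, "END": r.end,
                     "TRAITS": ",".join(sorted(r.traits)),
                     "LEAD": ";".join(f"{t}:{rsid}"
                                      for t, (rsid, _) in sorted(r.lead.items())),
                     "MIN_P": r.min_p, "SIGNIFICANT": r.significant})
    return pd.DataFrame(rows, columns=["CHR", "START", "END", "TRAITS",
                                       "LEAD", "MIN_P", "SIGNIFICANT"])


def write_regions(regions: list[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("# 1-based inclusive coordinates\n")
        regions_to_frame(regions).to_csv(fh, sep="\t", index=False)
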