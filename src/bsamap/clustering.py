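"""Grouping of candidate markers into genomic regions (linkage-drag blocks).

Single-linkage merging: consecutive candidates on the same chromosome whose
gap is at most ``max_gap`` join one region.  Spans are reported 1-based
inclusive (end - start in bp), in Mbp, and as an approximate genetic span
using a uniform cM/Mbp rate; BED export uses 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import DEFAULT_CM_PER_MBP

REGION_COLUMNS = ["chrom", "start", "end", "span_bp", "span_mbp", "span_cm",
                  "n_candidates"]


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int      # 1-based inclusive
    end: int
    n_candidates: int
    cm_per_mbp: float = DEFAULT_CM_PER_MBP

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.n_candidates < 1:
            raise ValueError("a region needs at least one candidate")

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def span_mbp(self) -> float:
        return self.span_bp / 1e6

    @property
    def span_cm(self) -> float:
        return self.span_mbp * self.cm_per_mbp


def cluster_candidates(candidates: pd.DataFrame, max_gap: int = 1_000_000,
                       cm_per_mbp: float = DEFAULT_CM_PER_MBP,
                       ) -> list[CandidateRegion]:
    """Single-linkage clustering of candidate positions into regions.

    ``candidates`` needs columns ``chrom`` and ``pos``; ordering of the
    input does not matter.  Regions are returned sorted by (chrom, start)
    and are disjoint by construction.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be > 0")
    regions: list[CandidateRegion] = []
    if candidates.empty:
        return regions
    df = candidates.sort_values(["chrom", "pos"])
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        start = prev = int(pos[0])
        n = 1
        for p in pos[1:]:
            p = int(p)
            if p - prev <= max_gap:
                prev, n = p, n + 1
            else:
                regions.append(CandidateRegion(chrom, start, prev, n, cm_per_mbp))
                start = prev = p
                n = 1
        regions.append(CandidateRegion(chrom, start, prev, n, cm_per_mbp))
    return regions


def regions_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = [(r.chrom, r.start, r.end, r.span_bp, r.span_mbp, r.span_cm,
             r.n_candidates) for r in regions]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def regions_bed(regions: list[CandidateRegion]) -> pd.DataFrame:
    """0-based half-open BED representation of the regions."""
    rows = [(r.chrom, r.start - 1, r.end, f"region_{i + 1}", r.n_candidates)
            for i, r in enumerate(regions)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
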