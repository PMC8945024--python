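"""Differentially methylated regions by gap-chaining of significant CpGs.

A region is a run of significant probes (p below threshold) on one
chromosome, all changing in the same direction, with consecutive gaps no
larger than ``max_gap_bp``.  A run is reported as a DMR iff it has at
least ``min_cpgs`` members and at least one member whose |delta-beta|
exceeds ``delta_threshold``.  The region p-value combines member p-values
by Stouffer's method (equal weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class Region:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    probe_ids: list[str] = field(default_factory=list)
    effects: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)
    region_p: float = 1.0
    max_abs_delta: float = 0.0
    direction: str = "GAIN"

    @property
    def n_cpgs(self) -> int:
        return len(self.probe_ids)


def _stouffer(p_values: np.ndarray) -> float:
    """Two-sided Stouffer combination of equally-weighted p-values."""
    z = stats.norm.isf(np.asarray(p_values) / 2.0)
    z = np.clip(z, -38, 38)
    combined = z.sum() / np.sqrt(len(z))
    return float(min(1.0, 2.0 * stats.norm.sf(combined)))


def call_dmrs(
    stats_df: pd.DataFrame,
    annot: pd.DataFrame,
    max_gap_bp: int = 1000,
    min_cpgs: int = 3,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.05,
) -> list[Region]:
    """Call DMRs from per-probe statistics.

    ``stats_df`` needs columns ``effect`` and ``p`` (indexed by probe_id);
    ``annot`` supplies ``chrom`` and ``pos``.  Probes are sorted internally
    (with a warning if they arrived unsorted).
    """
    df = stats_df[["effect", "p"]].join(annot[["chrom", "pos"]])
    sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort")
    if not (df["pos"].to_numpy() == sorted_df["pos"].to_numpy()).all():
        log.warning("call_dmrs: probes were not position-sorted; sorting internally")
    df = sorted_df

    cand = df[(df["p"] < p_threshold) & (df["effect"] != 0)]
    regions: list[Region] = []

    def flush(chunk: pd.DataFrame) -> None:
        if len(chunk) < min_cpgs:
            return
        if not (chunk["effect"].abs() > delta_threshold).any():
            return
        regions.append(
            Region(
                chrom=str(chunk["chrom"].iloc[0]),
                start=int(chunk["pos"].iloc[0]),
                end=int(chunk["pos"].iloc[-1]) + 1,
                probe_ids=list(chunk.index),
                effects=[float(e) for e in chunk["effect"]],
                p_values=[float(p) for p in chunk["p"]],
                region_p=_stouffer(chunk["p"].to_numpy()),
                max_abs_delta=float(chunk["effect"].abs().max()),
                direction="GAIN" if chunk["effect"].iloc[0] > 0 else "LOSS",
            )
        )

    for _, chrom_df in cand.groupby("chrom", sort=True):
        pos = chrom_df["pos"].to_numpy()
        sign = np.sign(chrom_df["effect"].to_numpy())
        start = 0
        for i in range(1, len(chrom_df) + 1):
            if (
                i == len(chrom_df)
                or pos[i] - pos[i - 1] > max_gap_bp
                or sign[i] != sign[i - 1]
            ):
                flush(chrom_df.iloc[start:i])
                start = i
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_cpgs": r.n_cpgs,
                "max_abs_delta": r.max_abs_delta,
                "region_p": r.region_p,
                "direction": r.direction,
                "probe_ids": ",".join(r.probe_ids),
            }
            for r in regions
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "n_cpgs",
            "max_abs_delta",
            "region_p",
            "direction",
            "probe_ids",
        ],
    )


def write_dmr_bed(regions: list[Region], path) -> None:
    """BED6+ output: name is a placeholder until annotation, score is
    round(1000 * max |delta-beta|) capped at 1000."""
    rows = []
    for r in regions:
        rows.append(
            (
                r.chrom,
                r.start,
                r.end,
                ";".join(r.probe_ids),
                min(1000, int(round(1000 * r.max_abs_delta))),
                ".",
                r.n_cpgs,
                f"{r.region_p:.6g}",
                r.direction,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def intersect_regions(
    regions: list[Region] | pd.DataFrame,
    intervals: pd.DataFrame,
) -> pd.DataFrame:
    """All (region, interval) pairs with >= 1 bp overlap.

    Both inputs are 0-based half-open; ``intervals`` needs columns
    ``chrom``, ``start``, ``end`` and optionally ``name``.  Overlap is
    ``min(ends) - max(starts)``.
    """
    if isinstance(regions, pd.DataFrame):
        reg_list = [
            (str(t.Index), str(t.chrom), int(t.start), int(t.end))
            for t in regions[["chrom", "start", "end"]].itertuples()
        ]
    else:
        reg_list = [
            (f"{r.chrom}:{r.start}-{r.end}", r.chrom, r.start, r.end) for r in regions
        ]
    for _, _, s, e in reg_list:
        if s >= e:
            raise ValueError("region with start >= end; check coordinate conventions")

    trees: dict[str, IntervalTree] = {}
    names = intervals["name"] if "name" in intervals else intervals.index.astype(str)
    for (chrom, s, e, name) in zip(
        intervals["chrom"], intervals["start"], intervals["end"], names
    ):
        if s >= e:
            raise ValueError("interval with start >= end; check coordinate conventions")
        trees.setdefault(str(chrom), IntervalTree()).addi(int(s), int(e), str(name))

    rows = []
    for rid, chrom, s, e in reg_list:
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(s, e)):
            overlap = min(e, hit.end) - max(s, hit.begin)
            if overlap >= 1:
                rows.append((rid, hit.data, overlap))
    return pd.DataFrame(rows, columns=["region", "interval", "overlap_bp"])
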