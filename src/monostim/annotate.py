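"""Nearest-gene assignment and promoter/distal classification.

Each probe (or region midpoint) is assigned to the gene whose TSS is
closest, provided the distance is within 1 Mb; equidistant TSSs resolve
to the lexicographically smallest gene_id.  Assigned probes are split
into PROMOTER (within 5 kb of the TSS) and DISTAL (beyond 5 kb) classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"
PROMOTER = "PROMOTER"
DISTAL = "DISTAL"


@dataclass
class TSSIndex:
    """Per-chromosome sorted arrays of (TSS position, gene_id, strand)."""

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def from_annotation(cls, gene_annot: pd.DataFrame) -> "TSSIndex":
        """Build from a gene table with columns chrom, tss, strand (indexed
        by gene_id)."""
        if gene_annot.index.duplicated().any():
            raise ValueError("one TSS per gene_id required")
        if (gene_annot["tss"] < 0).any():
            raise ValueError("TSS positions must be non-negative")
        by = {}
        for chrom, sub in gene_annot.groupby("chrom"):
            # sort by position, then gene_id so equal-position ties resolve
            # to the lexicographically smallest gene deterministically
            sub = sub.sort_values("tss", kind="mergesort")
            sub = sub.iloc[np.lexsort((sub.index.to_numpy(), sub["tss"].to_numpy()))]
            by[str(chrom)] = (
                sub["tss"].to_numpy(dtype=np.int64),
                sub.index.to_numpy(),
                sub["strand"].to_numpy(),
            )
        return cls(by)


def nearest_gene(
    chrom: str,
    pos: int,
    index: TSSIndex,
    max_distance_bp: int = 1_000_000,
) -> tuple[str, int] | None:
    """Nearest gene for one position, or None (unassigned).

    Returns ``(gene_id, signed_distance)``; the sign is genomic relative
    to the gene: positive when the position lies downstream of the TSS
    (right of it on '+' strand genes, left of it on '-' strand genes).
    """
    entry = index.by_chrom.get(str(chrom))
    if entry is None:
        return None
    tss, genes, strands = entry
    i = int(np.searchsorted(tss, pos))
    best = None  # (abs_distance, gene_id, tss, strand)
    for j in (i - 1, i):
        if 0 <= j < len(tss):
            cand = (abs(int(pos) - int(tss[j])), str(genes[j]), int(tss[j]), str(strands[j]))
            if best is None or cand[:2] < best[:2]:
                best = cand
    # equal-position duplicates: scan the tie neighborhood for smallest id
    if best is not None:
        d = best[0]
        lo = int(np.searchsorted(tss, pos - d, side="left"))
        hi = int(np.searchsorted(tss, pos + d, side="right"))
        for j in range(lo, hi):
            cand = (abs(int(pos) - int(tss[j])), str(genes[j]), int(tss[j]), str(strands[j]))
            if cand[:2] < best[:2]:
                best = cand
    if best is None or best[0] > max_distance_bp:
        return None
    _, gene, gtss, strand = best
    signed = int(pos) - gtss if strand == "+" else gtss - int(pos)
    return gene, signed


def annotate_probes(
    probe_annot: pd.DataFrame,
    index: TSSIndex,
    max_distance_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Nearest-gene table for every probe (columns gene_id, distance_bp);
    unassigned probes carry gene_id = UNASSIGNED."""
    rows = []
    for pid, row in probe_annot.iterrows():
        hit = nearest_gene(row["chrom"], int(row["pos"]), index, max_distance_bp)
        if hit is None:
            rows.append((pid, UNASSIGNED, np.nan))
        else:
            rows.append((pid, hit[0], hit[1]))
    out = pd.DataFrame(rows, columns=["probe_id", "gene_id", "distance_bp"])
    return out.set_index("probe_id")


def promoter_distal_split(
    assignments: pd.DataFrame,
    promoter_max_bp: int = 5000,
) -> pd.DataFrame:
    """Label assigned probes PROMOTER (|distance| <= promoter_max_bp) or
    DISTAL.  The exact boundary counts as PROMOTER.  Unassigned probes are
    excluded (count logged)."""
    assigned = assignments[assignments["gene_id"] != UNASSIGNED].copy()
    n_dropped = len(assignments) - len(assigned)
    if n_dropped:
        log.info("promoter_distal_split: excluding %d unassigned probes", n_dropped)
    dist = assigned["distance_bp"].abs()
    assigned["tss_class"] = np.where(dist <= promoter_max_bp, PROMOTER, DISTAL)
    return assigned
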