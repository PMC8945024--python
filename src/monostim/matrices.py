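"""In-memory containers for methylation and expression matrices.

Both containers pair a features x samples value matrix (pandas DataFrame)
with a per-feature annotation table, and round-trip losslessly through
plain TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_ANNOT_COLUMNS = [
    "probe_id",
    "chrom",
    "pos",
    "detection_p",
    "snp_at_cg",
    "cross_reactive",
]

GENE_ANNOT_COLUMNS = ["gene_id", "length_bp", "chrom", "tss", "strand"]


@dataclass
class BetaMatrix:
    """Methylation beta values (probes x samples) plus probe annotation.

    ``values`` is indexed by probe_id; ``annot`` is indexed by probe_id with
    columns chrom, pos (0-based), detection_p, snp_at_cg, cross_reactive.
    """

    values: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe_ids must be unique")
        if not self.values.index.equals(self.annot.index):
            self.annot = self.annot.loc[self.values.index]
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("beta matrix contains missing values")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def select_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[probe_ids], self.annot.loc[probe_ids])

    def write(self, values_path, annot_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="probe_id")
        out = self.annot.copy()
        out.insert(2, "end", out["pos"] + 1)  # BED-like half-open single-base interval
        cols = ["chrom", "pos", "end", "detection_p", "snp_at_cg", "cross_reactive"]
        out[cols].to_csv(annot_path, sep="\t", index_label="probe_id")

    @classmethod
    def read(cls, values_path, annot_path) -> "BetaMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
        annot = pd.read_csv(annot_path, sep="\t", index_col="probe_id")
        annot = annot.drop(columns=[c for c in ("end",) if c in annot.columns])
        annot["snp_at_cg"] = annot["snp_at_cg"].astype(bool)
        annot["cross_reactive"] = annot["cross_reactive"].astype(bool)
        return cls(values, annot)


@dataclass
class CountMatrix:
    """RNA-seq read counts (genes x samples) plus gene annotation.

    ``annot`` is indexed by gene_id with columns length_bp, chrom, tss
    (0-based transcription start position) and strand.
    """

    counts: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("gene_ids must be unique")
        if not self.counts.index.equals(self.annot.index):
            self.annot = self.annot.loc[self.counts.index]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.annot["length_bp"].to_numpy() <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def write(self, counts_path, annot_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.annot.to_csv(annot_path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, counts_path, annot_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        annot = pd.read_csv(annot_path, sep="\t", index_col="gene_id")
        return cls(counts, annot)


@dataclass
class RPKMMatrix:
    """Reads per kilobase per million mapped reads, with library sizes."""

    values: pd.DataFrame
    library_sizes: pd.Series = field(repr=False)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
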