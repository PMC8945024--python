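"""PWM motif scanning and hypergeometric enrichment with composite filters.

Motif scanning: log-odds scoring of every offset on both strands of each
sequence window; a sequence is a hit when its best score reaches the
motif's threshold (default 80% of the maximum attainable log-odds).

Enrichment: one-sided hypergeometric tail over target vs background hit
counts.  A motif passes the composite filter iff p < 0.05, fold change in
abundance > 1.5 (% targets with motif / % background with motif),
difference in abundance > 5 percentage points, at least two target
sequences contain the motif, and its transcription factor is expressed
(log2 mean RPKM >= 0 in at least one treatment group).  Term enrichment
applies the same test with a p < 0.05 / minimum-two-genes filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TF_NOT_EXPRESSED = "TF_NOT_EXPRESSED"


@dataclass
class PWM:
    """Position weight matrix with log-odds scoring.

    ``matrix`` is positions x 4 (A, C, G, T) base probabilities; rows must
    sum to 1.  ``threshold`` is an absolute log-odds score; when None it
    defaults to ``threshold_fraction`` of the maximum attainable score.
    """

    motif_id: str
    matrix: np.ndarray
    tf_gene_id: str | None = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 4:
            raise ValueError("PWM matrix must be L x 4 with L >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")
        if self.threshold is None:
            self.threshold = self.threshold_fraction * self.max_score

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 log2-odds table; the 5th column (N) scores 0."""
        with np.errstate(divide="ignore"):
            lo = np.log2(np.maximum(self.matrix, 1e-9) / self.background)
        return np.hstack([lo, np.zeros((self.length, 1))])

    @property
    def max_score(self) -> float:
        with np.errstate(divide="ignore"):
            lo = np.log2(np.maximum(self.matrix, 1e-9) / self.background)
        return float(lo.max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls, consensus: str, motif_id: str | None = None, match_p: float = 0.91, **kw
    ) -> "PWM":
        """Sharp PWM from a consensus string (match_p on the consensus base,
        the remainder split over the other three)."""
        consensus = consensus.upper()
        off = (1.0 - match_p) / 3.0
        m = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            m[i, _BASE_INDEX[b]] = match_p
        return cls(motif_id=motif_id or consensus, matrix=m, **kw)


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


def best_score(seq: str, pwm: PWM) -> float:
    """Best log-odds score over all offsets of both strands; -inf when the
    sequence is shorter than the motif."""
    L = pwm.length
    best = -np.inf
    lo = pwm.log_odds
    for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
        enc = _encode(s)
        n = len(enc) - L + 1
        if n < 1:
            continue
        # score every offset via a strided window lookup
        idx = np.lib.stride_tricks.sliding_window_view(enc, L)
        scores = lo[np.arange(L)[None, :], idx].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


def scan_pwm(seqs: dict[str, str], pwm: PWM) -> pd.DataFrame:
    """Per-sequence best score and hit flag for one motif."""
    rows = []
    for sid, seq in seqs.items():
        if len(seq) < pwm.length:
            log.info("scan_pwm: sequence %s shorter than motif %s", sid, pwm.motif_id)
            rows.append((sid, -np.inf, False))
            continue
        score = best_score(seq, pwm)
        rows.append((sid, score, score >= pwm.threshold))
    return pd.DataFrame(rows, columns=["sequence_id", "best_score", "hit"]).set_index(
        "sequence_id"
    )


def hypergeom_p(n_target_with: int, n_target: int, n_background_with: int, n_background: int) -> float:
    """One-sided hypergeometric tail: probability of >= n_target_with hits
    among n_target draws from the pooled target+background universe."""
    N = n_target + n_background
    K = n_target_with + n_background_with
    return float(stats.hypergeom.sf(n_target_with - 1, N, K, n_target))


def motif_enrichment(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    pwms: list[PWM],
    tf_expression: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    fold_min: float = 1.5,
    diff_min_pct: float = 5.0,
    min_targets: int = 2,
) -> pd.DataFrame:
    """Composite-filtered motif enrichment of target vs background windows.

    ``tf_expression`` is a genes x treatment-arms table of log2 mean RPKM;
    a motif whose TF is below 0 in every arm is excluded (reason
    TF_NOT_EXPRESSED) regardless of its p-value.
    """
    if not background_seqs:
        raise ValueError("empty background sequence set")
    rows = []
    for pwm in pwms:
        hits_t = scan_pwm(target_seqs, pwm)["hit"]
        hits_b = scan_pwm(background_seqs, pwm)["hit"]
        k_t, n_t = int(hits_t.sum()), len(hits_t)
        k_b, n_b = int(hits_b.sum()), len(hits_b)
        pct_t = 100.0 * k_t / n_t if n_t else 0.0
        pct_b = 100.0 * k_b / n_b if n_b else 0.0
        fold = pct_t / pct_b if pct_b > 0 else np.inf if pct_t > 0 else 0.0
        diff = pct_t - pct_b
        p = hypergeom_p(k_t, n_t, k_b, n_b)

        excluded_reason = ""
        if tf_expression is not None and pwm.tf_gene_id is not None:
            if pwm.tf_gene_id in tf_expression.index:
                if (tf_expression.loc[pwm.tf_gene_id] < 0).all():
                    excluded_reason = TF_NOT_EXPRESSED
        passes = (
            (p < p_threshold)
            and (fold > fold_min)
            and (diff > diff_min_pct)
            and (k_t >= min_targets)
            and not excluded_reason
        )
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "tf_gene_id": pwm.tf_gene_id,
                "n_target_with": k_t,
                "n_target": n_t,
                "n_background_with": k_b,
                "n_background": n_b,
                "pct_target": pct_t,
                "pct_background": pct_b,
                "fold": fold,
                "difference_pct": diff,
                "p": p,
                "passes_filter": passes,
                "excluded_reason": excluded_reason,
            }
        )
    return pd.DataFrame(rows).set_index("motif_id")


def term_enrichment(
    gene_set,
    universe,
    term_db: dict[str, list[str]],
    p_threshold: float = 0.05,
    min_genes: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene set against a term
    database; a term passes iff p < 0.05 and at least two set genes fall
    in it."""
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    for term, genes in term_db.items():
        term_genes = set(genes) & universe
        if not term_genes:
            log.info("term_enrichment: term %s has no universe genes; skipped", term)
            continue
        k = len(gene_set & term_genes)
        p = float(
            stats.hypergeom.sf(k - 1, len(universe), len(term_genes), len(gene_set))
        )
        rows.append(
            {
                "term_id": term,
                "n_overlap": k,
                "n_term": len(term_genes),
                "n_set": len(gene_set),
                "n_universe": len(universe),
                "p": p,
                "passes_filter": (p < p_threshold) and (k >= min_genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "n_overlap",
            "n_term",
            "n_set",
            "n_universe",
            "p",
            "passes_filter",
        ],
    ).set_index("term_id")


def tf_expression_table(rpkm, design) -> pd.DataFrame:
    """Genes x treatment-arms table of log2 mean RPKM (pseudocount 0.1),
    used for the TF-expression exclusion."""
    from .design import RNA

    rna = design.subset(RNA)
    cols = {}
    for (arm, tp), sub in rna.groupby(["treatment", "timepoint_h"]):
        samples = [s for s in sub["sample_id"] if s in rpkm.values.columns]
        cols[f"{arm}@{tp}h"] = np.log2(rpkm.values[samples].mean(axis=1) + 0.1)
    return pd.DataFrame(cols)


def read_pwms(path) -> list[PWM]:
    """HOMER-style motif text: '>consensus motif_id threshold' header, then
    one 'A C G T' probability row per position."""
    pwms = []
    header = None
    rows: list[list[float]] = []

    def flush():
        if header is None:
            return
        parts = header.split()
        motif_id = parts[1] if len(parts) > 1 else parts[0]
        threshold = float(parts[2]) if len(parts) > 2 else None
        tf = parts[3] if len(parts) > 3 else None
        pwms.append(
            PWM(motif_id=motif_id, matrix=np.array(rows), tf_gene_id=tf, threshold=threshold)
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def write_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            consensus = "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))
            tf = f" {pwm.tf_gene_id}" if pwm.tf_gene_id else ""
            fh.write(f">{consensus} {pwm.motif_id} {pwm.threshold:.6g}{tf}\n")
            for row in pwm.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT term database: term <tab> description <tab> gene1 <tab> ..."""
    db = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                db[parts[0]] = parts[2:]
    return db


def write_gmt(term_db: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in term_db.items():
            fh.write("\t".join([term, term] + list(genes)) + "\n")
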