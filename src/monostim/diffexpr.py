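"""Differential expression: RPKM, donor-blocked per-gene models, DEG
calling with an expression gate and a sign-agreement noise filter, and the
all-donor-concordant fold-change-of-means test.

A DEG must satisfy all of: |log2FC| > 0.58 (model scale, strict),
unadjusted p < 0.05, mean RPKM > 1 across the compared groups, and
agreement in sign between the model fold change and the fold change of
mean RPKM values.  The model here is a log-linear fit on
median-of-ratios-normalized counts with donor blocking; its outputs
(log2FC, p, RPKM) are exactly the quantities the downstream category
logic consumes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._linear import group_donor_fit, moderate
from .design import RNA, StudyDesign, comparison_id, comparison_samples
from .matrices import CountMatrix, RPKMMatrix

log = logging.getLogger(__name__)

#: pseudocount (RPKM units) guarding ratios of means against zero
RPKM_PSEUDOCOUNT = 0.1

MALE = "MALE"
FEMALE = "FEMALE"


def compute_rpkm(counts: CountMatrix) -> RPKMMatrix:
    """Reads per kilobase per million mapped reads, per sample."""
    libsize = counts.counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero) > 0:
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    length_kb = counts.annot["length_bp"].to_numpy() / 1000.0
    vals = counts.counts.div(libsize / 1e6, axis=1).div(length_kb, axis=0)
    return RPKMMatrix(vals, libsize)


def assign_sex_from_xist(
    rpkm: RPKMMatrix,
    design: StudyDesign,
    xist_gene_id: str = "XIST",
    threshold_rpkm: float = 1.0,
) -> dict[str, str]:
    """Label each donor FEMALE if its mean XIST RPKM strictly exceeds the
    threshold, else MALE."""
    if xist_gene_id not in rpkm.values.index:
        raise KeyError(f"gene {xist_gene_id!r} not present in RPKM matrix")
    xist = rpkm.values.loc[xist_gene_id]
    rna = design.subset(RNA)
    out = {}
    for donor, sub in rna.groupby("donor_id"):
        samples = [s for s in sub["sample_id"] if s in xist.index]
        mean = float(xist[samples].mean()) if samples else 0.0
        out[donor] = FEMALE if mean > threshold_rpkm else MALE
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, centered to geometric mean 1."""
    with np.errstate(divide="ignore"):
        logc = np.log(counts.to_numpy(dtype=float))
        ref = logc.mean(axis=1)  # log geometric mean per gene
    ok = np.isfinite(ref)
    if ok.sum() == 0:
        raise ValueError("no gene with all-positive counts; cannot compute size factors")
    ratios = logc[ok] - ref[ok, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns)


def fit_gene_models(
    counts: CountMatrix,
    design: StudyDesign,
    comparison: tuple[str, str, int],
    block_donor: bool = True,
    pseudocount: float = 0.5,
    moderate_variances: bool = False,
) -> pd.DataFrame:
    """Per-gene model for one comparison.

    Counts are normalized by median-of-ratios size factors; the response is
    ``log2(count / size_factor + pseudocount)``, fit against group + donor.
    ``effect`` is the group log2 fold change on the modeling scale.  Genes
    with zero counts in every sample of the comparison are excluded and
    flagged in ``attrs['excluded_all_zero']``.
    """
    target, reference, tp = comparison
    tgt_ids, ref_ids = comparison_samples(design, RNA, target, reference, tp)
    samples = tgt_ids + ref_ids
    sub = counts.counts[samples]

    all_zero = (sub.sum(axis=1) == 0)
    excluded = list(sub.index[all_zero])
    if excluded:
        log.info("fit_gene_models: excluding %d all-zero genes", len(excluded))
    sub = sub[~all_zero]

    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    y = np.log2(norm.to_numpy(dtype=float) + pseudocount)
    group = np.array([1.0] * len(tgt_ids) + [0.0] * len(ref_ids))
    donor_codes = pd.Categorical([design.donor_of(s) for s in samples]).codes.astype(int)
    fits = group_donor_fit(y, group, donor_codes, sub.index, block_donor=block_donor)
    if moderate_variances:
        fits = moderate(fits)

    # group mean RPKM on the full library (library size from all genes)
    rpkm = compute_rpkm(counts).values
    mean_t = rpkm.loc[sub.index, tgt_ids].mean(axis=1)
    mean_r = rpkm.loc[sub.index, ref_ids].mean(axis=1)
    fits = fits.rename(columns={"coef": "effect"})
    fits["mean_rpkm_target"] = mean_t.to_numpy()
    fits["mean_rpkm_reference"] = mean_r.to_numpy()
    fits["mean_rpkm"] = ((mean_t + mean_r) / 2.0).to_numpy()
    with np.errstate(divide="ignore"):
        fits["rpkm_log2fc"] = np.log2(
            (mean_t.to_numpy() + RPKM_PSEUDOCOUNT) / (mean_r.to_numpy() + RPKM_PSEUDOCOUNT)
        )
    fits.attrs["comparison_id"] = comparison_id(target, reference, tp)
    fits.attrs["excluded_all_zero"] = excluded
    return fits


def add_deg_gates(stats_df: pd.DataFrame, rpkm_min: float = 1.0) -> pd.DataFrame:
    """Attach the expression-level DEG gates as a boolean ``pass_gates``
    column: mean RPKM strictly above ``rpkm_min`` and sign agreement
    between the model fold change and the fold change of mean RPKM."""
    out = stats_df.copy()
    out["pass_gates"] = (out["mean_rpkm"] > rpkm_min) & (
        np.sign(out["effect"]) == np.sign(out["rpkm_log2fc"])
    )
    out.attrs.update(stats_df.attrs)
    return out


def call_degs(
    stats_df: pd.DataFrame,
    lfc_threshold: float = 0.58,
    p_threshold: float = 0.05,
    rpkm_min: float = 1.0,
) -> pd.DataFrame:
    """Differentially expressed genes.

    All criteria strict: |model log2FC| > ``lfc_threshold``; unadjusted
    p < ``p_threshold``; mean RPKM over the two compared groups >
    ``rpkm_min``; and the model fold change must agree in sign with the
    fold change of mean RPKM (the noise filter).  Labels UP / DOWN by the
    model log2FC sign.
    """
    eff = stats_df["effect"]
    keep = (
        (eff.abs() > lfc_threshold)
        & (stats_df["p"] < p_threshold)
        & (stats_df["mean_rpkm"] > rpkm_min)
        & (np.sign(eff) == np.sign(stats_df["rpkm_log2fc"]))
    )
    out = stats_df[keep].copy()
    out["direction"] = np.where(out["effect"] > 0, "UP", "DOWN")
    out.attrs.update(stats_df.attrs)
    return out


def fc_mean_test(
    rpkm: RPKMMatrix,
    design: StudyDesign,
    group_a: str,
    group_b: str,
    timepoint_h: int = 24,
    lfc_threshold: float = 0.58,
) -> pd.DataFrame:
    """Fold-change-of-means test with all-donor concordance.

    A gene passes iff |log2(mean_a / mean_b)| strictly exceeds the
    threshold (0.58, i.e. a linear fold change of ~1.5) AND every donor's
    individual a-vs-b ratio changes in the same direction.  Zero means are
    guarded with a 0.1 RPKM pseudocount.
    """
    a_ids, b_ids = comparison_samples(design, RNA, group_a, group_b, timepoint_h)
    va = rpkm.values[a_ids].to_numpy() + RPKM_PSEUDOCOUNT
    vb = rpkm.values[b_ids].to_numpy() + RPKM_PSEUDOCOUNT
    mean_lfc = np.log2(va.mean(axis=1) / vb.mean(axis=1))

    donors_a = [design.donor_of(s) for s in a_ids]
    donors_b = [design.donor_of(s) for s in b_ids]
    order = {d: i for i, d in enumerate(donors_a)}
    if set(donors_a) != set(donors_b):
        raise ValueError("fc_mean_test requires paired donors in both groups")
    vb_paired = vb[:, [donors_b.index(d) for d in sorted(order, key=order.get)]]
    donor_lfc = np.log2(va / vb_paired)
    signs = np.sign(donor_lfc)
    concordant = (np.abs(signs.sum(axis=1)) == signs.shape[1]) & (signs != 0).all(axis=1)

    passes = (np.abs(mean_lfc) > lfc_threshold) & concordant
    return pd.DataFrame(
        {
            "mean_log2fc": mean_lfc,
            "concordant": concordant,
            "passes": passes,
            "direction": np.where(mean_lfc > 0, "UP", "DOWN"),
        },
        index=rpkm.values.index,
    )


def write_stats(stats_df: pd.DataFrame, path) -> None:
    cols = [
        c
        for c in ("effect", "t", "p", "mean_rpkm", "rpkm_log2fc", "direction")
        if c in stats_df
    ]
    stats_df[cols].to_csv(path, sep="\t", index_label="gene_id")
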