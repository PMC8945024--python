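"""Differential methylation: probe filtering, per-probe moderated linear
models with donor blocking, and DMP calling.

The effect size reported per probe is the beta-scale group difference
(delta-beta), while hypothesis testing runs on M-values
(log2(beta / (1 - beta))), which are closer to homoskedastic.  A DMP is a
probe with |delta-beta| > 0.05 and unadjusted p < 0.05 (both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._linear import group_donor_fit, moderate
from .design import METH, StudyDesign, comparison_id, comparison_samples
from .matrices import BetaMatrix

log = logging.getLogger(__name__)

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}

#: default beta clipping before the logit transform
M_EPS = 1e-6


class FilterError(ValueError):
    pass


def filter_probes(
    beta: BetaMatrix,
    detection_p_max: float = 0.01,
    drop_sex_chromosomes: bool = True,
) -> tuple[BetaMatrix, dict[str, int]]:
    """Remove poor-quality and confounded probes.

    Drops probes with detection p above ``detection_p_max``, probes with a
    SNP at the interrogated CpG, cross-reactive probes, and (by default)
    probes on the sex chromosomes.  Order is preserved.  Returns the
    filtered matrix and a per-reason removal count.
    """
    a = beta.annot
    bad_det = a["detection_p"] > detection_p_max
    snp = a["snp_at_cg"].astype(bool)
    cross = a["cross_reactive"].astype(bool)
    sex = a["chrom"].isin(SEX_CHROMS) if drop_sex_chromosomes else pd.Series(False, index=a.index)
    keep = ~(bad_det | snp | cross | sex)
    counts = {
        "detection_p": int(bad_det.sum()),
        "snp_at_cg": int((snp & ~bad_det).sum()),
        "cross_reactive": int((cross & ~bad_det & ~snp).sum()),
        "sex_chromosome": int((sex & ~bad_det & ~snp & ~cross).sum()),
        "kept": int(keep.sum()),
    }
    if counts["kept"] == 0:
        raise FilterError("probe filtering removed every probe")
    for reason, n in counts.items():
        log.info("filter_probes: %s = %d", reason, n)
    return beta.select_probes(beta.probe_ids[keep]), counts


def beta_to_m(beta_values, eps: float = M_EPS):
    """M-value transform log2(b / (1 - b)), after clipping to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta_values, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta_values, pd.DataFrame):
        return pd.DataFrame(out, index=beta_values.index, columns=beta_values.columns)
    return out


def m_to_beta(m_values):
    m = np.asarray(m_values, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def fit_probe_models(
    beta: BetaMatrix,
    design: StudyDesign,
    comparison: tuple[str, str, int],
    block_donor: bool = True,
    on_m_values: bool = True,
) -> pd.DataFrame:
    """Per-probe linear model for one (target, reference, timepoint) comparison.

    Fits ``response ~ group + donor`` by least squares; the response is the
    M-value by default (``on_m_values=False`` fits on raw betas).  The
    reported ``effect`` is always the beta-scale delta-beta
    (mean target beta - mean reference beta).  P-values are unmoderated;
    apply :func:`moderate_variance` for the empirical-Bayes test.
    """
    target, reference, tp = comparison
    tgt_ids, ref_ids = comparison_samples(design, METH, target, reference, tp)
    samples = tgt_ids + ref_ids
    sub = beta.values[samples]
    group = np.array([1.0] * len(tgt_ids) + [0.0] * len(ref_ids))
    donor_codes = pd.Categorical(
        [design.donor_of(s) for s in samples]
    ).codes.astype(int)

    y = beta_to_m(sub).to_numpy() if on_m_values else sub.to_numpy()
    fits = group_donor_fit(y, group, donor_codes, beta.probe_ids, block_donor=block_donor)

    mean_t = sub[tgt_ids].mean(axis=1)
    mean_r = sub[ref_ids].mean(axis=1)
    fits.insert(0, "effect", (mean_t - mean_r).to_numpy())
    fits["mean_target"] = mean_t.to_numpy()
    fits["mean_reference"] = mean_r.to_numpy()
    fits.attrs["comparison_id"] = comparison_id(target, reference, tp)
    fits.attrs["scale"] = "M" if on_m_values else "beta"
    return fits


def moderate_variance(
    fits: pd.DataFrame,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes shrinkage of per-probe variances (limma-style).

    With ``prior_df=None`` the prior is moment-matched to the marginal
    distribution of the residual variances; ``prior_df=0`` disables
    shrinkage.
    """
    out = moderate(fits, prior_df=prior_df, prior_var=prior_var)
    out.attrs.update(fits.attrs)
    return out


def add_fdr(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg column, emitted for transparency only (DMP and
    category calls use unadjusted p-values throughout)."""
    out = stats_df.copy()
    out["fdr"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


def call_dmps(
    stats_df: pd.DataFrame,
    delta_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differentially methylated probes: |delta-beta| > threshold (strict)
    and unadjusted p < threshold (strict), labeled GAIN / LOSS."""
    if not (0 < delta_threshold < 1 and 0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    eff = stats_df["effect"]
    keep = (eff.abs() > delta_threshold) & (stats_df["p"] < p_threshold)
    out = stats_df[keep].copy()
    out["direction"] = np.where(out["effect"] > 0, "GAIN", "LOSS")
    out.attrs.update(stats_df.attrs)
    return out


def write_stats(stats_df: pd.DataFrame, path) -> None:
    cols = [c for c in ("effect", "t", "p", "fdr", "mean_target", "mean_reference", "direction") if c in stats_df]
    stats_df[cols].to_csv(path, sep="\t", index_label="probe_id")


def write_dmp_bed(dmps: pd.DataFrame, annot: pd.DataFrame, path) -> None:
    """BED6 of called DMPs (0-based half-open; score = 1000*|delta-beta|, capped)."""
    a = annot.loc[dmps.index]
    score = np.minimum(1000, (dmps["effect"].abs() * 1000).round().astype(int))
    bed = pd.DataFrame(
        {
            "chrom": a["chrom"].to_numpy(),
            "start": a["pos"].to_numpy(),
            "end": a["pos"].to_numpy() + 1,
            "name": dmps.index.to_numpy(),
            "score": score.to_numpy(),
            "strand": ".",
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
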