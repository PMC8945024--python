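"""End-to-end orchestration of the two experiments (differentiation +/- T3
and LPS +/- T3) on a synthetic study.

Stage order: simulate -> probe filter -> differential statistics ->
categories -> DMRs -> annotation -> enrichment -> report.  Every output
file name carries the configuration hash, and a machine-readable manifest
records per-stage counts (including the category counts in 'x/y (z%)'
form) so two runs with the same configuration can be compared byte for
byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annomod
from . import categories as catmod
from . import diffexpr, diffmeth, dmr, enrichment, report, synthetic
from .config import PipelineConfig, validate_config
from .design import (
    LPS,
    METH,
    RNA,
    RPMI,
    T3,
    T3_LPS,
    ZERO_H,
    comparison_id,
    write_sample_sheet,
)

log = logging.getLogger(__name__)

#: methylation comparison schedule (target, reference) at the late timepoint
METH_COMPARISONS = [
    (RPMI, ZERO_H),
    (T3, RPMI),
    (T3, ZERO_H),
    (LPS, RPMI),
    (LPS, ZERO_H),
    (T3_LPS, T3),
    (T3_LPS, RPMI),
    (T3_LPS, ZERO_H),
    (T3_LPS, LPS),
]

RNA_COMPARISONS = METH_COMPARISONS

#: consensus planted into synthetic probe windows for the motif stage
PLANTED_MOTIF = "GATTACAG"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _meth_comparison_table(beta, design, cfg) -> catmod.ComparisonTable:
    tables = {}
    for target, reference in METH_COMPARISONS:
        fits = diffmeth.fit_probe_models(beta, design, (target, reference, cfg.meth_timepoint))
        fits = diffmeth.moderate_variance(fits)
        fits = diffmeth.add_fdr(fits)
        tables[fits.attrs["comparison_id"]] = fits
    return catmod.ComparisonTable(tables)


def _rna_comparison_table(counts, design, cfg, timepoint: int) -> catmod.ComparisonTable:
    tables = {}
    for target, reference in RNA_COMPARISONS:
        fits = diffexpr.fit_gene_models(counts, design, (target, reference, timepoint))
        fits = diffexpr.add_deg_gates(fits, rpkm_min=cfg.rpkm_min)
        # genes excluded as all-zero in this comparison re-enter as nulls so
        # every comparison shares one feature universe
        attrs = dict(fits.attrs)
        fits = fits.reindex(counts.gene_ids)
        missing = fits["p"].isna()
        fits.loc[missing, ["effect", "p", "pass_gates"]] = [0.0, 1.0, False]
        fits["pass_gates"] = fits["pass_gates"].astype(bool)
        fits.attrs.update(attrs)
        tables[attrs["comparison_id"]] = fits
    return catmod.ComparisonTable(tables)


def _fc_mean_stats(rpkm, design, cfg, timepoint: int) -> pd.DataFrame:
    """fold-change-of-means test recast as an (effect, p) stats frame so
    the category engine can consume it: p is 0 for genes passing the
    all-donor concordance requirement and 1 otherwise."""
    fc = diffexpr.fc_mean_test(
        rpkm, design, T3_LPS, LPS, timepoint_h=timepoint, lfc_threshold=cfg.lfc_threshold
    )
    return pd.DataFrame(
        {
            "effect": fc["mean_log2fc"],
            "p": np.where(fc["concordant"], np.nextafter(0, 1), 1.0),
        },
        index=fc.index,
    )


def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = cfg.config_hash()

    def path(name: str) -> Path:
        return outdir / f"{tag}.{name}"

    manifest: dict = {"config_hash": tag, "config": cfg.to_dict(), "stages": {}}

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        study = synthetic.simulate_study(
            n_donors=cfg.n_donors,
            n_probes=cfg.n_probes,
            n_genes=cfg.n_genes,
            noise_sd=cfg.noise_sd,
            donor_sd=cfg.donor_sd,
            dispersion=cfg.dispersion,
            seed=cfg.seed,
            female=cfg.female,
        )
        write_sample_sheet(study.design, path("samples.csv"))
        study.beta.write(path("beta.tsv"), path("probes.tsv"))
        study.counts.write(path("counts.tsv"), path("genes.tsv"))
        study.truth.to_csv(path("truth.tsv"), sep="\t")
        manifest["stages"][stage] = {
            "n_probes": int(cfg.n_probes),
            "n_genes": int(cfg.n_genes),
            "n_meth_samples": len(study.beta.sample_ids),
            "n_rna_samples": len(study.counts.sample_ids),
            "n_planted": int(len(study.truth)),
        }

        # ---- probe filter -----------------------------------------------
        stage = "filter"
        beta, filter_counts = diffmeth.filter_probes(study.beta)
        manifest["stages"][stage] = filter_counts

        # ---- differential methylation -----------------------------------
        stage = "diffmeth"
        meth_table = _meth_comparison_table(beta, study.design, cfg)
        dmp_counts = {}
        for cid, fits in meth_table.items():
            diffmeth.write_stats(fits, path(f"meth_stats.{cid}.tsv"))
            dmps = diffmeth.call_dmps(fits, cfg.delta_threshold, cfg.p_threshold)
            diffmeth.write_dmp_bed(dmps, beta.annot, path(f"dmps.{cid}.bed"))
            dmp_counts[cid] = int(len(dmps))
        manifest["stages"][stage] = {"dmp_counts": dmp_counts}

        # ---- differential expression ------------------------------------
        stage = "diffexpr"
        rpkm = diffexpr.compute_rpkm(study.counts)
        rpkm.write(path("rpkm.tsv"))
        sex = diffexpr.assign_sex_from_xist(rpkm, study.design)
        rna_tables = {}
        deg_counts = {}
        for tp in sorted(set(cfg.timepoints) & {4, 24}):
            table = _rna_comparison_table(study.counts, study.design, cfg, tp)
            rna_tables[tp] = table
            for cid, fits in table.items():
                diffexpr.write_stats(fits, path(f"rna_stats.{cid}.tsv"))
                degs = diffexpr.call_degs(
                    fits, cfg.lfc_threshold, cfg.p_threshold, cfg.rpkm_min
                )
                deg_counts[cid] = int(len(degs))
        manifest["stages"][stage] = {"deg_counts": deg_counts, "donor_sex": sex}

        # ---- categories --------------------------------------------------
        stage = "categories"
        meth_cats = catmod.classify_all(
            meth_table,
            timepoint_h=cfg.meth_timepoint,
            delta_threshold=cfg.delta_threshold,
            p_threshold=cfg.p_threshold,
        )
        catmod.write_categories(meth_cats, path("categories.meth.tsv"))

        rna_cats_by_tp = {}
        tertiles = {}
        for tp, table in rna_tables.items():
            kw = dict(
                timepoint_h=tp,
                delta_threshold=cfg.lfc_threshold,
                p_threshold=cfg.p_threshold,
            )
            cats = {
                "DIFFERENTIATION": catmod.classify_induced(
                    table, catmod.STANDARD_ROUTES["DIFFERENTIATION"], **kw
                ),
                "T3_SPECIFIC": catmod.classify_induced(
                    table, catmod.STANDARD_ROUTES["T3_SPECIFIC"], **kw
                ),
                "LPS_INDUCED": catmod.classify_induced(
                    table, catmod.STANDARD_ROUTES["LPS_INDUCED"], **kw
                ),
            }
            cats["DIFF_ATTENUATED"] = catmod.classify_attenuated(
                cats["DIFFERENTIATION"],
                comparison_id(T3, RPMI, tp),
                table,
                delta_threshold=cfg.lfc_threshold,
                p_threshold=cfg.p_threshold,
            )
            # the modifier for LPS-induced genes is the concordant
            # fold-change-of-means comparison, not the count model
            fc_stats = _fc_mean_stats(rpkm, study.design, cfg, tp)
            fc_cid = f"fcmean.{comparison_id(T3_LPS, LPS, tp)}"
            aug = catmod.ComparisonTable({**table, fc_cid: fc_stats})
            cats["LPS_ATTENUATED"] = catmod.classify_attenuated(
                cats["LPS_INDUCED"],
                fc_cid,
                aug,
                delta_threshold=cfg.lfc_threshold,
                p_threshold=cfg.p_threshold,
            )
            rna_cats_by_tp[tp] = cats
            catmod.write_categories(cats, path(f"categories.rna.{tp}h.tsv"))

            lps_up = cats["LPS_INDUCED"]
            lps_up = lps_up[lps_up["direction"] == catmod.GAIN]
            if len(lps_up) >= 1:
                tert = catmod.tertile_partition(
                    lps_up.index, rpkm, study.design, timepoint_h=tp
                )
                tert.to_csv(path(f"tertiles.{tp}h.tsv"), sep="\t", index_label="gene_id")
                tertiles[tp] = {
                    lab: int((tert["tertile"] == lab).sum())
                    for lab in (catmod.ENHANCED, catmod.NO_EFFECT, catmod.ABROGATED)
                }

        manifest["stages"][stage] = {
            "meth": catmod.category_summary(meth_cats),
            "rna": {
                f"{tp}h": catmod.category_summary(cats)
                for tp, cats in rna_cats_by_tp.items()
            },
            "tertiles": {f"{tp}h": c for tp, c in tertiles.items()},
        }

        # ---- DMRs --------------------------------------------------------
        stage = "dmr"
        dmr_counts = {}
        probe_intervals = pd.DataFrame(
            {
                "chrom": beta.annot["chrom"],
                "start": beta.annot["pos"],
                "end": beta.annot["pos"] + 1,
                "name": beta.annot.index,
            }
        )
        for cid in (comparison_id(RPMI, ZERO_H, cfg.meth_timepoint),
                    comparison_id(T3, RPMI, cfg.meth_timepoint),
                    comparison_id(T3_LPS, LPS, cfg.meth_timepoint)):
            regions = dmr.call_dmrs(
                meth_table[cid],
                beta.annot,
                max_gap_bp=cfg.dmr_max_gap_bp,
                min_cpgs=cfg.dmr_min_cpgs,
                p_threshold=cfg.p_threshold,
                delta_threshold=cfg.delta_threshold,
            )
            dmr.write_dmr_bed(regions, path(f"dmrs.{cid}.bed"))
            hits = dmr.intersect_regions(regions, probe_intervals)
            hits.to_csv(path(f"dmr_probes.{cid}.tsv"), sep="\t", index=False)
            dmr_counts[cid] = len(regions)
        manifest["stages"][stage] = {"dmr_counts": dmr_counts}

        # ---- annotation --------------------------------------------------
        stage = "annotation"
        tss = annomod.TSSIndex.from_annotation(study.counts.annot)
        t3_dmps = meth_cats["T3_SPECIFIC"]
        assign = annomod.annotate_probes(
            beta.annot.loc[t3_dmps.index], tss, cfg.nearest_max_bp
        )
        split = annomod.promoter_distal_split(assign, cfg.promoter_max_bp)
        split.to_csv(path("t3_dmp_genes.tsv"), sep="\t", index_label="probe_id")
        manifest["stages"][stage] = {
            "t3_specific_assigned": int(len(split)),
            "promoter": int((split["tss_class"] == annomod.PROMOTER).sum()),
            "distal": int((split["tss_class"] == annomod.DISTAL).sum()),
        }

        # ---- enrichment --------------------------------------------------
        stage = "enrichment"
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0] % (2**31))
        target_ids = list(t3_dmps.index)
        bg_pool = [p for p in beta.probe_ids if p not in set(target_ids)]
        bg_ids = list(rng.choice(bg_pool, size=min(500, len(bg_pool)), replace=False))
        seqs, _ = synthetic.simulate_sequences(
            target_ids + bg_ids,
            window_bp=100,
            motif_consensus=PLANTED_MOTIF,
            target_ids=target_ids,
            target_fraction=0.6,
            background_fraction=0.1,
            seed=int(rng.integers(2**31)),
        )
        synthetic.write_fasta(seqs, path("dmp_windows.fasta"))
        pwms = [
            enrichment.PWM.from_consensus(PLANTED_MOTIF, "planted", tf_gene_id="G00001"),
            enrichment.PWM.from_consensus("CCGGAACC", "decoy1", tf_gene_id="G00002"),
            enrichment.PWM.from_consensus("TTAAGGCCA", "decoy2", tf_gene_id="G00003"),
        ]
        tf_expr = enrichment.tf_expression_table(rpkm, study.design)
        motifs = enrichment.motif_enrichment(
            {p: seqs[p] for p in target_ids},
            {p: seqs[p] for p in bg_ids},
            pwms,
            tf_expression=tf_expr,
            p_threshold=cfg.p_threshold,
            fold_min=cfg.motif_fold_min,
            diff_min_pct=cfg.motif_diff_min_pct,
            min_targets=cfg.motif_min_targets,
        )
        motifs.to_csv(path("motif_enrichment.tsv"), sep="\t")

        # generic term enrichment on the differentiation DEG set
        diff_degs = rna_cats_by_tp[max(rna_cats_by_tp)]["DIFFERENTIATION"].index
        universe = [g for g in study.counts.gene_ids]
        truth_diff = study.truth[
            (study.truth["assay"] == RNA)
            & (study.truth["effect_class"] == synthetic.DIFFERENTIATION)
        ].index.tolist()
        term_db = {"planted_differentiation": truth_diff}
        for i in range(5):
            term_db[f"random_term_{i}"] = list(
                rng.choice(universe, size=50, replace=False)
            )
        terms = enrichment.term_enrichment(list(diff_degs), universe, term_db)
        terms.to_csv(path("term_enrichment.tsv"), sep="\t")
        manifest["stages"][stage] = {
            "motifs_passing": int(motifs["passes_filter"].sum()),
            "terms_passing": int(terms["passes_filter"].sum()),
        }

        # ---- report ------------------------------------------------------
        stage = "report"
        diff_gain = meth_cats["DIFFERENTIATION"]
        diff_gain = diff_gain[diff_gain["direction"] == catmod.GAIN]
        traj = report.trajectory_summary(
            beta.values,
            study.design,
            diff_gain.index,
            METH,
            [(ZERO_H, 0), (RPMI, cfg.meth_timepoint), (T3, cfg.meth_timepoint)],
            mode="methylation",
        )
        traj.to_csv(path("trajectory.meth.tsv"), sep="\t", index=False)

        pca_info = {}
        if len(t3_dmps) >= 2:
            sel = beta.values.loc[t3_dmps.index]
            coords, evr = report.pca_project(sel)
            coords.to_csv(path("pca.t3_dmps.tsv"), sep="\t", index_label="sample_id")
            pca_info = {"n_features": int(len(sel)), "pc1_var": round(float(evr[0]), 4)}
            z, _ = report.zscore_matrix(sel)
            z.to_csv(path("heatmap.t3_dmps.tsv"), sep="\t", index_label="probe_id")
            if cfg.make_plots:
                _plot_pca(coords, study.design, path("pca.t3_dmps.png"))
        mod_stats = meth_table[comparison_id(T3, RPMI, cfg.meth_timepoint)]
        if len(meth_cats["DIFF_ATTENUATED"]):
            mod_stats = mod_stats.loc[meth_cats["DIFF_ATTENUATED"].index]
        top = report.rank_top_features(mod_stats, key="effect", n=10)
        top = top.join(
            annomod.annotate_probes(beta.annot.loc[top.index], tss, cfg.nearest_max_bp)
        )
        top.to_csv(path("top_attenuated_dmps.tsv"), sep="\t", index_label="probe_id")
        manifest["stages"][stage] = {"pca": pca_info, "n_top_ranked": int(len(top))}
    except Exception as exc:  # noqa: BLE001 - surface stage context
        raise StageError(stage, exc) from exc

    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plot_pca(coords: pd.DataFrame, design, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = design.samples.set_index("sample_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    for arm, sub in coords.groupby(meta.loc[coords.index, "treatment"]):
        ax.scatter(sub["PC1"], sub.get("PC2", 0), label=str(arm), s=25)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)
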