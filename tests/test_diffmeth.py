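import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from monostim import diffmeth
from monostim.design import METH, RPMI, T3, ZERO_H, build_design
from monostim.matrices import BetaMatrix
from monostim.synthetic import simulate_methylation


def make_beta(values: np.ndarray, sample_ids, chrom="chr1", detection_p=1e-4):
    n = values.shape[0]
    probes = pd.Index([f"cg{i:06d}" for i in range(n)], name="probe_id")
    annot = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n) * 1000,
            "detection_p": detection_p,
            "snp_at_cg": False,
            "cross_reactive": False,
        },
        index=probes,
    )
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=sample_ids), annot)


class TestFilterProbes:
    def build(self, **annot_overrides):
        beta = make_beta(np.full((4, 2), 0.5), ["s1", "s2"])
        for col, vals in annot_overrides.items():
            beta.annot[col] = vals
        return beta

    def test_high_detection_p_removed(self):
        beta = self.build(detection_p=[1e-4, 0.02, 1e-4, 1e-4])
        kept, counts = diffmeth.filter_probes(beta)
        assert len(kept.probe_ids) == 3 and counts["detection_p"] == 1
        assert "cg000001" not in kept.probe_ids

    def test_sex_chromosome_removed(self):
        beta = self.build(chrom=["chr1", "chrX", "chrY", "chr2"])
        kept, counts = diffmeth.filter_probes(beta)
        assert counts["sex_chromosome"] == 2 and len(kept.probe_ids) == 2

    def test_sex_chromosomes_kept_when_disabled(self):
        beta = self.build(chrom=["chr1", "chrX", "chrY", "chr2"])
        kept, _ = diffmeth.filter_probes(beta, drop_sex_chromosomes=False)
        assert len(kept.probe_ids) == 4

    def test_flagged_probes_removed(self):
        beta = self.build(snp_at_cg=[True, False, False, False],
                          cross_reactive=[False, True, False, False])
        kept, counts = diffmeth.filter_probes(beta)
        assert counts["snp_at_cg"] == 1 and counts["cross_reactive"] == 1
        assert len(kept.probe_ids) == 2

    def test_clean_matrix_unchanged(self):
        beta = self.build()
        kept, counts = diffmeth.filter_probes(beta)
        assert kept.values.equals(beta.values) and counts["kept"] == 4

    def test_everything_removed_raises(self):
        beta = self.build(detection_p=[0.5] * 4)
        with pytest.raises(diffmeth.FilterError):
            diffmeth.filter_probes(beta)


class TestMValues:
    def test_symmetry_point(self):
        assert diffmeth.beta_to_m(0.5) == pytest.approx(0.0)

    def test_log2_of_four(self):
        assert diffmeth.beta_to_m(0.8) == pytest.approx(2.0)

    def test_roundtrip_inverse(self, rng):
        b = rng.uniform(0.001, 0.999, size=1000)
        back = diffmeth.m_to_beta(diffmeth.beta_to_m(b))
        assert np.abs(back - b).max() < 1e-12

    def test_monotone(self, rng):
        b = np.sort(rng.uniform(0.01, 0.99, 100))
        assert (np.diff(diffmeth.beta_to_m(b)) > 0).all()


class TestProbeModels:
    def test_identical_groups_null(self):
        design = build_design(3, {0, 24})
        meth = design.subset(METH)
        # target betas equal reference betas within each donor
        per_donor = {"D1": 0.2, "D2": 0.4, "D3": 0.6}
        vals = np.array([[per_donor[d] for d in meth["donor_id"]]])
        beta = make_beta(vals, meth["sample_id"].tolist())
        fits = diffmeth.fit_probe_models(beta, design, (RPMI, ZERO_H, 24))
        assert fits["t"].iloc[0] == 0.0
        assert fits["p"].iloc[0] == 1.0
        assert fits["effect"].iloc[0] == pytest.approx(0.0)

    def test_paired_design_closed_form(self):
        # per-donor values ref {0.1, 0.2, 0.3}, target {0.2, 0.3, 0.4}:
        # the blocked group estimate is exactly +0.1 on the raw scale
        design = build_design(3, {0, 24})
        meth = design.subset(METH)
        base = {"D1": 0.1, "D2": 0.2, "D3": 0.3}
        vals = []
        for row in meth.itertuples(index=False):
            v = base[row.donor_id] + (0.1 if row.treatment == RPMI else 0.0)
            vals.append(v)
        beta = make_beta(np.array([vals]), meth["sample_id"].tolist())
        fits = diffmeth.fit_probe_models(
            beta, design, (RPMI, ZERO_H, 24), on_m_values=False
        )
        # independent closed-form check via direct least squares
        sub = meth[meth["treatment"].isin([RPMI, ZERO_H])]
        yy = np.array([base[r.donor_id] + (0.1 if r.treatment == RPMI else 0.0)
                       for r in sub.itertuples(index=False)])
        X = np.column_stack([
            np.ones(len(sub)),
            (sub["treatment"] == RPMI).to_numpy(float),
            (sub["donor_id"] == "D2").to_numpy(float),
            (sub["donor_id"] == "D3").to_numpy(float),
        ])
        expected = np.linalg.lstsq(X, yy, rcond=None)[0][1]
        assert fits["coef"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert fits["coef"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_matches_bruteforce_ols(self, rng):
        # oracle equivalence on 100 random probes, per-probe lstsq refit
        design = build_design(3, {0, 24})
        beta, _ = simulate_methylation(design, 100, [], seed=42)
        fits = diffmeth.fit_probe_models(beta, design, (T3, RPMI, 24))
        meth = design.subset(METH)
        sub = meth[(meth["treatment"].isin([T3, RPMI])) & (meth["timepoint_h"] == 24)]
        order = [*sub[sub["treatment"] == T3]["sample_id"], *sub[sub["treatment"] == RPMI]["sample_id"]]
        g = np.array([1.0] * 3 + [0.0] * 3)
        donors = np.array([s.split("_")[0] for s in order])
        X = np.column_stack([np.ones(6), g] + [(donors == d).astype(float) for d in ["D2", "D3"]])
        M = diffmeth.beta_to_m(beta.values[order]).to_numpy()
        for i in range(100):
            coef, rss, *_ = np.linalg.lstsq(X, M[i], rcond=None)
            resid = M[i] - X @ coef
            s2 = resid @ resid / (6 - 4)
            se = np.sqrt(s2 * np.linalg.pinv(X.T @ X)[1, 1])
            t = coef[1] / se
            p = 2 * scipy_stats.t.sf(abs(t), 2)
            assert fits["coef"].iloc[i] == pytest.approx(coef[1], abs=1e-8)
            assert fits["p"].iloc[i] == pytest.approx(p, abs=1e-8)

    def test_single_donor_rejected(self):
        design = build_design(1, {0, 24})
        meth = design.subset(METH)
        beta = make_beta(np.full((3, len(meth)), 0.5), meth["sample_id"].tolist())
        with pytest.raises(Exception, match="rank|donor"):
            diffmeth.fit_probe_models(beta, design, (RPMI, ZERO_H, 24))

    def test_null_pvalues_uniform(self):
        design = build_design(3, {0, 24})
        beta, _ = simulate_methylation(design, 10_000, [], seed=99)
        fits = diffmeth.fit_probe_models(beta, design, (RPMI, ZERO_H, 24))
        ks = scipy_stats.kstest(fits["p"], "uniform")
        assert ks.pvalue > 0.01


class TestModeration:
    @pytest.fixture()
    def fits(self):
        design = build_design(3, {0, 24})
        beta, _ = simulate_methylation(design, 2000, [], seed=17)
        return diffmeth.fit_probe_models(beta, design, (RPMI, ZERO_H, 24))

    def test_zero_prior_df_is_identity(self, fits):
        mod = diffmeth.moderate_variance(fits, prior_df=0)
        assert np.allclose(mod["t"], fits["t"])
        assert np.allclose(mod["p"], fits["p"])

    def test_identical_variances_are_fixed_point(self, fits):
        f = fits.copy()
        f["s2"] = 0.04
        for d0 in (1.0, 10.0, 1000.0):
            mod = diffmeth.moderate_variance(f, prior_df=d0, prior_var=0.04)
            assert np.allclose(mod["s2_post"], 0.04)

    def test_infinite_prior_df_limit(self, fits):
        mod = diffmeth.moderate_variance(fits, prior_df=1e9, prior_var=0.02)
        assert np.abs(mod["s2_post"] - 0.02).max() < 1e-6

    def test_estimated_prior_recovers_simulated_heterogeneity(self):
        # probe variances were drawn from a scaled inverse-chi-square with
        # 20 prior df; the moment-matched estimate should land near it
        design = build_design(3, {0, 24})
        beta, _ = simulate_methylation(design, 20_000, [], seed=31)
        fits = diffmeth.fit_probe_models(beta, design, (RPMI, ZERO_H, 24))
        mod = diffmeth.moderate_variance(fits)
        assert 5 < mod.attrs["prior_df"] < 100
        assert mod.attrs["prior_var"] == pytest.approx(0.01, rel=0.5)


class TestCallDmps:
    def make_stats(self, effect, p):
        return pd.DataFrame({"effect": [effect], "p": [p]}, index=["cg1"])

    @pytest.mark.parametrize(
        "effect,p,called,direction",
        [
            (0.051, 0.04, True, "GAIN"),
            (0.05, 0.01, False, None),  # strict delta threshold
            (0.20, 0.20, False, None),  # p fails
            (-0.06, 0.04, True, "LOSS"),
            (0.06, 0.05, False, None),  # strict p threshold
        ],
    )
    def test_threshold_semantics(self, effect, p, called, direction):
        dmps = diffmeth.call_dmps(self.make_stats(effect, p))
        assert (len(dmps) == 1) is called
        if called:
            assert dmps["direction"].iloc[0] == direction

    def test_sign_consistency(self):
        design = build_design(3, {0, 24})
        beta, _ = simulate_methylation(design, 3000, [], seed=55)
        fits = diffmeth.fit_probe_models(beta, design, (RPMI, ZERO_H, 24))
        dmps = diffmeth.call_dmps(diffmeth.moderate_variance(fits))
        signs = np.sign(dmps["mean_target"] - dmps["mean_reference"])
        assert (np.sign(dmps["effect"]) == signs).all()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.call_dmps(self.make_stats(0.1, 0.01), delta_threshold=0.0)
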