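import json

import numpy as np
import pandas as pd
import pytest

from monostim import categories as cat
from monostim.design import LPS, RPMI, T3, T3_LPS, ZERO_H, comparison_id
from monostim.matrices import RPKMMatrix

TP = 24
CIDS = [
    comparison_id(t, r, TP)
    for t, r in [
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
]


def random_table(n_features, rng, p_max=0.15):
    feats = pd.Index([f"f{i:04d}" for i in range(n_features)])
    tables = {}
    for cid in CIDS:
        tables[cid] = pd.DataFrame(
            {
                "effect": rng.uniform(-0.15, 0.15, n_features),
                "p": rng.uniform(0.0, p_max, n_features),
            },
            index=feats,
        )
    return cat.ComparisonTable(tables)


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain per-feature evaluation of the
# logical category definitions
# ---------------------------------------------------------------------------

def oracle_sign(table, cid, fid, d_thr, p_thr):
    row = table[cid].loc[fid]
    if abs(row["effect"]) > d_thr and row["p"] < p_thr:
        return 1 if row["effect"] > 0 else -1
    return 0


def oracle_classify(table, d_thr=0.05, p_thr=0.05):
    routes = {
        "DIFFERENTIATION": [(RPMI, [ZERO_H])],
        "T3_SPECIFIC": [(T3, [RPMI, ZERO_H])],
        "LPS_INDUCED": [(LPS, [RPMI, ZERO_H]), (T3_LPS, [T3, ZERO_H])],
        "T3LPS_SPECIFIC": [(T3_LPS, [T3, RPMI, ZERO_H])],
    }
    out = {}
    for name, rts in routes.items():
        members = {}
        for fid in table.universe:
            fired = []
            for target, refs in rts:
                signs = {
                    oracle_sign(table, comparison_id(target, r, TP), fid, d_thr, p_thr)
                    for r in refs
                }
                if len(signs) == 1 and 0 not in signs:
                    fired.append(signs.pop())
            if fired:
                # union semantics; direction from the first firing route
                members[fid] = fired[0]
        out[name] = members

    def attenuate(base, modifier_cid):
        return {
            fid: s
            for fid, s in base.items()
            if oracle_sign(table, modifier_cid, fid, d_thr, p_thr) == -s
        }

    def unique(base, versus_cid):
        return {
            fid: s
            for fid, s in base.items()
            if oracle_sign(table, versus_cid, fid, d_thr, p_thr) == s
        }

    out["DIFF_ATTENUATED"] = attenuate(out["DIFFERENTIATION"], comparison_id(T3, RPMI, TP))
    out["LPS_ATTENUATED"] = attenuate(out["LPS_INDUCED"], comparison_id(T3_LPS, LPS, TP))
    out["T3LPS_UNIQUE"] = unique(out["T3LPS_SPECIFIC"], comparison_id(T3_LPS, LPS, TP))
    return out


class TestExamples:
    def build(self, effects_p):
        """single-feature table from {cid: (effect, p)}; others null"""
        feats = pd.Index(["f0"])
        tables = {}
        for cid in CIDS:
            e, p = effects_p.get(cid, (0.0, 1.0))
            tables[cid] = pd.DataFrame({"effect": [e], "p": [p]}, index=feats)
        return cat.ComparisonTable(tables)

    def test_t3_specific_both_references(self):
        t = self.build({
            comparison_id(T3, RPMI, TP): (0.08, 0.01),
            comparison_id(T3, ZERO_H, TP): (0.07, 0.02),
        })
        res = cat.classify_induced(t, cat.STANDARD_ROUTES["T3_SPECIFIC"])
        assert list(res.index) == ["f0"] and res["direction"].iloc[0] == "GAIN"
        prov = json.loads(res["provenance"].iloc[0])
        assert set(prov) == {comparison_id(T3, RPMI, TP), comparison_id(T3, ZERO_H, TP)}

    def test_sign_conflict_excluded(self):
        t = self.build({
            comparison_id(T3, RPMI, TP): (0.08, 0.01),
            comparison_id(T3, ZERO_H, TP): (-0.06, 0.02),
        })
        res = cat.classify_induced(t, cat.STANDARD_ROUTES["T3_SPECIFIC"])
        assert res.empty

    def test_one_reference_failing_excluded(self):
        t = self.build({
            comparison_id(T3, RPMI, TP): (0.08, 0.01),
            comparison_id(T3, ZERO_H, TP): (0.07, 0.20),  # p fails
        })
        assert cat.classify_induced(t, cat.STANDARD_ROUTES["T3_SPECIFIC"]).empty

    def test_attenuated_opposite_sign(self):
        t = self.build({
            comparison_id(RPMI, ZERO_H, TP): (0.12, 0.01),
            comparison_id(T3, RPMI, TP): (-0.06, 0.03),
        })
        base = cat.classify_induced(t, cat.STANDARD_ROUTES["DIFFERENTIATION"])
        att = cat.classify_attenuated(base, comparison_id(T3, RPMI, TP), t)
        assert list(att.index) == ["f0"]

    def test_same_sign_modifier_not_attenuated(self):
        t = self.build({
            comparison_id(RPMI, ZERO_H, TP): (0.12, 0.01),
            comparison_id(T3, RPMI, TP): (0.06, 0.03),  # further gain
        })
        base = cat.classify_induced(t, cat.STANDARD_ROUTES["DIFFERENTIATION"])
        assert cat.classify_attenuated(base, comparison_id(T3, RPMI, TP), t).empty

    def test_small_modifier_magnitude_not_attenuated(self):
        t = self.build({
            comparison_id(RPMI, ZERO_H, TP): (0.12, 0.01),
            comparison_id(T3, RPMI, TP): (-0.04, 0.01),  # below 0.05
        })
        base = cat.classify_induced(t, cat.STANDARD_ROUTES["DIFFERENTIATION"])
        assert cat.classify_attenuated(base, comparison_id(T3, RPMI, TP), t).empty

    def test_unique_requires_fourth_comparison(self):
        common = {
            comparison_id(T3_LPS, T3, TP): (0.08, 0.01),
            comparison_id(T3_LPS, RPMI, TP): (0.09, 0.01),
            comparison_id(T3_LPS, ZERO_H, TP): (0.07, 0.01),
        }
        passing = self.build({**common, comparison_id(T3_LPS, LPS, TP): (0.07, 0.02)})
        failing = self.build({**common, comparison_id(T3_LPS, LPS, TP): (0.02, 0.02)})
        for t, expect in ((passing, 1), (failing, 0)):
            spec = cat.classify_induced(t, cat.STANDARD_ROUTES["T3LPS_SPECIFIC"])
            assert len(spec) == 1
            uniq = cat.classify_unique(spec, comparison_id(T3_LPS, LPS, TP), t)
            assert len(uniq) == expect

    def test_missing_comparison_named(self):
        t = self.build({})
        del t[comparison_id(T3, ZERO_H, TP)]
        with pytest.raises(KeyError, match="T3_vs_0h@24h"):
            cat.classify_induced(t, cat.STANDARD_ROUTES["T3_SPECIFIC"])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_categories_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(400, rng)
        got = cat.classify_all(table)
        expected = oracle_classify(table)
        for name, members in expected.items():
            assert set(got[name].index) == set(members), name
            for fid, sign in members.items():
                assert got[name].at[fid, "direction"] == ("GAIN" if sign > 0 else "LOSS")

    def test_subset_and_fraction_audit(self):
        rng = np.random.default_rng(7)
        table = random_table(600, rng)
        got = cat.classify_all(table)
        assert set(got["DIFF_ATTENUATED"].index) <= set(got["DIFFERENTIATION"].index)
        assert set(got["LPS_ATTENUATED"].index) <= set(got["LPS_INDUCED"].index)
        assert set(got["T3LPS_UNIQUE"].index) <= set(got["T3LPS_SPECIFIC"].index)
        summary = cat.category_summary(got)
        x, rest = summary["DIFF_ATTENUATED"].split("/")
        y = rest.split(" ")[0]
        z = float(rest.split("(")[1].rstrip("%)"))
        assert z == pytest.approx(100 * int(x) / int(y), abs=0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        table = random_table(200, rng)
        shuffled = cat.ComparisonTable(
            {cid: df.sample(frac=1.0, random_state=3) for cid, df in table.items()}
        )
        a = cat.classify_all(table)
        b = cat.classify_all(shuffled)
        for name in a:
            assert set(a[name].index) == set(b[name].index)

    def test_loosening_p_never_shrinks(self):
        rng = np.random.default_rng(13)
        table = random_table(500, rng, p_max=0.3)
        strict = cat.classify_induced(table, cat.STANDARD_ROUTES["LPS_INDUCED"], p_threshold=0.05)
        loose = cat.classify_induced(table, cat.STANDARD_ROUTES["LPS_INDUCED"], p_threshold=0.15)
        assert set(strict.index) <= set(loose.index)


class TestTertiles:
    def make_rpkm(self, design, ratios):
        """genes with T3+LPS/LPS mean-RPKM ratio as given (after the 0.1
        pseudocount)."""
        rna = design.subset(RNA := "RNA")
        rows = {}
        for gid, r in ratios.items():
            vals = []
            for s in rna.itertuples(index=False):
                if s.treatment == T3_LPS and s.timepoint_h == 24:
                    vals.append(r * 1.1 - 0.1)
                elif s.treatment == LPS and s.timepoint_h == 24:
                    vals.append(1.0)
                else:
                    vals.append(1.0)
            rows[gid] = vals
        df = pd.DataFrame.from_dict(rows, orient="index", columns=rna["sample_id"].tolist())
        return RPKMMatrix(df, pd.Series(1e6, index=df.columns))

    def test_exact_division(self, design3):
        ratios = {f"g{i}": float(10 - i) for i in range(1, 10)}  # 9..1
        rpkm = self.make_rpkm(design3, ratios)
        t = cat.tertile_partition(list(ratios), rpkm, design3)
        assert t["tertile"].value_counts().to_dict() == {
            "ENHANCED": 3, "NO_EFFECT": 3, "ABROGATED": 3,
        }
        assert t.loc["g1", "tertile"] == "ENHANCED"  # ratio 9
        assert t.loc["g9", "tertile"] == "ABROGATED"  # ratio 1

    def test_remainder_rule_143_genes(self, design3):
        ratios = {f"g{i:03d}": 1.0 + i / 100 for i in range(143)}
        rpkm = self.make_rpkm(design3, ratios)
        t = cat.tertile_partition(list(ratios), rpkm, design3)
        sizes = t["tertile"].value_counts()
        assert sizes["ENHANCED"] == 48 and sizes["NO_EFFECT"] == 48 and sizes["ABROGATED"] == 47

    def test_ties_resolve_by_gene_id(self, design3):
        ratios = {g: 2.0 for g in ["b", "a", "c", "e", "d", "f"]}
        rpkm = self.make_rpkm(design3, ratios)
        t = cat.tertile_partition(list(ratios), rpkm, design3)
        assert list(t.index) == ["a", "b", "c", "d", "e", "f"]
        assert list(t["tertile"]) == ["ENHANCED"] * 2 + ["NO_EFFECT"] * 2 + ["ABROGATED"] * 2

    def test_tiny_set_falls_back(self, design3):
        rpkm = self.make_rpkm(design3, {"a": 2.0, "b": 0.5})
        t = cat.tertile_partition(["a", "b"], rpkm, design3)
        assert (t["tertile"] == "NO_EFFECT").all()


@pytest.mark.parametrize(
    "x,y,expected",
    [
        (315, 11927, "315/11927 (2.6%)"),
        (312, 7210, "312/7210 (4.3%)"),
        (136, 575, "136/575 (23.7%)"),
        (0, 10, "0/10 (0.0%)"),
    ],
)
def test_format_fraction(x, y, expected):
    assert cat.format_fraction(x, y) == expected
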