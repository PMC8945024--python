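"""Multi-arm category engine.

Classifies features (probes or genes) by set logic over per-comparison
statistics:

* induced  -- changed versus EVERY reference arm of a route, with one
  shared sign (e.g. T3-specific = T3 vs RPMI and T3 vs 0 h);
* attenuated -- an induced feature whose modifier comparison (T3 vs RPMI,
  or T3+LPS vs LPS) is significant with the OPPOSITE sign, i.e. the
  modifier pulls the change back toward baseline (0 h < RPMI > T3
  patterns);
* unique -- a co-stimulation-specific feature that additionally differs
  from the single-stimulus arm with the same sign;
* tertile partition -- ranking of an induced gene set by the modifier
  ratio of mean expression, split into three near-equal classes.

All thresholds are strict inequalities, matching the DMP/DEG definitions.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .design import LPS, RPMI, T3, T3_LPS, ZERO_H, comparison_id
from .matrices import RPKMMatrix

log = logging.getLogger(__name__)

GAIN = "GAIN"
LOSS = "LOSS"

ENHANCED = "ENHANCED"
NO_EFFECT = "NO_EFFECT"
ABROGATED = "ABROGATED"

#: Standard induced-category routes: category -> list of
#: (target_arm, reference_arms) routes, any of which may fire.
STANDARD_ROUTES = {
    "DIFFERENTIATION": [(RPMI, [ZERO_H])],
    "T3_SPECIFIC": [(T3, [RPMI, ZERO_H])],
    "LPS_INDUCED": [(LPS, [RPMI, ZERO_H]), (T3_LPS, [T3, ZERO_H])],
    "T3LPS_SPECIFIC": [(T3_LPS, [T3, RPMI, ZERO_H])],
}


class ComparisonTable(dict):
    """comparison_id -> per-feature stats DataFrame (columns effect, p).

    All member tables must share one feature universe.
    """

    def __init__(self, tables: dict[str, pd.DataFrame]):
        super().__init__(tables)
        universe = None
        for cid, df in tables.items():
            idx = df.index
            if universe is None:
                universe = idx
            elif not universe.equals(idx):
                raise ValueError(f"comparison {cid!r} has a different feature universe")
        self.universe = universe if universe is not None else pd.Index([])

    def stats(self, cid: str) -> pd.DataFrame:
        if cid not in self:
            raise KeyError(f"missing comparison {cid!r} in ComparisonTable")
        return self[cid]


def _pass_sign(
    df: pd.DataFrame, delta_threshold: float, p_threshold: float
) -> pd.Series:
    """Signed pass indicator per feature: +1 / -1 if the comparison passes
    both strict thresholds, else 0.

    If the stats table carries a boolean ``pass_gates`` column (e.g. the
    expression-level RPKM and sign-agreement gates), it is ANDed in.
    """
    sig = (df["effect"].abs() > delta_threshold) & (df["p"] < p_threshold)
    if "pass_gates" in df.columns:
        sig &= df["pass_gates"].astype(bool)
    return pd.Series(np.where(sig, np.sign(df["effect"]), 0.0), index=df.index)


def classify_induced(
    table: ComparisonTable,
    routes: list[tuple[str, list[str]]],
    timepoint_h: int = 24,
    delta_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Features passing thresholds against every reference of some route,
    with one shared effect sign.

    ``routes`` is a list of ``(target_arm, [reference_arms])``; a feature
    is induced if at least one route fires in full (union semantics, so
    loosening a threshold can only grow the set).  The direction comes
    from the first firing route in the declared route order; every firing
    route's comparisons enter the provenance.  Returns a DataFrame indexed
    by feature with columns ``direction`` and ``provenance`` (JSON:
    comparison -> [effect, p]).
    """
    route_signs = []
    route_cids = []
    for target, refs in routes:
        cids = [comparison_id(target, r, timepoint_h) for r in refs]
        route_cids.append(cids)
        signs = [_pass_sign(table.stats(c), delta_threshold, p_threshold) for c in cids]
        s = signs[0].copy()
        for other in signs[1:]:
            s = s.where(s == other, 0.0)  # all refs must agree, incl. both nonzero
        route_signs.append(s)

    fired = pd.concat(route_signs, axis=1)
    keep = (fired != 0).any(axis=1)

    rows = {}
    for fid in table.universe[keep]:
        sign = 0.0
        prov = {}
        for cids, s in zip(route_cids, route_signs):
            if s[fid] != 0:
                if sign == 0.0:
                    sign = s[fid]
                for c in cids:
                    st = table.stats(c)
                    prov[c] = [float(st.at[fid, "effect"]), float(st.at[fid, "p"])]
        rows[fid] = {
            "direction": GAIN if sign > 0 else LOSS,
            "provenance": json.dumps(prov, sort_keys=True),
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["direction", "provenance"])
    out.index.name = "feature_id"
    return out.loc[[f for f in table.universe if f in out.index]]


def classify_attenuated(
    base: pd.DataFrame,
    modifier: str,
    table: ComparisonTable,
    delta_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Subset of an induced set whose modifier comparison is significant
    with the OPPOSITE sign (the modifier pulls the change back)."""
    if base.empty:
        return base.copy()
    mod = table.stats(modifier)
    sign = _pass_sign(mod, delta_threshold, p_threshold)
    base_sign = base["direction"].map({GAIN: 1.0, LOSS: -1.0})
    keep = [fid for fid in base.index if sign[fid] == -base_sign[fid]]
    out = base.loc[keep].copy()
    prov = []
    for fid in out.index:
        p = json.loads(out.at[fid, "provenance"])
        p[modifier] = [float(mod.at[fid, "effect"]), float(mod.at[fid, "p"])]
        prov.append(json.dumps(p, sort_keys=True))
    out["provenance"] = prov
    return out


def classify_unique(
    specific: pd.DataFrame,
    versus: str,
    table: ComparisonTable,
    delta_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Subset of a co-stimulation-specific set that also differs from the
    single-stimulus arm with the SAME sign."""
    if specific.empty:
        return specific.copy()
    ver = table.stats(versus)
    sign = _pass_sign(ver, delta_threshold, p_threshold)
    spec_sign = specific["direction"].map({GAIN: 1.0, LOSS: -1.0})
    keep = [fid for fid in specific.index if sign[fid] == spec_sign[fid]]
    out = specific.loc[keep].copy()
    prov = []
    for fid in out.index:
        p = json.loads(out.at[fid, "provenance"])
        p[versus] = [float(ver.at[fid, "effect"]), float(ver.at[fid, "p"])]
        prov.append(json.dumps(p, sort_keys=True))
    out["provenance"] = prov
    return out


def classify_all(
    table: ComparisonTable,
    timepoint_h: int = 24,
    delta_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """All seven category sets from one comparison table.

    Categories: DIFFERENTIATION, DIFF_ATTENUATED, T3_SPECIFIC,
    LPS_INDUCED, LPS_ATTENUATED, T3LPS_SPECIFIC, T3LPS_UNIQUE.
    """
    kw = dict(
        timepoint_h=timepoint_h, delta_threshold=delta_threshold, p_threshold=p_threshold
    )
    thr = dict(delta_threshold=delta_threshold, p_threshold=p_threshold)
    out = {}
    out["DIFFERENTIATION"] = classify_induced(table, STANDARD_ROUTES["DIFFERENTIATION"], **kw)
    out["DIFF_ATTENUATED"] = classify_attenuated(
        out["DIFFERENTIATION"], comparison_id(T3, RPMI, timepoint_h), table, **thr
    )
    out["T3_SPECIFIC"] = classify_induced(table, STANDARD_ROUTES["T3_SPECIFIC"], **kw)
    out["LPS_INDUCED"] = classify_induced(table, STANDARD_ROUTES["LPS_INDUCED"], **kw)
    out["LPS_ATTENUATED"] = classify_attenuated(
        out["LPS_INDUCED"], comparison_id(T3_LPS, LPS, timepoint_h), table, **thr
    )
    out["T3LPS_SPECIFIC"] = classify_induced(table, STANDARD_ROUTES["T3LPS_SPECIFIC"], **kw)
    out["T3LPS_UNIQUE"] = classify_unique(
        out["T3LPS_SPECIFIC"], comparison_id(T3_LPS, LPS, timepoint_h), table, **thr
    )
    return out


def tertile_partition(
    gene_ids,
    rpkm: RPKMMatrix,
    design,
    numerator_arm: str = T3_LPS,
    denominator_arm: str = LPS,
    timepoint_h: int = 24,
) -> pd.DataFrame:
    """Rank genes by the modifier effect on their mean expression
    (numerator arm / denominator arm) and split into three near-equal
    classes: top third ENHANCED, middle NO_EFFECT, bottom ABROGATED.

    Sizes differ by at most one, extras going to the top classes first;
    ties in the ratio are broken by gene_id (ascending).
    """
    from .design import RNA, comparison_samples

    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("tertile_partition requires a non-empty gene set")
    num_ids, den_ids = comparison_samples(design, RNA, numerator_arm, denominator_arm, timepoint_h)
    num = rpkm.values.loc[gene_ids, num_ids].mean(axis=1) + 0.1
    den = rpkm.values.loc[gene_ids, den_ids].mean(axis=1) + 0.1
    ratio = (num / den).rename("ratio")
    order = ratio.to_frame().assign(gene_id=ratio.index)
    order = order.sort_values(["ratio", "gene_id"], ascending=[False, True])

    n = len(order)
    if n < 3:
        log.warning("tertile_partition: fewer than 3 genes; single-class fallback")
        order["tertile"] = NO_EFFECT
        return order[["ratio", "tertile"]]
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = [ENHANCED] * sizes[0] + [NO_EFFECT] * sizes[1] + [ABROGATED] * sizes[2]
    order["tertile"] = labels
    return order[["ratio", "tertile"]]


def format_fraction(x: int, y: int) -> str:
    """Counts in 'x/y (z%)' form; one decimal place, round-half-even."""
    pct = round(100.0 * x / y, 1) if y else 0.0
    return f"{x}/{y} ({pct}%)"


def category_summary(categories: dict[str, pd.DataFrame]) -> dict[str, str]:
    """Per-category counts, with attenuated/unique reported as fractions of
    their parent sets."""
    parents = {
        "DIFF_ATTENUATED": "DIFFERENTIATION",
        "LPS_ATTENUATED": "LPS_INDUCED",
        "T3LPS_UNIQUE": "T3LPS_SPECIFIC",
    }
    out = {}
    for name, df in categories.items():
        if name in parents:
            out[name] = format_fraction(len(df), len(categories[parents[name]]))
        else:
            out[name] = str(len(df))
    return out


def write_categories(categories: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for name, df in categories.items():
        if df.empty:
            continue
        f = df.copy()
        f.insert(0, "category", name)
        frames.append(f)
    if frames:
        allf = pd.concat(frames)
    else:
        allf = pd.DataFrame(columns=["category", "direction", "provenance"])
    allf.to_csv(path, sep="\t", index_label="feature_id")
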