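"""Synthetic study generator with planted, recoverable effects.

Emulates the structure of a monocyte stimulation study (EPIC-style beta
matrix at 0/24 h, RNA-seq counts at 0/4/24 h, 3 donors, 4 treatment arms)
so the whole analysis stack can be exercised and validated without any
external data.  Every non-null feature is recorded in a ground-truth table.

Methylation model
-----------------
Beta values are generated on the logit (M-value) scale:

    m = logit2(baseline + arm_offset) + donor_intercept + noise

and inverse-transformed, which keeps values strictly inside (0, 1) while
making the planted beta-scale group difference equal to the requested
magnitude in expectation.  Donor intercepts are shared across arms within
a donor, inducing the within-donor correlation that donor blocking is
meant to absorb.  Per-probe noise SDs are drawn from a scaled
inverse-chi-square distribution so that probe variances are heterogeneous,
as on real arrays.

Expression model
----------------
Counts are negative-binomial with donor-specific library size factors and
planted log2 group offsets.  An XIST gene is always present: near-zero
mean for male donors (the default), high for female, so XIST-based sex
assignment can be tested.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    ARMS,
    LPS,
    METH,
    RNA,
    RPMI,
    T3,
    T3_LPS,
    ZERO_H,
    StudyDesign,
)

# Planted effect classes.  Each mirrors one category the downstream
# classification engine is supposed to recover.
NULL = "NULL"
DIFFERENTIATION = "DIFFERENTIATION"
DIFF_ATTENUATED_BY_T3 = "DIFF_ATTENUATED_BY_T3"
T3_SPECIFIC = "T3_SPECIFIC"
LPS_INDUCED = "LPS_INDUCED"
LPS_ATTENUATED_BY_T3LPS = "LPS_ATTENUATED_BY_T3LPS"
T3LPS_UNIQUE = "T3LPS_UNIQUE"

EFFECT_CLASSES = (
    NULL,
    DIFFERENTIATION,
    DIFF_ATTENUATED_BY_T3,
    T3_SPECIFIC,
    LPS_INDUCED,
    LPS_ATTENUATED_BY_T3LPS,
    T3LPS_UNIQUE,
)

GAIN = "GAIN"
LOSS = "LOSS"

_ATTENUATED = {DIFF_ATTENUATED_BY_T3, LPS_ATTENUATED_BY_T3LPS}

#: Synthetic autosomes used for probe and gene coordinates.
AUTOSOMES = ("chr1", "chr2", "chr3", "chr4", "chr5", "chr6")
CHROM_LENGTH = 50_000_000


class EffectError(ValueError):
    """Raised when a planted effect cannot be realised."""


@dataclass(frozen=True)
class PlantedEffect:
    """One planted effect.

    magnitude is in beta units (methylation) or log2 fold-change units
    (expression).  For the attenuated classes, ``atten_magnitude`` is the
    amount by which the modifier arm (T3, or T3+LPS) pulls the base effect
    back toward baseline; the net offset in that arm is
    ``magnitude - atten_magnitude``.
    """

    effect_class: str
    direction: str = GAIN
    magnitude: float = 0.0
    atten_magnitude: float = 0.0
    assay: str = METH
    timepoints: tuple[int, ...] = (24,)
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise EffectError(f"unknown effect class {self.effect_class!r}")
        if self.direction not in (GAIN, LOSS):
            raise EffectError(f"direction must be GAIN or LOSS, got {self.direction!r}")
        if self.effect_class == NULL:
            if self.magnitude != 0:
                raise EffectError("NULL effects must have magnitude 0")
        elif self.magnitude <= 0:
            raise EffectError("planted magnitude must be > 0")
        if self.effect_class in _ATTENUATED and self.atten_magnitude <= 0:
            raise EffectError("attenuated classes require atten_magnitude > 0")

    @property
    def sign(self) -> int:
        return 1 if self.direction == GAIN else -1

    def arm_offsets(self) -> dict[str, float]:
        """Signed per-arm offsets (relative to the 0 h baseline)."""
        s, m, a = self.sign, self.magnitude, self.atten_magnitude
        if self.effect_class == NULL:
            return {}
        if self.effect_class == DIFFERENTIATION:
            return {arm: s * m for arm in ARMS}
        if self.effect_class == DIFF_ATTENUATED_BY_T3:
            return {RPMI: s * m, LPS: s * m, T3: s * (m - a), T3_LPS: s * (m - a)}
        if self.effect_class == T3_SPECIFIC:
            return {T3: s * m}
        if self.effect_class == LPS_INDUCED:
            return {LPS: s * m, T3_LPS: s * m}
        if self.effect_class == LPS_ATTENUATED_BY_T3LPS:
            return {LPS: s * m, T3_LPS: s * (m - a)}
        if self.effect_class == T3LPS_UNIQUE:
            return {T3_LPS: s * m}
        raise AssertionError(self.effect_class)


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulated study produced."""

    design: StudyDesign
    beta: "object"  # BetaMatrix
    counts: "object"  # CountMatrix
    truth: pd.DataFrame
    seed: int


def _logit2(b: np.ndarray) -> np.ndarray:
    return np.log2(b / (1.0 - b))


def _inv_logit2(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp2(-m))


def truth_table(effects: list[PlantedEffect]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": e.feature_id,
            "assay": e.assay,
            "effect_class": e.effect_class,
            "direction": e.direction,
            "magnitude": e.magnitude,
            "atten_magnitude": e.atten_magnitude,
            "timepoints": ",".join(str(t) for t in e.timepoints),
        }
        for e in effects
        if e.effect_class != NULL
    ]
    cols = [
        "feature_id",
        "assay",
        "effect_class",
        "direction",
        "magnitude",
        "atten_magnitude",
        "timepoints",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("feature_id")


def simulate_methylation(
    design: StudyDesign,
    n_probes: int,
    effects: list[PlantedEffect] | None = None,
    noise_sd: float = 0.10,
    donor_sd: float = 0.15,
    seed: int = 0,
    variance_prior_df: float = 20.0,
    frac_bad_detection: float = 0.01,
    frac_snp: float = 0.01,
    frac_cross_reactive: float = 0.01,
    frac_sex_chrom: float = 0.02,
):
    """Simulate a beta matrix plus probe annotation and a truth table.

    Planted effects are assigned to distinct clean autosomal probes (so
    quality filtering never removes a planted feature); all remaining
    probes are null.  Returns ``(BetaMatrix, truth)``.
    """
    from .matrices import BetaMatrix  # local import to avoid cycles

    effects = list(effects or [])
    meth_effects = [e for e in effects if e.assay == METH and e.effect_class != NULL]
    if n_probes < len(meth_effects):
        raise EffectError("n_probes smaller than the number of planted effects")
    if noise_sd <= 0 or donor_sd < 0:
        raise EffectError("noise_sd must be > 0 and donor_sd >= 0")

    rng = np.random.default_rng(seed)
    probe_ids = np.array([f"cg{i:08d}" for i in range(1, n_probes + 1)])

    # Annotation: flagged / sex-chromosome probes are drawn from the tail
    # of the probe list so the head stays clean for planting.
    n_flag = int(round(n_probes * (frac_bad_detection + frac_snp + frac_cross_reactive + frac_sex_chrom)))
    if n_probes - n_flag < len(meth_effects):
        raise EffectError("too few clean probes for the requested planted effects")
    # Probe coordinates cluster like CpG islands: runs of closely spaced
    # probes (50-800 bp apart) separated by larger jumps, laid out in
    # chromosome blocks so consecutive probe indices are genomic neighbours.
    chrom = np.empty(n_probes, dtype=object)
    pos = np.empty(n_probes, dtype=np.int64)
    per_chrom = -(-n_probes // len(AUTOSOMES))
    i = 0
    for chrom_name in AUTOSOMES:
        cur = int(rng.integers(10_000, 100_000))
        for _ in range(min(per_chrom, n_probes - i)):
            chrom[i] = chrom_name
            pos[i] = cur
            if rng.random() < 0.75:
                cur += int(rng.integers(50, 800))
            else:
                cur += int(rng.integers(5_000, 50_000))
            i += 1
        if i >= n_probes:
            break
    detection_p = np.full(n_probes, 1e-4)
    snp = np.zeros(n_probes, dtype=bool)
    cross = np.zeros(n_probes, dtype=bool)
    tail = np.arange(n_probes - n_flag, n_probes)
    rng.shuffle(tail)
    k = 0
    for frac, action in (
        (frac_bad_detection, "det"),
        (frac_snp, "snp"),
        (frac_cross_reactive, "cross"),
        (frac_sex_chrom, "sex"),
    ):
        n_here = int(round(n_probes * frac))
        idx = tail[k : k + n_here]
        k += n_here
        if action == "det":
            detection_p[idx] = 0.02
        elif action == "snp":
            snp[idx] = True
        elif action == "cross":
            cross[idx] = True
        else:
            chrom[idx] = rng.choice(["chrX", "chrY"], size=len(idx))

    # Per-arm beta offsets for planted probes.
    offsets = np.zeros((n_probes, len(ARMS)), dtype=float)  # columns follow ARMS order
    arm_col = {arm: j for j, arm in enumerate(ARMS)}
    planted: list[PlantedEffect] = []
    for i, eff in enumerate(meth_effects):
        eff = dataclasses.replace(eff, feature_id=probe_ids[i])
        planted.append(eff)
        for arm, off in eff.arm_offsets().items():
            offsets[i, arm_col[arm]] = off

    # Baselines: nulls uniform in (0.1, 0.9); planted probes drawn so every
    # arm-level expected beta stays inside (0.05, 0.95).
    baseline = rng.uniform(0.1, 0.9, size=n_probes)
    for i in range(len(planted)):
        lo_off = min(0.0, offsets[i].min())
        hi_off = max(0.0, offsets[i].max())
        lo = max(0.05, 0.05 - lo_off)
        hi = min(0.95, 0.95 - hi_off)
        if lo >= hi:
            raise EffectError(
                f"effect on {planted[i].feature_id} pushes expected beta outside (0.01, 0.99)"
            )
        baseline[i] = rng.uniform(lo, hi)

    probe_sd = noise_sd * np.sqrt(
        variance_prior_df / rng.chisquare(variance_prior_df, size=n_probes)
    )

    meth = design.subset(METH)
    donors = sorted(meth["donor_id"].unique())
    donor_idx = {d: j for j, d in enumerate(donors)}
    donor_effects = rng.normal(0.0, donor_sd, size=(n_probes, len(donors)))

    # Timepoint-resolved arm offsets (planted effects fire only at their
    # stated timepoints; methylation is measured at 24 h).
    tp_mask = {}
    for eff in planted:
        tp_mask[eff.feature_id] = set(eff.timepoints)

    values = np.empty((n_probes, len(meth)), dtype=float)
    for j, row in enumerate(meth.itertuples(index=False)):
        off = np.zeros(n_probes)
        if row.treatment != ZERO_H:
            col = arm_col[row.treatment]
            off = offsets[:, col].copy()
            for i, eff in enumerate(planted):
                if row.timepoint_h not in tp_mask[eff.feature_id]:
                    off[i] = 0.0
        m = (
            _logit2(baseline + off)
            + donor_effects[:, donor_idx[row.donor_id]]
            + rng.normal(0.0, 1.0, size=n_probes) * probe_sd
        )
        values[:, j] = _inv_logit2(m)

    values = np.clip(values, 1e-6, 1.0 - 1e-6)
    vdf = pd.DataFrame(values, index=probe_ids, columns=meth["sample_id"].tolist())
    annot = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "detection_p": detection_p,
            "snp_at_cg": snp,
            "cross_reactive": cross,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return BetaMatrix(vdf, annot), truth_table(planted)


def simulate_expression(
    design: StudyDesign,
    n_genes: int,
    effects: list[PlantedEffect] | None = None,
    dispersion: float = 0.02,
    seed: int = 0,
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 1.0,
    donor_libsize_sd: float = 0.15,
    female: bool = False,
):
    """Simulate an RNA count matrix plus gene annotation and a truth table.

    Counts are negative-binomial (gamma-Poisson) around
    ``baseline * libsize_factor * 2**offset``.  Returns
    ``(CountMatrix, truth)``.
    """
    from .matrices import CountMatrix

    if dispersion <= 0:
        raise EffectError("dispersion must be > 0")
    effects = list(effects or [])
    rna_effects = [e for e in effects if e.assay == RNA and e.effect_class != NULL]
    if n_genes < len(rna_effects):
        raise EffectError("n_genes smaller than the number of planted effects")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(1, n_genes + 1)] + ["XIST"]
    n_total = n_genes + 1

    base_mean = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_total))
    base_mean[-1] = 500.0 if female else 0.05  # XIST sex signal

    lengths = rng.integers(500, 5001, size=n_total)
    chrom = rng.choice(AUTOSOMES, size=n_total)
    tss = rng.integers(0, CHROM_LENGTH, size=n_total)
    strand = rng.choice(["+", "-"], size=n_total)

    arm_col = {arm: j for j, arm in enumerate(ARMS)}
    offsets = np.zeros((n_total, len(ARMS)))
    planted: list[PlantedEffect] = []
    for i, eff in enumerate(rna_effects):
        eff = dataclasses.replace(eff, feature_id=gene_ids[i])
        planted.append(eff)
        for arm, off in eff.arm_offsets().items():
            offsets[i, arm_col[arm]] = off

    rna = design.subset(RNA)
    donors = sorted(rna["donor_id"].unique())
    donor_factor = {d: float(np.exp(rng.normal(0.0, donor_libsize_sd))) for d in donors}

    counts = np.empty((n_total, len(rna)), dtype=np.int64)
    shape = 1.0 / dispersion
    for j, row in enumerate(rna.itertuples(index=False)):
        off = np.zeros(n_total)
        if row.treatment != ZERO_H:
            off = offsets[:, arm_col[row.treatment]].copy()
            for i, eff in enumerate(planted):
                if row.timepoint_h not in eff.timepoints:
                    off[i] = 0.0
        libfac = donor_factor[row.donor_id] * float(
            np.exp(rng.normal(0.0, donor_libsize_sd / 3.0))
        )
        mu = base_mean * libfac * np.exp2(off)
        lam = rng.gamma(shape, mu / shape)
        counts[:, j] = rng.poisson(lam)

    cdf = pd.DataFrame(counts, index=gene_ids, columns=rna["sample_id"].tolist())
    annot = pd.DataFrame(
        {"length_bp": lengths, "chrom": chrom, "tss": tss, "strand": strand},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return CountMatrix(cdf, annot), truth_table(planted)


def simulate_sequences(
    probe_ids,
    window_bp: int = 100,
    motif_consensus: str = "GATTACAG",
    target_ids=(),
    target_fraction: float = 1.0,
    background_fraction: float = 0.0,
    seed: int = 0,
):
    """Random sequence windows around probes, with a motif planted.

    Each probe receives a random sequence of length ``2 * window_bp + 1``
    (the probe site plus +/- window_bp of flank).  The consensus string is
    embedded at a random offset in a Bernoulli(fraction) subset of target
    and background probes.  Returns ``(dict probe_id -> sequence,
    set of probe_ids that received the motif)``.
    """
    motif_consensus = motif_consensus.upper()
    if not (0 <= target_fraction <= 1 and 0 <= background_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if window_bp <= len(motif_consensus):
        raise ValueError("window_bp must exceed the motif length")
    rng = np.random.default_rng(seed)
    length = 2 * window_bp + 1
    bases = np.array(list("ACGT"))
    target_ids = set(target_ids)
    seqs: dict[str, str] = {}
    embedded: set[str] = set()
    for pid in probe_ids:
        seq = rng.choice(bases, size=length)
        frac = target_fraction if pid in target_ids else background_fraction
        if rng.random() < frac:
            start = int(rng.integers(0, length - len(motif_consensus) + 1))
            seq[start : start + len(motif_consensus)] = list(motif_consensus)
            embedded.add(pid)
        seqs[str(pid)] = "".join(seq)
    return seqs, embedded


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=pid, description="") for pid, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq).upper() for rec in parse(str(path), "fasta")}


def _panel(spec_rows, assay, timepoints, scale=1.0) -> list[PlantedEffect]:
    out = []
    for effect_class, n, magnitude, atten in spec_rows:
        n = max(1, round(n * scale))
        # directions are contiguous (all gains, then all losses) so that
        # planted neighbours share a sign and can support region calling
        for i in range(n):
            out.append(
                PlantedEffect(
                    effect_class=effect_class,
                    direction=GAIN if i < (n + 1) // 2 else LOSS,
                    magnitude=magnitude,
                    atten_magnitude=atten,
                    assay=assay,
                    timepoints=timepoints,
                )
            )
    return out


def default_methylation_panel(
    magnitude: float = 0.15, atten_magnitude: float = 0.10, scale: float = 1.0
) -> list[PlantedEffect]:
    """Standard planted panel for the methylation arm of a synthetic study.

    ``scale`` shrinks the per-class counts proportionally for small
    studies (the stated counts assume the 20,000-probe default).
    """
    rows = [
        (DIFFERENTIATION, 300, magnitude, 0.0),
        (DIFF_ATTENUATED_BY_T3, 100, magnitude, atten_magnitude),
        (T3_SPECIFIC, 100, magnitude, 0.0),
        (LPS_INDUCED, 150, magnitude, 0.0),
        (LPS_ATTENUATED_BY_T3LPS, 50, magnitude, atten_magnitude),
        (T3LPS_UNIQUE, 50, magnitude, 0.0),
    ]
    return _panel(rows, METH, (24,), scale=scale)


def default_expression_panel(
    log2fc: float = 1.5, atten_log2fc: float = 1.0, scale: float = 1.0
) -> list[PlantedEffect]:
    """Standard planted panel for the expression arm of a synthetic study.

    ``scale`` shrinks the per-class counts proportionally for small
    studies (the stated counts assume the 5,000-gene default).
    """
    rows = [
        (DIFFERENTIATION, 150, log2fc, 0.0),
        (DIFF_ATTENUATED_BY_T3, 40, log2fc, atten_log2fc),
        (T3_SPECIFIC, 40, log2fc, 0.0),
        (LPS_INDUCED, 80, log2fc, 0.0),
        (LPS_ATTENUATED_BY_T3LPS, 25, log2fc, atten_log2fc),
        (T3LPS_UNIQUE, 25, log2fc, 0.0),
    ]
    return _panel(rows, RNA, (4, 24), scale=scale)


def simulate_study(
    n_donors: int = 3,
    n_probes: int = 20_000,
    n_genes: int = 5_000,
    meth_effects: list[PlantedEffect] | None = None,
    rna_effects: list[PlantedEffect] | None = None,
    noise_sd: float = 0.10,
    donor_sd: float = 0.15,
    dispersion: float = 0.02,
    seed: int = 0,
    female: bool = False,
) -> SyntheticStudy:
    """One-call generator for a full synthetic study (both assays)."""
    from .design import build_design

    design = build_design(n_donors=n_donors, timepoints={0, 4, 24})
    if meth_effects is None:
        meth_effects = default_methylation_panel(scale=min(1.0, n_probes / 20_000))
    if rna_effects is None:
        rna_effects = default_expression_panel(scale=min(1.0, n_genes / 5_000))
    # Independent child seeds keep the two assays decoupled but reproducible.
    ss = np.random.SeedSequence(seed)
    meth_seed, rna_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    beta, meth_truth = simulate_methylation(
        design, n_probes, meth_effects, noise_sd=noise_sd, donor_sd=donor_sd, seed=meth_seed
    )
    counts, rna_truth = simulate_expression(
        design, n_genes, rna_effects, dispersion=dispersion, seed=rna_seed, female=female
    )
    truth = pd.concat([meth_truth, rna_truth])
    return SyntheticStudy(design=design, beta=beta, counts=counts, truth=truth, seed=seed)
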