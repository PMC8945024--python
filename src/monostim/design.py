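"""Study design: donors x treatment arms x timepoints x assays.

The experimental layout is an in vitro monocyte stimulation time course:
monocytes are collected at attachment (the 0 h control) and then cultured
in medium alone (RPMI), with triiodothyronine (T3), with lipopolysaccharide
(LPS), or with both (T3+LPS).  RNA is profiled at 0, 4 and 24 h; DNA
methylation at 0 and 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

ZERO_H = "0h"
RPMI = "RPMI"
T3 = "T3"
LPS = "LPS"
T3_LPS = "T3+LPS"

#: Treatment arms applied after attachment (everything except the 0 h control).
ARMS = (RPMI, T3, LPS, T3_LPS)
TREATMENTS = (ZERO_H,) + ARMS

METH = "METH"
RNA = "RNA"
ASSAYS = (METH, RNA)

#: Timepoints (hours) at which each assay is collected.
ASSAY_TIMEPOINTS = {METH: frozenset({0, 24}), RNA: frozenset({0, 4, 24})}

SAMPLE_COLUMNS = ["sample_id", "donor_id", "treatment", "timepoint_h", "assay"]


class DesignError(ValueError):
    """Raised for invalid study-design requests."""


@dataclass(frozen=True)
class StudyDesign:
    """Immutable table of samples (one row per sample)."""

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_ids in design")

    @property
    def donors(self) -> list[str]:
        return sorted(self.samples["donor_id"].unique())

    @property
    def n_donors(self) -> int:
        return self.samples["donor_id"].nunique()

    def subset(self, assay: str) -> pd.DataFrame:
        return self.samples[self.samples["assay"] == assay].reset_index(drop=True)

    def arm_samples(self, assay: str, treatment: str, timepoint_h: int) -> list[str]:
        """Sample ids for one (assay, arm, timepoint) cell, donor-sorted."""
        s = self.samples
        sel = s[
            (s["assay"] == assay)
            & (s["treatment"] == treatment)
            & (s["timepoint_h"] == timepoint_h)
        ].sort_values("donor_id")
        return sel["sample_id"].tolist()

    def donor_of(self, sample_id: str) -> str:
        row = self.samples[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["donor_id"].iloc[0]


def sample_name(donor_id: str, treatment: str, timepoint_h: int, assay: str) -> str:
    return f"{donor_id}_{treatment}_{timepoint_h}h_{assay}"


def build_design(n_donors: int = 3, timepoints: set[int] = frozenset({0, 4, 24})) -> StudyDesign:
    """Full crossing of donors x arms x timepoints for both assays.

    The 0 h control exists only at timepoint 0 (one untreated sample per
    donor per assay); the four treatment arms exist at every non-zero
    timepoint the assay covers.

    Parameters
    ----------
    n_donors:
        Number of donors (>= 1).
    timepoints:
        Timepoints in hours; a subset of {0, 4, 24}.
    """
    if n_donors < 1:
        raise DesignError("n_donors must be >= 1")
    timepoints = set(timepoints)
    if not timepoints:
        raise DesignError("invalid design: empty timepoint set")
    unknown = timepoints - {0, 4, 24}
    if unknown:
        raise DesignError(f"invalid design: unsupported timepoints {sorted(unknown)}")

    rows = []
    for d in range(1, n_donors + 1):
        donor = f"D{d}"
        for assay in ASSAYS:
            allowed = ASSAY_TIMEPOINTS[assay] & timepoints
            if 0 in allowed:
                rows.append((sample_name(donor, ZERO_H, 0, assay), donor, ZERO_H, 0, assay))
            for arm in ARMS:
                for tp in sorted(allowed - {0}):
                    rows.append((sample_name(donor, arm, tp, assay), donor, arm, tp, assay))
    return StudyDesign(pd.DataFrame(rows, columns=SAMPLE_COLUMNS))


def comparison_id(target: str, reference: str, timepoint_h: int) -> str:
    """Canonical name for a pairwise arm comparison at one timepoint."""
    return f"{target}_vs_{reference}@{timepoint_h}h"


def parse_comparison_id(cid: str) -> tuple[str, str, int]:
    pair, _, tp = cid.rpartition("@")
    target, _, reference = pair.partition("_vs_")
    if not target or not reference or not tp.endswith("h"):
        raise ValueError(f"malformed comparison id: {cid!r}")
    return target, reference, int(tp[:-1])


def comparison_samples(
    design: StudyDesign, assay: str, target: str, reference: str, timepoint_h: int
) -> tuple[list[str], list[str]]:
    """Sample ids for (target, reference) groups of one comparison.

    The 0 h control is always taken at timepoint 0; any other reference arm
    is taken at the same timepoint as the target.
    """
    tgt = design.arm_samples(assay, target, timepoint_h)
    ref_tp = 0 if reference == ZERO_H else timepoint_h
    ref = design.arm_samples(assay, reference, ref_tp)
    if not tgt:
        raise DesignError(f"no {assay} samples for arm {target} at {timepoint_h}h")
    if not ref:
        raise DesignError(f"no {assay} samples for arm {reference} at {ref_tp}h")
    return tgt, ref


def write_sample_sheet(design: StudyDesign, path) -> None:
    design.samples.to_csv(path, index=False)


def read_sample_sheet(path) -> StudyDesign:
    return StudyDesign(pd.read_csv(path))
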