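"""Pipeline configuration: a single declarative block with every
threshold, validated strictly (unknown keys rejected, types checked) and
hashed into all outputs for provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class PipelineConfig:
    # synthetic-study parameters
    seed: int = 1
    n_donors: int = 3
    n_probes: int = 20_000
    n_genes: int = 5_000
    noise_sd: float = 0.10
    donor_sd: float = 0.15
    dispersion: float = 0.02
    female: bool = False
    # differential thresholds
    delta_threshold: float = 0.05
    p_threshold: float = 0.05
    lfc_threshold: float = 0.58
    rpkm_min: float = 1.0
    # region calling
    dmr_max_gap_bp: int = 1000
    dmr_min_cpgs: int = 3
    # annotation
    nearest_max_bp: int = 1_000_000
    promoter_max_bp: int = 5000
    # enrichment composite filter
    motif_fold_min: float = 1.5
    motif_diff_min_pct: float = 5.0
    motif_min_targets: int = 2
    # schedule and output
    timepoints: tuple[int, ...] = (0, 4, 24)
    meth_timepoint: int = 24
    outdir: str = "monostim_results"
    make_plots: bool = False

    _POSITIVE = (
        "n_donors",
        "n_probes",
        "n_genes",
        "noise_sd",
        "dispersion",
        "delta_threshold",
        "p_threshold",
        "lfc_threshold",
        "dmr_max_gap_bp",
        "dmr_min_cpgs",
        "nearest_max_bp",
        "promoter_max_bp",
        "motif_fold_min",
        "motif_min_targets",
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d

    def config_hash(self) -> str:
        """Provenance hash over the analysis-relevant parameters (where
        outputs land and whether plots are drawn do not change results)."""
        d = {k: v for k, v in self.to_dict().items() if k not in ("outdir", "make_plots")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(raw) -> PipelineConfig:
    """Build a config from a dict, YAML text, or file path.

    All errors (unknown keys, type mismatches, sign violations) are
    collected and raised together as one :class:`ConfigError`.
    """
    if isinstance(raw, PipelineConfig):
        raw = raw.to_dict()
    elif isinstance(raw, str):
        try:
            with open(raw) as fh:
                raw = yaml.safe_load(fh)
        except OSError:
            raw = yaml.safe_load(raw)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])

    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    errors = []
    clean = {}
    for key, value in raw.items():
        if key not in fields:
            errors.append(f"unknown key {key!r}")
            continue
        ftype = fields[key].type
        if key == "timepoints":
            try:
                value = tuple(int(v) for v in value)
            except (TypeError, ValueError):
                errors.append("timepoints must be a list of integers")
                continue
        elif ftype in ("int", int):
            if isinstance(value, bool) or not isinstance(value, int):
                errors.append(f"{key} must be an integer, got {value!r}")
                continue
        elif ftype in ("float", float):
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                errors.append(f"{key} must be a number, got {value!r}")
                continue
            value = float(value)
        elif ftype in ("bool", bool):
            if not isinstance(value, bool):
                errors.append(f"{key} must be true/false, got {value!r}")
                continue
        clean[key] = value

    cfg = PipelineConfig(**{k: v for k, v in clean.items()})
    for key in PipelineConfig._POSITIVE:
        if key in clean and not (getattr(cfg, key) > 0):
            errors.append(f"{key} must be positive")
    if not cfg.timepoints:
        errors.append("timepoints: empty comparison schedule")
    for thr in ("delta_threshold", "p_threshold"):
        if not (0 < getattr(cfg, thr) < 1):
            errors.append(f"{thr} must lie in (0, 1)")
    if errors:
        raise ConfigError(sorted(errors))
    return cfg
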