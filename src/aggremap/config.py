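"""Pipeline configuration: every threshold the analysis uses, in one place.

All fold-change thresholds are on the log2 scale.  The defaults encode the
published analysis choices: |log2FC| > 0.5 for the total proteome, > 1.0 for
phosphosites, >= 0.25 for the detergent-insoluble fraction, BH-adjusted
p < 0.05 throughout, and a PPI edge-confidence cutoff of 0.999.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and stage parameters for the full analysis.

    Attributes
    ----------
    lfc_total, lfc_phospho, lfc_insoluble:
        log2 fold-change cutoffs for calling significance in the three
        analyses.  Total and phospho use strict ``>``; the insoluble
        fraction uses ``>=`` (matching the printed operator).
    padj:
        BH-adjusted p-value cutoff (strict ``<``).
    conf_cutoff:
        minimum PPI edge confidence retained (``>=`` semantics).
    global_observed_min:
        a feature must be observed in strictly more than this fraction of
        all analytic samples to be kept.
    condition_missing_max:
        a feature is dropped if its missing fraction in any treatment group
        strictly exceeds this.
    impute_width, impute_shift:
        downshifted-normal imputation parameters in units of the per-sample
        standard deviation.
    outlier_z:
        robust z threshold on PC1-2 centroid distance for sample outliers.
    condition_missing_scope:
        'group' (per-treatment-group missingness, default) or 'all'
        (across all analytic samples of the run).
    first_order_mode:
        'induced' keeps every edge among seeds+neighbors; 'seed_incident'
        keeps only edges touching a seed.
    quantile_stage:
        whether to apply quantile normalization after median normalization
        (off by default).
    """

    lfc_total: float = 0.5
    lfc_phospho: float = 1.0
    lfc_insoluble: float = 0.25
    padj: float = 0.05
    conf_cutoff: float = 0.999
    global_observed_min: float = 0.5
    condition_missing_max: float = 0.2
    impute_width: float = 0.3
    impute_shift: float = 1.8
    outlier_z: float = 4.0
    seed: int = 0
    condition_missing_scope: str = "group"
    first_order_mode: str = "induced"
    quantile_stage: bool = False

    def __post_init__(self) -> None:
        for name in ("lfc_total", "lfc_phospho", "lfc_insoluble"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.padj < 1):
            raise ValueError("padj must lie in (0, 1)")
        if not (0 <= self.conf_cutoff <= 1):
            raise ValueError("conf_cutoff must lie in [0, 1]")
        if self.condition_missing_scope not in ("group", "all"):
            raise ValueError("condition_missing_scope must be 'group' or 'all'")
        if self.first_order_mode not in ("induced", "seed_incident"):
            raise ValueError("first_order_mode must be 'induced' or 'seed_incident'")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file; unknown keys are rejected.

    An empty file yields all defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a key/value mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys are {sorted(valid)}"
        )
    return PipelineConfig(**raw)
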