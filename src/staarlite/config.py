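"""Analysis configuration with the framework's standard defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .set_tests import WeightSetting

#: PHRED-scaled functional annotation channels expected in the annotation table
ANNOTATION_CHANNELS = [f"aPC{i}" for i in range(1, 10)] + ["CADD", "LINSIGHT", "FATHMM_XF"]

#: pseudo-channel for pure Beta(MAF) weighting (no annotation factor)
MAF_ONLY = "MAF_only"

CODING_CATEGORIES = ["pLoF", "DS", "pLoF_and_DS", "missense", "synonymous"]
NONCODING_CATEGORIES = [
    "UTR",
    "upstream",
    "downstream",
    "promoter_CAGE",
    "promoter_DHS",
    "enhancer_CAGE",
    "enhancer_DHS",
]
ALL_CATEGORIES = CODING_CATEGORIES + NONCODING_CATEGORIES + ["ncRNA"]


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the gene-centric rare-variant analysis.

    rare_maf_threshold : include variants with MAF below this (in-sample MAF).
    mac_threshold : MAC below this is "ultra-rare"; drives the ACAT-V pooled
        burden component and the omnibus safeguards.
    cmac_report_min : aggregates with cumulative MAC below this are dropped
        from the results table (reported only in the log).
    alpha / alpha_suggestive : genome-wide and suggestive significance
        thresholds for flagging results.
    channels : annotation channels to run (subset of ANNOTATION_CHANNELS);
        the MAF-only channel is always included in addition.
    """

    rare_maf_threshold: float = 0.01
    mac_threshold: int = 10
    cmac_report_min: int = 10
    alpha: float = 1e-7
    alpha_suggestive: float = 1e-6
    channels: list = field(default_factory=lambda: list(ANNOTATION_CHANNELS))
    weight_settings: tuple = ((1.0, 25.0), (1.0, 1.0))

    @property
    def settings(self) -> list:
        return [WeightSetting(a1, a2) for a1, a2 in self.weight_settings]

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "weight_settings" in data:
            data["weight_settings"] = tuple(tuple(s) for s in data["weight_settings"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
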