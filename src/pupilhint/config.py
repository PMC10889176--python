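"""Pipeline configuration: one flat record of every tunable parameter.

Defaults follow the study protocol wherever it fixes a value (60 Hz
grid, 35/100 ms blink margins, 2.5 SD / 40 ms outlier rule, 50%
exclusion, 50 ms smoothing, [-1, +4] s epochs, 20-sentence lists,
+5 dB SNR start, 65 dB SPL speech, 3 s noise lead / 4 s tail) and the
package's documented choices elsewhere (confidence floor, MAD
multiplier, gap bridging, staircase step, outcome rule).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    # preprocessing
    fs: float = 60.0
    confidence_floor: float = 0.6
    k_mad: float = 3.0
    pre_margin: float = 0.035
    post_margin: float = 0.100
    outlier_z: float = 2.5
    min_island: float = 0.040
    outlier_islands: bool = True
    max_gap: float = 0.3
    smooth_window: float = 0.050
    max_removed_fraction: float = 0.5
    interpolate: bool = True
    # epoching
    epoch_start: float = -1.0
    epoch_end: float = 4.0
    ppd_window_start: float = 0.0
    ppd_window_end: float = 4.0
    # staircase
    n_sentences: int = 20
    start_snr: float = 5.0
    speech_level: float = 65.0
    step: float = 2.0
    noise_lead: float = 3.0
    noise_tail: float = 4.0
    sentence_duration: float = 3.0
    outcome_rule: str = "mean_after_4"
    # design
    n_subjects: int = 8
    # statistics
    alpha: float = 0.05
    # reproducibility
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
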