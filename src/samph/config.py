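"""Pipeline configuration: every tunable with its default, serializable.

Defaults are the reference analysis settings: 500 ms merge threshold, 10 s
length floor with 1 s joiner silence, 3 s end pads, 28-channel ERB_N acoustic
bank over 100-7250 Hz, 24-channel log-spaced modulation bank over 0.9-40 Hz,
5/3 retained components, 2/5-channel peak separations, 10% low-cycle
threshold, ratio grid up to max integer 4, FDR alpha 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # preprocessing
    gap_threshold_ms: float = 500.0
    min_length_s: float = 10.0
    joiner_silence_s: float = 1.0
    pad_s: float = 3.0
    # acoustic (spectral) filter bank
    spectral_f_lo: float = 100.0
    spectral_f_hi: float = 7250.0
    spectral_channels: int = 28
    spectral_spacing: str = "erb_n"
    # modulation (temporal) filter bank
    temporal_f_lo: float = 0.9
    temporal_f_hi: float = 40.0
    temporal_channels: int = 24
    temporal_spacing: str = "log"
    # envelope rates
    spectral_env_fs: float = 1050.0
    temporal_env_fs: float = 120.0
    # PCA / band criteria
    spectral_components: int = 5
    temporal_components: int = 3
    spectral_target_bands: int = 5
    temporal_target_bands: int = 3
    spectral_peak_separation: int = 2
    temporal_peak_separation: int = 5
    low_cycle_threshold: float = 0.10
    pca_standardize: bool = False
    # phase synchronization
    ratio_labels: tuple = ("1:2", "1:3", "2:3")
    ratio_max_integer: int = 4
    # statistics
    fdr_alpha: float = 0.05
    equivalence_margin: tuple = (0.90, 1.10)
    equivalence_conf: float = 0.90
    # randomness
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        cfg.ratio_labels = tuple(cfg.ratio_labels)
        cfg.equivalence_margin = tuple(cfg.equivalence_margin)
        return cfg

    def sha1(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]
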