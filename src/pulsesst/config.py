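"""Analysis configuration with YAML round-trip and content hashing.

Defaults follow the study setup: Gaussian window sigma = 0.5 s, harmonic
cutoff D = 6, 100-Hz 10-s records, 1000 bootstrap replicas, 200 LOOCV
repeats, and a 0.01 significance level for the functional ANOVA.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass

import yaml

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    # STFT / SST
    sigma: float = 0.5            # Gaussian kernel bandwidth, s
    half_width: float = 2.0       # window truncation (4*sigma), s
    hop: int = 1                  # frame hop, samples
    freq_max: float = 10.0        # top of the frequency axis, Hz
    df: float = 0.02              # frequency bin width, Hz
    threshold: float = 1e-4       # relative magnitude floor for reassignment
    # ridge / demodulation
    ridge_low: float = 0.5        # search band, Hz (30 bpm)
    ridge_high: float = 3.0       # search band, Hz (180 bpm)
    smoothness: float = 1.0       # DP jump penalty per squared bin
    recon_band: float = 0.25      # reconstruction half-band, Hz
    # regression
    D: int = 6                    # harmonic cutoff
    edge_trim: float = 2.0        # seconds trimmed from each end (= half_width)
    detrend_hz: float = 0.4       # high-pass cutoff before TF analysis
    n_passes: int = 2             # demodulation passes (2 = harmonic-refined)
    # cohort statistics
    n_components: int = 2         # PLS latent components
    n_perm: int = 999             # GPF permutations
    n_boot: int = 1000            # bootstrap replicas for the AUC CI
    n_repeats: int = 200          # LOOCV repeats
    alpha: float = 0.01           # significance level
    seed: int = 0

    def __post_init__(self):
        positive = ("sigma", "half_width", "freq_max", "df", "ridge_low",
                    "ridge_high", "smoothness", "recon_band", "edge_trim",
                    "alpha")
        for name in positive:
            if getattr(self, name) < 0 or (name != "edge_trim"
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.detrend_hz < 0:
            raise ValueError("detrend_hz must be non-negative")
        if self.n_passes not in (1, 2):
            raise ValueError("n_passes must be 1 or 2")
        for name in ("hop", "D", "n_components", "n_perm", "n_boot",
                     "n_repeats"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.ridge_low >= self.ridge_high:
            raise ValueError("ridge search band is empty")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ValueError("config source did not parse to a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
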