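"""Run configuration: every tunable of the extraction/staging chain.

Defaults are the reference settings the rest of the package is tested
against; any field can be overridden from a YAML file or CLI flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RespConfig:
    band_hz: tuple[float, float] = (200.0, 2000.0)  # breath-sound passband
    window_s: float = 0.2        # envelope window
    hop_s: float = 0.05          # envelope hop
    threshold_factor: float = 1.2   # breath threshold = factor * median(envelope)
    min_breath_s: float = 0.3    # breath-duration plausibility gate
    max_breath_s: float = 10.0
    bb_bounds_s: tuple[float, float] = (1.0, 15.0)  # 4-60 breaths/min
    envelope_kind: str = "rms"   # "rms" or "mean_abs"
    noise_quantile: float = 0.10  # quietest fraction used for the noise template
    context_s: float = 60.0      # interval statistics use epoch +/- context

    def validate(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("resp.band_hz must satisfy 0 < low < high")
        if not 0 < self.hop_s <= self.window_s:
            raise ValueError("resp hop must be in (0, window]")
        if self.threshold_factor <= 0:
            raise ValueError("resp.threshold_factor must be positive")
        if self.envelope_kind not in ("rms", "mean_abs"):
            raise ValueError("resp.envelope_kind must be 'rms' or 'mean_abs'")
        if not 0 < self.noise_quantile < 1:
            raise ValueError("resp.noise_quantile must be in (0, 1)")


@dataclass
class CardiacConfig:
    band_hz: tuple[float, float] = (5.0, 30.0)     # heart-sound passband
    working_rate_hz: float = 250.0   # decimation target before filtering
    peak_k_mad: float = 3.0          # peak threshold = median + k * MAD
    refractory_s: float = 0.08       # minimum peak separation
    s1s2_window_s: tuple[float, float] = (0.15, 0.45)  # S1-S2 plausibility
    nn_bounds_s: tuple[float, float] = (0.33, 1.5)     # 40-180 bpm
    gap_factor: float = 1.5          # NN > factor * rolling median => gap
    gap_history: int = 10            # rolling-median horizon (beats)
    time_context_s: float = 60.0     # time-domain HRV window: epoch +/- context
    spectral_context_s: float = 120.0  # spectral HRV window
    nn_resample_hz: float = 4.0      # NN-series resampling for spectra

    def validate(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("cardiac.band_hz must satisfy 0 < low < high")
        if self.working_rate_hz < 2 * hi:
            raise ValueError("cardiac working rate must cover the band (Nyquist)")
        s_lo, s_hi = self.s1s2_window_s
        if not 0 < s_lo < s_hi:
            raise ValueError("cardiac.s1s2_window_s must be increasing and positive")


@dataclass
class ImuConfig:
    beta: float = 0.1            # Madgwick gradient gain
    mounting: str = "z-dorsal"   # sensor z dorsal-ventral, y cranial-caudal
    hysteresis_samples: int = 5  # position-label debounce
    gravity: float = 9.81        # m/s^2

    def validate(self) -> None:
        if self.beta < 0:
            raise ValueError("imu.beta must be >= 0")
        if self.hysteresis_samples < 0:
            raise ValueError("imu.hysteresis_samples must be >= 0")


@dataclass
class StagingConfig:
    shrinkage: float = 0.1       # lambda in (1-l)*Sigma + l*diag(Sigma)
    priors: str = "empirical"    # or "uniform"
    median_filter_epochs: int = 0  # optional hypnogram smoothing, off by default

    def validate(self) -> None:
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("staging.shrinkage must be in [0, 1]")
        if self.priors not in ("empirical", "uniform"):
            raise ValueError("staging.priors must be 'empirical' or 'uniform'")


@dataclass
class RunConfig:
    resp: RespConfig = field(default_factory=RespConfig)
    cardiac: CardiacConfig = field(default_factory=CardiacConfig)
    imu: ImuConfig = field(default_factory=ImuConfig)
    staging: StagingConfig = field(default_factory=StagingConfig)
    offset_seconds: float = 0.0  # recording-to-epoch-0 alignment
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        self.resp.validate()
        self.cardiac.validate()
        self.imu.validate()
        self.staging.validate()
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_cls, sub):
            kwargs = dict(sub or {})
            for k, v in kwargs.items():
                if isinstance(v, list):
                    kwargs[k] = tuple(v)
            return dc_cls(**kwargs)

        cfg = cls(
            resp=build(RespConfig, data.get("resp")),
            cardiac=build(CardiacConfig, data.get("cardiac")),
            imu=build(ImuConfig, data.get("imu")),
            staging=build(StagingConfig, data.get("staging")),
            offset_seconds=float(data.get("offset_seconds", 0.0)),
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "INFO")),
        )
        return cfg.validate()
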