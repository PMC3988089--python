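"""Run configuration shared by the extraction pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the extraction/RIA pipeline.

    rt_window_min
        Full width (minutes) of the retention-time search window, applied
        ± half around each target's reference RT.
    tol_mono_ppm / tol_iso_ppm
        Matching half-windows for the first (gating) template peak and for
        subsequent isotope peaks; the isotope tolerance is wider because mass
        accuracy decreases with decreasing intensity.
    coelution_ratio
        A picked peak more than this factor above its predecessor is treated
        as a co-eluting interference and removed/re-picked.
    penalty_value, penalty_low, penalty_high, penalty_tol_ppm
        Score penalty applied when a peak one envelope spacing below the
        first picked peak has intensity within (low, high) times its
        intensity, indicating the gate is an isotope peak of another peptide.
    w_coverage, w_ppm
        Weights of the coverage reward and the ppm-deviation penalty in the
        total scan score.
    postfilter_epsilon
        Tolerated per-step RIA decrease in the monotonicity post-filter
        (0 = strict).
    """

    rt_window_min: float = 10.0
    tol_mono_ppm: float = 10.0
    tol_iso_ppm: float = 20.0
    coelution_ratio: float = 3.0
    penalty_value: float = 3.0
    penalty_low: float = 0.5
    penalty_high: float = 2.0
    penalty_tol_ppm: float = 10.0
    w_coverage: float = 1.0
    w_ppm: float = 1.0
    postfilter_epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "rt_window_min",
            "tol_mono_ppm",
            "tol_iso_ppm",
            "coelution_ratio",
            "penalty_tol_ppm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.postfilter_epsilon < 0:
            raise ValueError("postfilter_epsilon must be >= 0")
        if not 0 <= self.penalty_low < self.penalty_high:
            raise ValueError("penalty band must satisfy 0 <= low < high")

    @classmethod
    def from_mapping(cls, mapping) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**{k: type(getattr(cls(), k))(v) for k, v in mapping.items()})
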