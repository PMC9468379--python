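"""Run configuration shared by the CLI and the cohort pipeline.

Defaults are the clinical-protocol values: a 1 mm surface tolerance for
the efficiency gain, HD at the 95th percentile, 1 cGy DVH bins, a 0.05
relative-volume flagging tolerance with a 20 cGy dose window applied at
dose levels >= 20 cGy, and a longitudinal refinement factor of 3 (7.5 mm
CT slices -> 2.5 mm DVH sampling).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import ArgumentError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    delta_mm: float = 1.0
    hd_percentile: float = 95.0
    dvh_bin_cgy: float = 1.0
    vol_tolerance: float = 0.05
    dose_window_cgy: float = 20.0
    min_dose_cgy: float = 20.0
    longitudinal_factor: int = 3
    eff_direction: str = "a_to_b"  # AI -> clinical
    seed: int = 0

    def __post_init__(self):
        if self.delta_mm <= 0 or self.dvh_bin_cgy <= 0 or self.vol_tolerance <= 0:
            raise ArgumentError("tolerances must be positive")
        if not 0 < self.hd_percentile <= 100:
            raise ArgumentError("hd_percentile must lie in (0, 100]")
        if self.dose_window_cgy < 0 or self.min_dose_cgy < 0:
            raise ArgumentError("dose window and minimum dose must be >= 0")
        if self.longitudinal_factor < 1:
            raise ArgumentError("longitudinal_factor must be >= 1")
        if self.eff_direction not in ("a_to_b", "b_to_a", "symmetric"):
            raise ArgumentError("eff_direction must be a_to_b, b_to_a or symmetric")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat ``key = value`` text file mirroring the fields."""
        kwargs = {}
        types = {f: type(getattr(cls(), f)) for f in cls().as_dict()}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ArgumentError(f"cannot parse config line: '{line}'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ArgumentError(f"unknown config key '{key}'")
            kwargs[key] = types[key](value)
        return cls(**kwargs)
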