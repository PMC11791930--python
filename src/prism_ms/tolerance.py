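"""m/z matching tolerances.

Two tolerance semantics coexist in the workflow and are never converted
silently into one another:

* relative (ppm) — used when aligning peaks at read time and when pulling
  ion images (default 10 ppm);
* absolute (Da) — used when reducing spectra to annotated peaks
  (default ±0.005 Da).

A :class:`Tolerance` carries its kind explicitly so call sites cannot mix
them up.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Tolerance:
    value: float
    kind: str  # "ppm" or "da"

    def __post_init__(self) -> None:
        if self.kind not in ("ppm", "da"):
            raise ValueError(f"tolerance kind must be 'ppm' or 'da', got {self.kind!r}")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    def half_width(self, mz: float) -> float:
        """Absolute half-width of the matching window at a given m/z."""
        if self.kind == "ppm":
            return mz * self.value * 1e-6
        return self.value

    def window(self, mz: float) -> tuple[float, float]:
        h = self.half_width(mz)
        return mz - h, mz + h

    def __str__(self) -> str:
        return f"±{self.value:g} {'ppm' if self.kind == 'ppm' else 'Da'}"


def ppm(value: float) -> Tolerance:
    return Tolerance(value, "ppm")


def da(value: float) -> Tolerance:
    return Tolerance(value, "da")
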