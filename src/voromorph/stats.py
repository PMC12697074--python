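"""Summary statistics, the pooled-variance t-test, FT-IR band-area ratios,
and the Fickian diffusion-barrier time.

The significance test matches the convention used throughout the growth-curve
comparisons: a two-tailed Student's t-test assuming equal variance, with star
labels at the usual thresholds (ns p>=0.05, * <0.05, ** <0.01, *** <0.001).
p-values come from the exact t cumulative distribution — at n = 3 replicates
per group the normal approximation is far too optimistic in the tails.

FT-IR quantification follows the relative-band-area convention: peak areas are
integrated over fixed wavenumber windows (O-H/N-H 3200-3600, amide I+II
1500-1700, C-O 1000-1150 cm^-1) and expressed relative to the C-H stretching
reference window (2800-3000 cm^-1), which is insensitive to copper exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStat",
    "TTestResult",
    "Spectrum",
    "BandRatios",
    "FTIR_WINDOWS",
    "summarize",
    "relative_error",
    "student_t_test",
    "band_area",
    "band_ratios",
    "percent_reduction",
    "diffusion_t90",
]


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class SummaryStat:
    mean: float
    sd: float
    se: float
    n: int

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "se": self.se, "n": self.n}


def summarize(values) -> SummaryStat:
    """Mean, sample SD (n-1 denominator) and SE = SD/sqrt(n).

    A single value yields sd = se = 0 (degenerate but defined).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise StatsError("cannot summarize an empty list")
    if not np.all(np.isfinite(v)):
        raise StatsError("values must be finite")
    n = int(v.size)
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
    return SummaryStat(mean=mean, sd=sd, se=sd / math.sqrt(n), n=n)


def relative_error(observed_mean: float, theoretical: float) -> float:
    """Percent deviation of an observed mean from a theoretical value,
    (theoretical - observed) / theoretical x 100, reported to one decimal."""
    if theoretical == 0:
        raise StatsError("theoretical value must be nonzero")
    return round((theoretical - observed_mean) / theoretical * 100.0, 1)


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significance_label: str

    def to_dict(self) -> dict:
        return {
            "t": self.t_statistic,
            "df": self.degrees_of_freedom,
            "p": self.p_value,
            "label": self.significance_label,
        }


def _significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def student_t_test(group_a, group_b) -> TTestResult:
    """Two-tailed Student's t-test assuming equal variance (pooled)."""
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    df = na + nb - 2
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    diff = float(np.mean(a) - np.mean(b))
    if pooled == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, "ns")
        raise StatsError("zero pooled variance with unequal means: t undefined")
    t = diff / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), int(df), p, _significance_label(p))


# ---------------------------------------------------------------------------
# FT-IR band areas

#: Evaluation windows in cm^-1: a = O-H/N-H, b = amide I+II, c = C-O,
#: d = C-H reference.
FTIR_WINDOWS: dict[str, tuple[float, float]] = {
    "a": (3200.0, 3600.0),
    "b": (1500.0, 1700.0),
    "c": (1000.0, 1150.0),
    "d": (2800.0, 3000.0),
}


@dataclass(frozen=True)
class Spectrum:
    """1-D spectrum; wavenumbers may be in FT-IR descending convention."""

    wavenumbers: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"  # or "transmittance" (fractional, in (0, 1])

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wn.ndim != 1 or wn.shape != v.shape or wn.size < 2:
            raise StatsError("spectrum needs matching 1-D wavenumber/value arrays")
        if self.kind not in ("absorbance", "transmittance"):
            raise StatsError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "values", v)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.wavenumbers.min()), float(self.wavenumbers.max())


@dataclass(frozen=True)
class BandRatios:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise StatsError("reference band area d must be positive")

    @property
    def a_over_d(self) -> float:
        return self.a / self.d

    @property
    def b_over_d(self) -> float:
        return self.b / self.d

    @property
    def c_over_d(self) -> float:
        return self.c / self.d

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "a_over_d": self.a_over_d,
            "b_over_d": self.b_over_d,
            "c_over_d": self.c_over_d,
        }


def band_area(
    spectrum: Spectrum,
    window: tuple[float, float],
    baseline: str = "linear_endpoints",
    as_absorbance: bool = True,
) -> float:
    """Trapezoidal band area over a wavenumber window.

    Transmittance spectra are converted to absorbance (-log10 T) before
    integration unless ``as_absorbance`` is False (band-area comparisons are
    conventionally absorbance-based).  ``baseline='linear_endpoints'``
    subtracts the chord joining the window-edge values; ``'none'`` integrates
    the raw signal.
    """
    lo, hi = sorted(float(w) for w in window)
    wn = spectrum.wavenumbers
    if lo < wn.min() - 1e-9 or hi > wn.max() + 1e-9:
        raise StatsError(
            f"window ({lo}, {hi}) cm^-1 outside spectrum range {spectrum.range}"
        )
    order = np.argsort(wn)
    x = wn[order]
    y = spectrum.values[order]
    if spectrum.kind == "transmittance" and as_absorbance:
        y = -np.log10(np.clip(y, 1e-12, None))
    sel = (x >= lo) & (x <= hi)
    if np.count_nonzero(sel) < 3:
        raise StatsError(f"fewer than 3 samples inside window ({lo}, {hi})")
    xs, ys = x[sel], y[sel]
    if baseline == "linear_endpoints":
        base = ys[0] + (ys[-1] - ys[0]) * (xs - xs[0]) / (xs[-1] - xs[0])
        ys = ys - base
    elif baseline != "none":
        raise StatsError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(ys, xs))


def band_ratios(
    spectrum: Spectrum,
    baseline: str = "linear_endpoints",
    as_absorbance: bool = True,
    windows: dict[str, tuple[float, float]] | None = None,
) -> BandRatios:
    """Areas of the four evaluation windows and their ratios to the C-H
    reference band d."""
    windows = windows or FTIR_WINDOWS
    lo, hi = spectrum.range
    areas = {}
    for name in ("a", "b", "c", "d"):
        wlo, whi = windows[name]
        if wlo < lo - 1e-9 or whi > hi + 1e-9:
            raise StatsError(
                f"spectrum does not cover window {name} ({wlo}-{whi} cm^-1)"
            )
        areas[name] = band_area(spectrum, (wlo, whi), baseline, as_absorbance)
    return BandRatios(**areas)


def percent_reduction(control_ratio: float, treated_ratio: float) -> float:
    """Percent reduction of a treated band ratio relative to control:
    (1 - treated/control) x 100."""
    if control_ratio <= 0:
        raise StatsError("control ratio must be positive")
    return (1.0 - treated_ratio / control_ratio) * 100.0


def diffusion_t90(L: float, De: float) -> float:
    """Time for a solute at depth L inside a biofilm to reach 90% of the bulk
    concentration under Fickian diffusion: t90 = 1.03 L^2 / De."""
    if L <= 0 or De <= 0:
        raise StatsError("L and De must be positive")
    return 1.03 * L * L / De
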