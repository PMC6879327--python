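"""G4 fluorescent-intercalator-displacement (FID) titration analysis.

In a G4-FID assay a fluorescent probe (thiazole/thymidine orange, TO) bound
to a folded G-quadruplex is displaced by increasing amounts of a protein or
ligand. The percentage of probe displaced after the x-th addition is

    TOD(x) = 100 - (FA_x / FA_1) * 100

where FA_1 is the fluorescence area recorded after TO addition and before
any titrant, and FA_x the area after the x-th addition. DC50 is the titrant
amount (in molar equivalents) displacing 50% of the probe; an indicative
dissociation midpoint is obtained from a Hill fit of the displacement
curve.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class FIDSeries:
    """Titration points (titrant molar equivalents, fluorescence area).

    ``fa1`` is the pre-titrant fluorescence area; the first point must be
    (0, area at zero titrant).
    """

    points: Tuple[Tuple[float, float], ...]
    fa1: float

    def __post_init__(self) -> None:
        if self.fa1 <= 0:
            raise ValueError("fa1 must be positive")
        concs = [c for c, _ in self.points]
        if not concs or concs[0] != 0:
            raise ValueError("titration must start at concentration 0")
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")

    @classmethod
    def from_points(cls, points: Sequence[Tuple[float, float]], fa1: Optional[float] = None) -> "FIDSeries":
        pts = tuple((float(c), float(fa)) for c, fa in points)
        return cls(points=pts, fa1=float(fa1 if fa1 is not None else pts[0][1]))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "FIDSeries":
        """Read a (conc, fluorescence_area) TSV with a header row."""
        pts: List[Tuple[float, float]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if lineno == 1:
                    try:
                        float(fields[0])
                    except ValueError:
                        continue  # header
                pts.append((float(fields[0]), float(fields[1])))
        return cls.from_points(pts)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def areas(self) -> np.ndarray:
        return np.array([fa for _, fa in self.points])


@dataclass(frozen=True)
class FIDResult:
    tod_curve: Tuple[Tuple[float, float], ...]
    dc50: float
    kd_indicative: Optional[float] = None
    hill_coef: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "tod_curve": [list(p) for p in self.tod_curve],
            "dc50": self.dc50,
            "kd_indicative": self.kd_indicative,
            "hill_coef": self.hill_coef,
        }


def tod_percent(fa_x: float, fa1: float) -> float:
    """Percent probe displacement: 0 at FA_x = FA_1, 100 at FA_x = 0."""
    if fa1 <= 0:
        raise ValueError("fa1 must be positive")
    if fa_x < 0:
        raise ValueError("fluorescence area must be non-negative")
    return 100.0 - (fa_x / fa1) * 100.0


def tod_curve(series: FIDSeries, clamp: bool = False) -> List[Tuple[float, float]]:
    """Displacement curve (conc, TOD%). Raw values can exceed [0, 100] under
    noise; ``clamp`` restricts them to that range for reporting."""
    curve = [(c, tod_percent(fa, series.fa1)) for c, fa in series.points]
    if clamp:
        curve = [(c, min(100.0, max(0.0, t))) for c, t in curve]
    return curve


def dc50(series: FIDSeries) -> float:
    """Titrant amount at 50% displacement, by linear interpolation.

    The displacement curve is monotone-smoothed (running maximum) before
    interpolation; a non-monotone crossing uses the first crossing and
    emits a warning.
    """
    concs = series.concentrations
    raw = np.array([tod_percent(fa, series.fa1) for fa in series.areas])
    smooth = np.maximum.accumulate(raw)
    if smooth.max() < 50.0:
        raise ValueError(f"DC50 not reached: max displacement {smooth.max():.1f}% < 50%")
    i = int(np.argmax(smooth >= 50.0))
    if (raw[: i + 1] != smooth[: i + 1]).any():
        warnings.warn("non-monotone displacement curve: first 50% crossing used")
    if i == 0:
        return float(concs[0])
    t0, t1 = smooth[i - 1], smooth[i]
    c0, c1 = concs[i - 1], concs[i]
    if t1 == t0:
        return float(c1)
    return float(c0 + (50.0 - t0) * (c1 - c0) / (t1 - t0))


def _hill(c: np.ndarray, k: float, h: float) -> np.ndarray:
    ch = np.power(c, h)
    return 100.0 * ch / (ch + k**h)


def fit_hill(series: FIDSeries, max_nfev: int = 10000) -> Tuple[float, float]:
    """Least-squares Hill fit TOD(c) = 100 c^h / (c^h + K^h).

    Returns (K, h). K is the indicative dissociation midpoint in the same
    units as the titration (molar equivalents); h the Hill coefficient.
    Initialization uses the interpolated DC50 (or the median concentration
    when 50% is not reached) and h = 1. Raw, unclamped TOD values are
    fitted.
    """
    if len(series.points) < 4:
        raise ValueError("Hill fit requires >= 4 titration points")
    concs = series.concentrations
    tods = np.array([tod_percent(fa, series.fa1) for fa in series.areas])
    try:
        k0 = dc50(series)
    except ValueError:
        k0 = float(np.median(concs[concs > 0]))
    if k0 <= 0:
        k0 = float(np.median(concs[concs > 0]))
    try:
        popt, _ = curve_fit(
            _hill,
            concs,
            tods,
            p0=(k0, 1.0),
            bounds=((1e-9, 0.05), (np.inf, 20.0)),
            max_nfev=max_nfev,
        )
    except RuntimeError as exc:
        resid = float(np.sum((_hill(concs, k0, 1.0) - tods) ** 2))
        raise RuntimeError(
            f"Hill fit did not converge (initial residual {resid:.3g})"
        ) from exc
    return float(popt[0]), float(popt[1])


def analyze_series(series: FIDSeries, fit: bool = True) -> FIDResult:
    """Full FID analysis: clamped displacement curve, DC50, optional Hill fit."""
    curve = tuple(tod_curve(series, clamp=True))
    value = dc50(series)
    kd, h = (None, None)
    if fit and len(series.points) >= 4:
        try:
            kd, h = fit_hill(series)
        except RuntimeError:
            warnings.warn("Hill fit failed; reporting DC50 only")
    return FIDResult(tod_curve=curve, dc50=value, kd_indicative=kd, hill_coef=h)
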