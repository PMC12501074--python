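"""Per-motif calibration of misincorporation ratio to D stoichiometry.

The observed T->C mutation ratio y at a D site responds linearly to the
true modified fraction x of the transcript pool, with slope and intercept
that depend on the 5-mer sequence context: y = A x + b. Curves are fitted
per motif from a six-level defined-mixture probe series (0, 20, 40, 60,
80, 100% D) and inverted at call time, x = (y - b)/A, clamped to [0, 1].
Unmodified (0% D) probes give the per-motif background misincorporation
rate used by the callers' fold-over-background criteria.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from scipy import stats

from craci.io_formats import as_count_frame, motif_at

BASES = "ACGT"

#: Mixture levels of the defined D-fraction probe series.
CALIBRATION_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: Floor applied to denominators in fold-change ratios so perfectly clean
#: motifs or zero-ratio inputs do not divide by zero.
FOLD_EPSILON = 1e-4


class DegenerateDesignError(ValueError):
    """Calibration points do not span >= 2 distinct D-fraction levels."""


class NonInvertibleCurveError(ValueError):
    """Curve slope is not positive; ratio cannot be inverted to a fraction."""


def enumerate_motifs() -> list[str]:
    """All 256 5-mers over {A,C,G,T} with a central T, lexicographic."""
    return [
        a + b + "T" + c + d
        for a in BASES for b in BASES for c in BASES for d in BASES
    ]


@dataclass
class CalibrationPoint:
    """One (known D fraction, observed ratio) pair for one motif."""

    motif: str
    d_fraction_true: float
    ratio_observed: float
    depth: int = 0


@dataclass
class CalibrationCurve:
    """Fitted linear response y = A x + b for one motif."""

    motif: str
    slope_A: float
    intercept_b: float
    r2: float | None = None
    n_points: int = 0


class FractionEstimate(NamedTuple):
    """Inverted stoichiometry with a flag marking out-of-range clamping."""

    value: float
    clamped: bool


def fit_calibration(points: Iterable[CalibrationPoint],
                    weight_by_depth: bool = False) -> CalibrationCurve:
    """Ordinary least-squares fit of y = A x + b for one motif's points.

    Requires >= 2 distinct x levels. ``weight_by_depth`` switches to
    depth-weighted least squares; the default is unweighted, matching the
    plain linear fit of the probe design (probe depths are near-uniform).
    """
    pts = list(points)
    motifs = {p.motif for p in pts}
    if len(motifs) > 1:
        raise ValueError(f"fit_calibration got points from multiple motifs: {sorted(motifs)}")
    x = np.array([p.d_fraction_true for p in pts], dtype=float)
    y = np.array([p.ratio_observed for p in pts], dtype=float)
    if len(np.unique(x)) < 2:
        raise DegenerateDesignError(
            f"need >= 2 distinct D-fraction levels, got {sorted(set(x.tolist()))}"
        )
    if weight_by_depth:
        w = np.array([max(p.depth, 1) for p in pts], dtype=float)
        W = np.diag(w)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        slope, intercept = float(beta[0]), float(beta[1])
        yhat = slope * x + intercept
        ybar = np.average(y, weights=w)
        ss_res = float(np.sum(w * (y - yhat) ** 2))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2) if np.var(y) > 0 else None
    if slope == 0.0:
        warnings.warn(f"flat calibration for motif {pts[0].motif}: slope A = 0", stacklevel=2)
    return CalibrationCurve(
        motif=pts[0].motif, slope_A=slope, intercept_b=intercept,
        r2=r2, n_points=len(pts),
    )


def fit_calibration_table(points: Iterable[CalibrationPoint],
                          weight_by_depth: bool = False) -> "CalibrationSet":
    """Group points by motif and fit one curve per motif."""
    by_motif: dict[str, list[CalibrationPoint]] = {}
    for p in points:
        by_motif.setdefault(p.motif, []).append(p)
    curves = [
        fit_calibration(pts, weight_by_depth=weight_by_depth)
        for _, pts in sorted(by_motif.items())
    ]
    return CalibrationSet(curves)


def estimate_fraction(ratio_observed: float, curve: CalibrationCurve) -> FractionEstimate:
    """Invert an observed mutation ratio to D stoichiometry, x = (y - b)/A.

    The raw estimate is clamped to [0, 1]; ``clamped`` records whether
    clamping fired (over-/under-shoot is measurement noise, not an error).
    A non-positive slope cannot be inverted and raises.
    """
    if curve.slope_A <= 0:
        raise NonInvertibleCurveError(
            f"curve for motif {curve.motif} has slope A={curve.slope_A} <= 0"
        )
    raw = (ratio_observed - curve.intercept_b) / curve.slope_A
    clamped = raw < 0.0 or raw > 1.0
    return FractionEstimate(value=min(max(raw, 0.0), 1.0), clamped=clamped)


class CalibrationSet:
    """Per-motif curves with a global mean-curve fallback.

    Real genomes may not cover all 256 contexts; a motif with no fitted
    curve falls back to the mean (A, b) over available motifs, and the
    lookup reports the fallback so calls can be flagged.
    """

    def __init__(self, curves: Iterable[CalibrationCurve]):
        self.curves: dict[str, CalibrationCurve] = {c.motif: c for c in curves}
        if self.curves:
            slopes = [c.slope_A for c in self.curves.values()]
            intercepts = [c.intercept_b for c in self.curves.values()]
            self.global_curve = CalibrationCurve(
                motif="GLOBAL",
                slope_A=float(np.mean(slopes)),
                intercept_b=float(np.mean(intercepts)),
                n_points=sum(c.n_points for c in self.curves.values()),
            )
        else:
            self.global_curve = None

    def get(self, motif: str) -> tuple[CalibrationCurve | None, bool]:
        """Return (curve, used_fallback) for a motif."""
        if motif in self.curves:
            return self.curves[motif], False
        return self.global_curve, True

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves.values())


@dataclass
class BackgroundTable:
    """Per-motif misincorporation rate of unmodified (0% D) uridine."""

    rates: dict[str, float] = field(default_factory=dict)
    depths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for motif, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"background rate for {motif} out of [0,1]: {r}")

    @property
    def global_bg(self) -> float:
        """Unweighted mean rate across motifs present."""
        if not self.rates:
            raise ValueError("empty background table")
        return float(np.mean(list(self.rates.values())))

    def get(self, motif: str) -> tuple[float, bool]:
        """Return (rate, used_global_fallback) for a motif."""
        if motif in self.rates:
            return self.rates[motif], False
        return self.global_bg, True


def build_background(records, reference: Mapping[str, str]) -> BackgroundTable:
    """Per-motif background from 0%-D probe counts.

    Each motif's rate is the depth-weighted mean tc ratio over its
    reference-T sites (equivalently, pooled counts: sum n_C over
    sum n_C + n_T). Only T sites with a nonzero C+T denominator count.
    """
    df = as_count_frame(records)
    df = df[df["ref_base"] == "T"]
    if df.empty:
        raise ValueError("no reference-T sites in background records")
    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for row in df.itertuples(index=False):
        seq = reference[row.ref_id]
        motif = motif_at(seq, row.pos)
        ct = row.n_C + row.n_T
        if ct == 0:
            continue
        num[motif] = num.get(motif, 0.0) + row.n_C
        den[motif] = den.get(motif, 0.0) + ct
    if not num:
        raise ValueError("no covered reference-T sites in background records")
    rates = {m: num[m] / den[m] for m in num}
    depths = {m: int(den[m]) for m in den}
    return BackgroundTable(rates=rates, depths=depths)


def background_ci(table: BackgroundTable, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI of the mean background rate across motifs.

    mean +/- z * sd / sqrt(n) over motif-level rates; needs >= 2 motifs.
    """
    vals = np.array(list(table.rates.values()), dtype=float)
    if len(vals) < 2:
        raise ValueError("background CI needs >= 2 motifs")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * sd / math.sqrt(len(vals))
    return (mean - half, mean + half)
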