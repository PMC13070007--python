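"""Downstream assay summaries: flow fractions, DAR, 4PL dose-response.

Deterministic arithmetic applied after antibody selection: quadrant
percentages from TRBC1/TRBC2 co-staining of normal T cells, the malignant
fraction of circulating T cells in patient samples (cancer cells lose CD26,
so TRBC2+CD26- marks the malignant population), the drug-to-antibody ratio
as the area-weighted mean drug load over chromatogram peaks, and IC50
estimation by four-parameter logistic (4PL) fitting of killing curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class FlowQuadrantCounts:
    """Cell counts from TRBC1 x TRBC2 co-staining quadrants."""

    trbc1_only: int
    trbc2_only: int
    dual_pos: int
    dual_neg: int

    def __post_init__(self) -> None:
        if min(self.trbc1_only, self.trbc2_only, self.dual_pos, self.dual_neg) < 0:
            raise AssayError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.trbc1_only + self.trbc2_only + self.dual_pos + self.dual_neg


@dataclass(frozen=True)
class PatientFlowCounts:
    """Patient T-cell compartments: malignant (TRBC2+CD26-) and normal cells."""

    cancer: int
    normal_trbc2: int
    normal_trbc1: int
    total_T: int

    def __post_init__(self) -> None:
        if min(self.cancer, self.normal_trbc2, self.normal_trbc1) < 0:
            raise AssayError("counts must be non-negative")
        if self.cancer + self.normal_trbc2 + self.normal_trbc1 > self.total_T:
            raise AssayError("component counts exceed total T cells")


def quadrant_percentages(counts: FlowQuadrantCounts) -> dict[str, float]:
    """Percentage of total cells in each staining quadrant (sums to 100)."""
    total = counts.total
    if total == 0:
        raise AssayError("zero total cell count")
    return {
        "trbc1_only": 100.0 * counts.trbc1_only / total,
        "trbc2_only": 100.0 * counts.trbc2_only / total,
        "dual_pos": 100.0 * counts.dual_pos / total,
        "dual_neg": 100.0 * counts.dual_neg / total,
    }


def malignant_fraction(cancer: int, total_T: int) -> float:
    """Percentage of circulating T cells with the malignant phenotype."""
    if total_T <= 0:
        raise AssayError("total T-cell count must be positive")
    if not (0 <= cancer <= total_T):
        raise AssayError("cancer count must lie in [0, total]")
    return 100.0 * cancer / total_T


def dar_weighted_average(peaks: list[tuple[int, float]]) -> float:
    """Drug-to-antibody ratio: area-weighted mean over (drug_load, area) peaks."""
    if not peaks:
        raise AssayError("no chromatogram peaks")
    loads = np.array([p[0] for p in peaks], dtype=float)
    areas = np.array([p[1] for p in peaks], dtype=float)
    if (loads < 0).any() or (loads != np.round(loads)).any():
        raise AssayError("drug loads must be non-negative integers")
    if (areas < 0).any():
        raise AssayError("peak areas must be non-negative")
    total = areas.sum()
    if total <= 0:
        raise AssayError("total peak area must be positive")
    return float((loads * areas).sum() / total)


@dataclass(frozen=True)
class FourPLFit:
    """4PL parameters: y = bottom + (top - bottom) / (1 + (x/IC50)^hill)."""

    top: float
    bottom: float
    hill: float
    ic50: float
    sse: float = float("nan")

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise AssayError("IC50 must be positive")
        if self.top < self.bottom:
            raise AssayError("top must be >= bottom")

    def predict(self, doses) -> np.ndarray:
        return four_pl(np.asarray(doses, dtype=float),
                       self.top, self.bottom, self.hill, self.ic50)


def four_pl(x: np.ndarray, top: float, bottom: float, hill: float,
            ic50: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_4pl(doses, responses) -> FourPLFit:
    """Least-squares 4PL fit; IC50 is the dose at half-maximal response.

    Requires >= 5 positive dose levels spanning the transition.  Flat
    (response-free) data raise instead of returning a meaningless IC50.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 5:
        raise AssayError("need >= 5 (dose, response) pairs")
    if (x <= 0).any():
        raise AssayError("doses must be positive")
    span = float(np.ptp(y))
    scale = max(float(np.max(np.abs(y))), 1.0)
    if span < 1e-6 * scale:
        raise AssayError("no dose response: data are flat")

    top0, bottom0 = float(np.max(y)), float(np.min(y))
    # initial IC50: dose whose response is nearest the midpoint
    mid = 0.5 * (top0 + bottom0)
    ic50_0 = float(x[np.argmin(np.abs(y - mid))])

    def residual(theta):
        top, bottom, hill, log_ic50 = theta
        return four_pl(x, top, bottom, hill, 10.0 ** log_ic50) - y

    best = None
    for hill0 in (0.5, 1.0, 2.0, -1.0):
        try:
            sol = least_squares(
                residual, [top0, bottom0, hill0, np.log10(ic50_0)],
                method="lm", max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise AssayError("4PL fit failed to converge")
    sse, sol = best
    top, bottom, hill, log_ic50 = sol.x
    if top < bottom:  # canonicalize: flip orientation via the hill sign
        top, bottom, hill = bottom, top, -hill
    fitted = FourPLFit(top=top, bottom=bottom, hill=hill,
                       ic50=float(10.0 ** log_ic50), sse=sse)
    if fitted.top - fitted.bottom < 1e-6 * scale:
        raise AssayError("4PL fit degenerate: no transition detected")
    return fitted
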