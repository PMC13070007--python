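"""Confidence-bounded binding/enrichment scoring and backbone selection.

Each clone is scored from three molecule counts: input library, bound to
TRBC2+ cells, bound to TRBC1+ cells.  A 95% normal-approximation interval
``n +/- 2*sqrt(n)`` is attached to each count, and the ratios are biased
against false positives by taking the lower bound of the TRBC2+ count and
the upper bound of the TRBC1+ count:

* binding ratio   = lower(n_trbc2) / upper(n_trbc1)
* enrichment ratio = (lower(n_trbc2) / N_trbc2) / (n_input / N_input)

Ratios are min-max normalized to a 0-100 scale per library, and clones are
ranked; the default selection rule prefers clones that are high on *both*
normalized statistics (descending min of the two).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .reads import CloneCountTable


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class CountCI:
    """A count with its +/- 2*sqrt(n) normal-approximation bounds."""

    n: int
    lower: float
    upper: float


@dataclass
class ScoreConfig:
    """Knobs for the ratio definitions and selection rule.

    pseudocount
        Denominator floor (in reads) keeping ratios finite at zero counts.
    use_ci
        Apply the stringency bounds (lower bound on TRBC2+ counts, upper
        bound on TRBC1+ counts); off = plain point-estimate ratios.
    selection_rule
        ``max_min_of_normalized`` (both statistics high) or
        ``top_k_by_binding``.
    """

    pseudocount: float = 1.0
    use_ci: bool = True
    normalization: str = "minmax"
    selection_rule: str = "max_min_of_normalized"
    k: int = 5

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ScoringError("pseudocount must be > 0")
        if self.normalization != "minmax":
            raise ScoringError(f"unknown normalization {self.normalization!r}")
        if self.selection_rule not in ("max_min_of_normalized", "top_k_by_binding"):
            raise ScoringError(f"unknown selection rule {self.selection_rule!r}")


def count_ci(n: int) -> CountCI:
    """95% bounds ``n +/- 2*sqrt(n)``, lower floored at zero."""
    if n < 0:
        raise ScoringError("count must be non-negative")
    half = 2.0 * math.sqrt(n)
    return CountCI(n=n, lower=max(0.0, n - half), upper=n + half)


def _lower(n):
    n = np.asarray(n, dtype=float)
    return np.maximum(0.0, n - 2.0 * np.sqrt(n))


def _upper(n):
    n = np.asarray(n, dtype=float)
    return n + 2.0 * np.sqrt(n)


def binding_ratio(n_trbc2, n_trbc1, config: ScoreConfig | None = None):
    """TRBC2-bound over TRBC1-bound count ratio, stringency-biased.

    With ``use_ci`` the numerator is the lower bound of the TRBC2+ count and
    the denominator the upper bound of the TRBC1+ count, so noisy low counts
    cannot fake selectivity.  Accepts scalars or arrays.
    """
    config = config or ScoreConfig()
    n2 = np.asarray(n_trbc2, dtype=float)
    n1 = np.asarray(n_trbc1, dtype=float)
    if (n2 < 0).any() or (n1 < 0).any():
        raise ScoringError("counts must be non-negative")
    if config.use_ci:
        num, den = _lower(n2), _upper(n1)
    else:
        num, den = n2, n1
    out = num / np.maximum(den, config.pseudocount)
    return out.item() if out.ndim == 0 else out


def enrichment_ratio(
    n_trbc2, n_trbc2_total, n_input, n_input_total, config: ScoreConfig | None = None
):
    """Clone fraction in the TRBC2-bound pool over its input-library fraction.

    The stringency bound (lower) is applied to the clone's TRBC2+ count
    only; input counts and sample totals are point estimates.
    """
    config = config or ScoreConfig()
    n2 = np.asarray(n_trbc2, dtype=float)
    ni = np.asarray(n_input, dtype=float)
    if n_trbc2_total <= 0 or n_input_total <= 0:
        raise ScoringError("sample totals must be positive")
    if (n2 > n_trbc2_total).any() or (ni > n_input_total).any():
        raise ScoringError("clone count exceeds its sample total")
    num = (_lower(n2) if config.use_ci else n2) / n_trbc2_total
    den = np.maximum(ni, config.pseudocount) / n_input_total
    out = num / den
    return out.item() if out.ndim == 0 else out


def normalize_scores(ratios: Iterable[float]) -> np.ndarray:
    """Linear min-max map onto [0, 100]; an all-equal vector maps to all 0."""
    values = np.asarray(list(ratios), dtype=float)
    if values.size == 0:
        raise ScoringError("cannot normalize an empty set of ratios")
    if not np.isfinite(values).all():
        raise ScoringError("ratios must be finite")
    span = values.max() - values.min()
    if span == 0:
        return np.zeros_like(values)
    # divide before scaling so the maximum maps to exactly 100
    return np.clip((values - values.min()) / span, 0.0, 1.0) * 100.0


def score_clones(
    table: CloneCountTable, config: ScoreConfig | None = None
) -> pd.DataFrame:
    """Score every clone in a count table; returns a ranked DataFrame.

    Columns: n_input, n_trbc2, n_trbc1, binding_ratio, enrichment_ratio,
    binding_norm, enrichment_norm, rank (1 = best), indexed by clone_id.
    """
    config = config or ScoreConfig()
    ni = table.column("input_library").to_numpy()
    n2 = table.column("trbc2_bound").to_numpy()
    n1 = table.column("trbc1_bound").to_numpy()
    n2_total, ni_total = int(n2.sum()), int(ni.sum())
    scores = pd.DataFrame(
        {
            "n_input": ni,
            "n_trbc2": n2,
            "n_trbc1": n1,
            "binding_ratio": binding_ratio(n2, n1, config),
            "enrichment_ratio": enrichment_ratio(n2, n2_total, ni, ni_total, config),
        },
        index=table.counts.index,
    )
    scores.index.name = "clone_id"
    scores["binding_norm"] = normalize_scores(scores["binding_ratio"])
    scores["enrichment_norm"] = normalize_scores(scores["enrichment_ratio"])
    return rank_select(scores, config)[0]


def rank_select(
    scores: pd.DataFrame, config: ScoreConfig | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Order clones by the configured rule and return the top-k selection.

    Default rule: descending min(binding_norm, enrichment_norm) — a clone
    must be high on both statistics; ties break by descending binding_ratio,
    then lexicographic clone_id.
    """
    config = config or ScoreConfig()
    scores = scores.copy()
    scores.index.name = "clone_id"
    if config.selection_rule == "top_k_by_binding":
        primary = scores["binding_norm"]
    else:
        primary = np.minimum(scores["binding_norm"], scores["enrichment_norm"])
    order = scores.assign(_primary=primary).sort_values(
        by=["_primary", "binding_ratio", "clone_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    ranked = order.drop(columns="_primary")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    selected = list(ranked.index[: config.k])
    return ranked, selected
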