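"""Proteome-scale prediction and the turnover-correlation analysis.

Because the predictor needs only sequence, it scales to whole proteomes.
The turnover analysis asks whether proteins predicted to deamidate
quickly also turn over quickly in vivo: it correlates log10 experimental
protein half-life (minutes) against log10 predicted whole-protein
deamidation half-time (days), restricted to records with a positive
experimental half-life and a defined prediction. Pearson r is invariant
to the units (log-shift) of either axis, so the mixed units are
immaterial; the fit parameters are reported in base-10 log units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    DEFAULT_WEIGHTS,
    HalfLifeTable,
    ProteinPrediction,
    StructuralProfile,
    Weights,
    predict_protein,
)

__all__ = [
    "TurnoverRecord",
    "CorrelationResult",
    "BatchResult",
    "batch_predict",
    "turnover_correlation",
    "bin_log_halflives",
]

logger = logging.getLogger(__name__)

ProfileProvider = Callable[[str, str], StructuralProfile]


@dataclass(frozen=True)
class TurnoverRecord:
    protein_id: str
    experimental_half_life: float          # minutes; non-positive = unusable
    predicted_t50_protein: Optional[float]  # days; None = no scorable site


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of log10 half-life vs log10 predicted t50."""

    n: int
    r: float
    p_value: float
    slope: float
    intercept: float
    n_excluded_nonpositive: int
    n_excluded_nosites: int


@dataclass(frozen=True)
class BatchResult:
    predictions: tuple[ProteinPrediction, ...]
    failures: tuple[tuple[str, str], ...]  # (protein_id, reason)


def batch_predict(
    sequences: Sequence[tuple[str, str]],
    profile_provider: ProfileProvider,
    weights: Weights = DEFAULT_WEIGHTS,
    table: Optional[HalfLifeTable] = None,
    horizon: float = 2.0,
    threshold: Optional[float] = None,
) -> BatchResult:
    """Predict every sequence; per-sequence failures are logged and skipped.

    ``profile_provider(protein_id, sequence)`` supplies the structural
    profile (from files or a fallback predictor). Proteins without any
    internal Asn yield a prediction with ``t50_protein=None`` — a
    no-sites marker, not a failure.
    """
    if table is None:
        table = HalfLifeTable.default()
    predictions: list[ProteinPrediction] = []
    failures: list[tuple[str, str]] = []
    for protein_id, sequence in sequences:
        try:
            profile = profile_provider(protein_id, sequence)
            predictions.append(
                predict_protein(
                    sequence, protein_id, profile, weights, table, horizon, threshold
                )
            )
        except Exception as exc:  # keep the batch running
            logger.warning("skipping %s: %s", protein_id, exc)
            failures.append((protein_id, str(exc)))
    return BatchResult(predictions=tuple(predictions), failures=tuple(failures))


def turnover_correlation(records: Sequence[TurnoverRecord]) -> CorrelationResult:
    """Correlate log10 experimental half-life with log10 predicted t50.

    Records with non-positive experimental half-lives (in-vivo fits can
    return negative values) or without a defined prediction are excluded
    and counted, so n_input = n + n_excluded_nonpositive +
    n_excluded_nosites.
    """
    usable: list[TurnoverRecord] = []
    n_nonpos = n_nosites = 0
    for rec in records:
        if rec.predicted_t50_protein is None:
            n_nosites += 1
        elif rec.experimental_half_life <= 0:
            n_nonpos += 1
        else:
            usable.append(rec)
    if len(usable) < 3:
        raise ValueError(f"need at least 3 usable records, have {len(usable)}")
    x = np.log10([rec.experimental_half_life for rec in usable])
    y = np.log10([rec.predicted_t50_protein for rec in usable])
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        n=len(usable),
        r=float(r),
        p_value=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_excluded_nonpositive=n_nonpos,
        n_excluded_nosites=n_nosites,
    )


def bin_log_halflives(
    records: Sequence[TurnoverRecord], bin_width: float = 0.1
) -> list[tuple[float, int]]:
    """Optional visualisation export: counts per log10 half-life bin."""
    usable = [
        r.experimental_half_life
        for r in records
        if r.experimental_half_life > 0 and r.predicted_t50_protein is not None
    ]
    if not usable:
        return []
    logs = np.log10(usable)
    edges = np.floor(logs / bin_width).astype(int)
    out: dict[int, int] = {}
    for e in edges:
        out[e] = out.get(e, 0) + 1
    return [(k * bin_width, out[k]) for k in sorted(out)]
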