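"""Dataset curation, ROC machinery and weight training.

The model's two weights (helix, order) were fitted by repeated stratified
splitting of a literature-curated site dataset: for each split an
exhaustive grid search maximises the training-set AUROC of the model's
t50 scores (smaller t50 = more deamidation-prone = positive), and the
selected weights are averaged over splits. The test-set AUROC of the
full model is also compared against scoring by the dipeptide half-time
alone, tallying how often structure information helps.

Curation rules for experimental evidence records: only near-neutral pH
and temperatures up to 313 K are admitted (deamidation kinetics are
strongly pH- and temperature-dependent); natural-source samples of
unknown age are excluded; a site is positive when deamidation was
unequivocal and, where quantitative, conversion reached >= 50% with a
half-time < 100 days; negative when tested-and-absent or slower than
100 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .model import NEGATIVE, POSITIVE

__all__ = [
    "CurationConfig",
    "RawEvidenceRecord",
    "LabeledSite",
    "FeatureSite",
    "CurationResult",
    "curate_records",
    "ROCCurve",
    "build_roc",
    "compare_auc",
    "stratified_split",
    "TrainResult",
    "SplitResult",
    "grid_train",
    "threshold_at_fpr",
    "DEFAULT_GRID",
]

#: Default exhaustive grid for both weights: [0, 6] in steps of 0.01.
DEFAULT_GRID = (0.0, 6.0, 0.01)


@dataclass(frozen=True)
class CurationConfig:
    """Numeric operationalisation of the evidence-admission rules."""

    ph_min: float = 6.5          # "neutral or slightly basic"
    ph_max: float = 8.5
    temperature_max_k: float = 313.0
    positive_conversion_min: float = 50.0   # percent
    positive_half_time_max: float = 100.0   # days
    negative_half_time_min: float = 100.0   # days


@dataclass(frozen=True)
class RawEvidenceRecord:
    """One experimental report of (non-)deamidation at a specific Asn."""

    protein_id: str
    position: int
    n_plus_1: str
    ph: float
    temperature_k: float
    conversion_percent: Optional[float] = None
    half_time_days: Optional[float] = None
    deamidation_observed: Optional[bool] = None
    sample_age_known: bool = True
    source: str = ""

    def __post_init__(self) -> None:
        if (
            self.conversion_percent is None
            and self.half_time_days is None
            and self.deamidation_observed is None
        ):
            raise ValueError(
                f"{self.protein_id}:{self.position}: record carries no evidence "
                "(need conversion, half-time or an observed flag)"
            )


@dataclass(frozen=True)
class LabeledSite:
    protein_id: str
    position: int
    n_plus_1: str
    label: str  # POSITIVE | NEGATIVE


@dataclass(frozen=True)
class FeatureSite:
    """A labelled site with the model features attached (training format)."""

    protein_id: str
    position: int
    n_plus_1: str
    label: str
    helix: int
    disorder: float
    t50_sequence: float


@dataclass(frozen=True)
class CurationResult:
    """Labelled sites plus a per-record disposition log.

    Dispositions partition the input: every record is exactly one of
    positive, negative, or dropped (with a reason).
    """

    sites: tuple[LabeledSite, ...]
    dispositions: tuple[tuple[RawEvidenceRecord, str, str], ...]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, disposition, _ in self.dispositions:
            out[disposition] = out.get(disposition, 0) + 1
        return out


def curate_records(
    records: Sequence[RawEvidenceRecord], config: CurationConfig = CurationConfig()
) -> CurationResult:
    """Apply the admission and labelling rules to raw evidence records."""
    sites: list[LabeledSite] = []
    log: list[tuple[RawEvidenceRecord, str, str]] = []
    for rec in records:
        if not (config.ph_min <= rec.ph <= config.ph_max):
            log.append((rec, "dropped", f"pH {rec.ph} outside [{config.ph_min}, {config.ph_max}]"))
            continue
        if rec.temperature_k > config.temperature_max_k:
            log.append((rec, "dropped", f"temperature {rec.temperature_k} K > {config.temperature_max_k} K"))
            continue
        if not rec.sample_age_known:
            log.append((rec, "dropped", "natural-source sample of unknown age"))
            continue

        unequivocal = rec.deamidation_observed is True or (
            rec.conversion_percent is not None
            and rec.conversion_percent >= config.positive_conversion_min
        )
        quantitative_ok = (
            rec.conversion_percent is None
            or rec.conversion_percent >= config.positive_conversion_min
        ) and (
            rec.half_time_days is None
            or rec.half_time_days < config.positive_half_time_max
        )
        positive = unequivocal and quantitative_ok
        negative = rec.deamidation_observed is False or (
            rec.half_time_days is not None
            and rec.half_time_days > config.negative_half_time_min
        )

        if positive and negative:
            log.append((rec, "dropped", "contradictory evidence; flagged for manual review"))
        elif positive:
            sites.append(LabeledSite(rec.protein_id, rec.position, rec.n_plus_1, POSITIVE))
            log.append((rec, "positive", "unequivocal deamidation within the quantitative limits"))
        elif negative:
            sites.append(LabeledSite(rec.protein_id, rec.position, rec.n_plus_1, NEGATIVE))
            log.append((rec, "negative", "tested and absent, or half-time above the cutoff"))
        else:
            log.append((rec, "dropped", "evidence meets neither labelling criterion"))
    return CurationResult(sites=tuple(sites), dispositions=tuple(log))


# --------------------------------------------------------------------------
# ROC machinery. Orientation throughout: scores are half-times in days and
# *smaller* scores are more positive; a site is called positive at a
# threshold theta when t50 <= theta.
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    """Thresholds (in score units, call-positive-iff-score<=theta) with
    the corresponding (FPR, TPR) points and the trapezoidal AUC."""

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one positive and one negative label")
    return y


def build_roc(scores: Sequence[float], labels: Sequence[str]) -> ROCCurve:
    """ROC over all distinct thresholds of smaller-is-positive scores.

    Tied scores are grouped at a single threshold. AUC equals the
    Mann-Whitney probability that a random positive scores below a random
    negative (ties counting one half).
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    y = _as_binary(labels)
    fpr, tpr, thr = roc_curve(y, -s)          # negate: larger = more positive
    auc = float(roc_auc_score(y, -s))
    return ROCCurve(
        thresholds=tuple(float(-t) for t in thr),  # back to t50 units
        fpr=tuple(map(float, fpr)),
        tpr=tuple(map(float, tpr)),
        auc=auc,
    )


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # placement values of the DeLong decomposition, larger-is-positive
    pos = scores[y == 1]
    neg = scores[y == 0]
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    return cmp_.mean(axis=1), 1.0 - cmp_.mean(axis=0)


def compare_auc(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[str]
) -> float:
    """Two-sided p-value for the difference of two correlated AUCs.

    Uses the DeLong variance estimate for paired ROC curves (both score
    vectors are evaluated on the same labelled sites). Scores follow the
    smaller-is-positive convention. Identical score vectors give p = 1.
    """
    y = _as_binary(labels)
    a = -np.asarray(scores_a, dtype=float)
    b = -np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise ValueError("score vectors and labels must have equal length")
    v10_a, v01_a = _placements(a, y)
    v10_b, v01_b = _placements(b, y)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def stratified_split(
    dataset: Sequence, test_fraction: float, seed: int, label_of=lambda s: s.label
) -> tuple[list, list]:
    """Random split preserving the class balance within one site per class.

    Each class is shuffled independently under the seed and cut at
    round(n_class * test_fraction). Same seed, same split.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    by_class: dict[str, list[int]] = {}
    for i, site in enumerate(dataset):
        by_class.setdefault(label_of(site), []).append(i)
    if len(by_class) < 2:
        raise ValueError("need both classes to stratify")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        n_test = int(round(len(idx) * test_fraction))
        if n_test == 0 or n_test == len(idx):
            raise ValueError(f"class {label!r} too small to stratify at fraction {test_fraction}")
        rng.shuffle(idx)
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return [dataset[i] for i in sorted(train_idx)], [dataset[i] for i in sorted(test_idx)]


# --------------------------------------------------------------------------
# Grid training
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitResult:
    w_helix: float
    w_order: float
    train_auc: float
    test_auc: float
    test_auc_sequence_only: float


@dataclass(frozen=True)
class TrainResult:
    splits: tuple[SplitResult, ...]
    w_helix: float        # arithmetic mean over splits
    w_order: float
    wins: int             # splits where the full model beat sequence-only on test AUC

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def _grid_axis(grid: tuple[float, float, float]) -> np.ndarray:
    lo, hi, step = grid
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _auc_matrix(log_scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise AUC of smaller-is-positive score rows via midranks."""
    ranks = stats.rankdata(-log_scores, axis=1)
    m = int(y.sum())
    n = y.size - m
    return (ranks[:, y == 1].sum(axis=1) - m * (m + 1) / 2) / (m * n)


def grid_train(
    dataset: Sequence[FeatureSite],
    grid_helix: tuple[float, float, float] = DEFAULT_GRID,
    grid_order: tuple[float, float, float] = DEFAULT_GRID,
    n_splits: int = 100,
    test_fraction: float = 0.5,
    seed: int = 0,
) -> TrainResult:
    """Repeated-split exhaustive grid search for the protection weights.

    Per split: maximise training-set AUROC of log t50 = log t50(sequence)
    + wH*H + wO*(1-D) over the (wH, wO) grid; ties resolve to the
    lexicographically smallest pair. The selected weights are evaluated
    on the test set against sequence-only scoring (wH = wO = 0), and the
    final weights are the arithmetic means over splits.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    wh_axis = _grid_axis(grid_helix)
    wo_axis = _grid_axis(grid_order)
    if wh_axis.size == 0 or wo_axis.size == 0:
        raise ValueError("empty weight grid")
    # grid rows ordered lexicographically by (wH, wO): argmax -> smallest tie
    wh_flat = np.repeat(wh_axis, wo_axis.size)
    wo_flat = np.tile(wo_axis, wh_axis.size)

    split_seeds = np.random.SeedSequence(seed).generate_state(n_splits) % (2**31)
    results: list[SplitResult] = []
    for k in range(n_splits):
        train, test = stratified_split(dataset, test_fraction, int(split_seeds[k]))

        def features(part: Sequence[FeatureSite]):
            h = np.array([s.helix for s in part], dtype=float)
            o = np.array([1.0 - s.disorder for s in part], dtype=float)
            base = np.log(np.array([s.t50_sequence for s in part], dtype=float))
            y = _as_binary([s.label for s in part])
            return h, o, base, y

        h_tr, o_tr, base_tr, y_tr = features(train)
        scores = base_tr[None, :] + wh_flat[:, None] * h_tr[None, :] + wo_flat[:, None] * o_tr[None, :]
        aucs = _auc_matrix(scores, y_tr)
        best = int(np.argmax(aucs))
        wh, wo = float(wh_flat[best]), float(wo_flat[best])

        h_te, o_te, base_te, y_te = features(test)
        test_scores = np.vstack([base_te + wh * h_te + wo * o_te, base_te])
        test_auc, seq_auc = _auc_matrix(test_scores, y_te)
        results.append(
            SplitResult(
                w_helix=wh,
                w_order=wo,
                train_auc=float(aucs[best]),
                test_auc=float(test_auc),
                test_auc_sequence_only=float(seq_auc),
            )
        )
    return TrainResult(
        splits=tuple(results),
        w_helix=float(np.mean([r.w_helix for r in results])),
        w_order=float(np.mean([r.w_order for r in results])),
        wins=sum(r.test_auc > r.test_auc_sequence_only for r in results),
    )


def threshold_at_fpr(curve: ROCCurve, target_fpr: float) -> float:
    """Largest t50 threshold whose false-positive rate stays <= target.

    Conservative: the realised FPR never exceeds the target. When even
    the smallest data threshold overshoots, returns 0.0 days (no site
    called positive).
    """
    if not (0.0 <= target_fpr <= 1.0):
        raise ValueError(f"target FPR must lie in [0, 1], got {target_fpr}")
    if not curve.thresholds:
        raise ValueError("empty ROC curve")
    best = None
    for theta, fpr in zip(curve.thresholds, curve.fpr):
        if fpr <= target_fpr + 1e-12 and np.isfinite(theta):
            if best is None or theta > best:
                best = theta
    return 0.0 if best is None else float(best)
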