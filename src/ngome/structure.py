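"""Secondary-structure and disorder tracks for the deamidation model.

Two routes produce a :class:`~ngome.model.StructuralProfile`:

* **File ingestion** (the fidelity route): parse the horizontal H/E/C
  strings written by secondary-structure predictors and the 3-column
  per-residue tables (index, residue, score) written by disorder
  predictors. Reproducing published per-protein numbers requires the
  original predictor outputs supplied this way.
* **Bundled fallbacks** (the zero-dependency route): a deterministic
  window-averaged helix-propensity predictor and a FoldIndex-style
  charge/hydrophobicity disorder score. Both are pure functions of the
  sequence. Profiles built from them carry ``provenance="fallback"`` so
  downstream reports cannot be mistaken for predictor-backed ones.

Only helix protects in the model: strand (E) and coil (C) both map to
H = 0 when a profile is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .model import StructuralProfile, _validate_sequence

__all__ = [
    "SecondaryStructureTrack",
    "DisorderTrack",
    "parse_horizontal_ss",
    "write_horizontal_ss",
    "parse_ss_prediction",
    "parse_disorder_table",
    "fallback_helix",
    "fallback_disorder",
    "build_profile",
    "fallback_profile",
    "load_helix_propensities",
]

FALLBACK = "fallback"

#: Kyte-Doolittle hydrophobicity, rescaled to [0, 1] as used by FoldIndex.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: Default window-mean propensity above which the fallback calls helix.
DEFAULT_HELIX_CUTOFF = 1.10
DEFAULT_HELIX_WINDOW = 7
#: Disorder predictors integrate over a ~21-residue context window.
DEFAULT_DISORDER_WINDOW = 21
#: Logistic steepness mapping FoldIndex unfoldability to [0, 1].
DEFAULT_DISORDER_SLOPE = 6.0


@dataclass(frozen=True)
class SecondaryStructureTrack:
    """Per-residue states over {H, E, C} with a source tag."""

    states: str
    source: str = "file"

    def __post_init__(self) -> None:
        bad = set(self.states) - set("HEC")
        if bad:
            raise ValueError(f"secondary-structure states must be H/E/C, got {bad}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores in [0, 1] with a source tag."""

    scores: tuple[float, ...]
    source: str = "file"

    def __post_init__(self) -> None:
        for s in self.scores:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"disorder scores must lie in [0, 1], got {s}")

    def __len__(self) -> int:
        return len(self.scores)


def parse_horizontal_ss(text: str, source: str = "file") -> SecondaryStructureTrack:
    """Parse a horizontal H/E/C string; wrapped lines allowed, '-' read as C."""
    states = []
    pos = 0
    for ch in text:
        if ch.isspace():
            continue
        pos += 1
        if ch == "-":
            states.append("C")
        elif ch in "HEC":
            states.append(ch)
        else:
            raise ValueError(f"invalid secondary-structure character {ch!r} at position {pos}")
    return SecondaryStructureTrack(states="".join(states), source=source)


def write_horizontal_ss(track: SecondaryStructureTrack, width: int = 60) -> str:
    """Canonical horizontal form of a track (fixed-width wrapped lines)."""
    s = track.states
    return "\n".join(s[i : i + width] for i in range(0, len(s), width)) + "\n"


def parse_ss_prediction(text: str, key_hint: str = "pred") -> SecondaryStructureTrack:
    """Tolerant reader for the key:value dialect of common SS predictors.

    Accepts lines of the form ``name:H,H,E,C,-`` (comma-separated states);
    prefers the line whose key contains ``key_hint`` (e.g. ``jnetpred``),
    otherwise takes the first line whose values are all H/E/C/-.
    """
    candidates: list[tuple[str, str]] = []
    for raw in text.splitlines():
        if ":" not in raw:
            continue
        key, _, value = raw.partition(":")
        fields = [f.strip() for f in value.strip().rstrip(",").split(",")]
        if fields and all(f in ("H", "E", "C", "-") for f in fields):
            candidates.append((key.strip(), "".join(fields)))
    if not candidates:
        raise ValueError("no H/E/C state line found in prediction file")
    for key, states in candidates:
        if key_hint.lower() in key.lower():
            return parse_horizontal_ss(states, source=key)
    key, states = candidates[0]
    return parse_horizontal_ss(states, source=key)


def parse_disorder_table(
    text: str, sequence: Optional[str] = None, source: str = "file"
) -> DisorderTrack:
    """Parse a per-residue disorder table: ``index residue score`` rows.

    Rows may appear in any order but must be contiguous from 1. Scores
    outside [0, 1] are an error, never clamped. When ``sequence`` is
    given, the residue column is validated against it.
    """
    rows: dict[int, tuple[str, float]] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected 'index residue score'")
        idx = int(parts[0])
        res = parts[1].upper()
        score = float(parts[2])
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"line {lineno}: disorder score {score} outside [0, 1]")
        if idx in rows:
            raise ValueError(f"line {lineno}: duplicate index {idx}")
        rows[idx] = (res, score)
    if not rows:
        raise ValueError("empty disorder table")
    expected = set(range(1, len(rows) + 1))
    if set(rows) != expected:
        missing = sorted(expected - set(rows))[:3]
        raise ValueError(f"disorder table indices not contiguous from 1; missing {missing}")
    if sequence is not None:
        seq = sequence.upper()
        if len(seq) != len(rows):
            raise ValueError(
                f"disorder table length {len(rows)} does not match sequence length {len(seq)}"
            )
        for i in range(1, len(rows) + 1):
            if rows[i][0] != seq[i - 1]:
                raise ValueError(
                    f"residue mismatch at position {i}: table has {rows[i][0]!r}, "
                    f"sequence has {seq[i - 1]!r}"
                )
    scores = tuple(rows[i][1] for i in range(1, len(rows) + 1))
    return DisorderTrack(scores=scores, source=source)


def load_helix_propensities() -> dict[str, float]:
    """The packaged Chou-Fasman alpha-helix propensity table."""
    ref = resources.files("ngome.data").joinpath("helix_propensities.tsv")
    table: dict[str, float] = {}
    for raw in ref.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        res, value = line.split("\t")
        table[res] = float(value)
    return table


def _window_mean(values: list[float], center: int, half: int) -> float:
    # symmetric shrinkage at the termini: the window is truncated, not padded
    lo = max(0, center - half)
    hi = min(len(values), center + half + 1)
    return sum(values[lo:hi]) / (hi - lo)


def fallback_helix(
    sequence: str,
    window: int = DEFAULT_HELIX_WINDOW,
    cutoff: float = DEFAULT_HELIX_CUTOFF,
    propensities: Optional[dict[str, float]] = None,
) -> SecondaryStructureTrack:
    """Deterministic propensity-smoothing helix predictor.

    Averages per-residue alpha-helix propensities over a sliding window
    and calls H where the mean exceeds ``cutoff``. A coarse stand-in for
    alignment-based predictors, adequate for screening but not for
    reproducing published per-protein values; its output is tagged
    ``fallback``.
    """
    seq = _validate_sequence(sequence)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if propensities is None:
        propensities = load_helix_propensities()
    values = [propensities.get(aa, 1.0) for aa in seq]
    half = window // 2
    states = "".join(
        "H" if _window_mean(values, i, half) > cutoff else "C" for i in range(len(seq))
    )
    return SecondaryStructureTrack(states=states, source=FALLBACK)


def fallback_disorder(
    sequence: str,
    window: int = DEFAULT_DISORDER_WINDOW,
    slope: float = DEFAULT_DISORDER_SLOPE,
) -> DisorderTrack:
    """FoldIndex-style disorder score per residue.

    Unfoldability u = 2.785*<hydrophobicity> - |<net charge>| - 1.151 over
    a sliding window (Kyte-Doolittle hydrophobicity rescaled to [0, 1]);
    squashed to a disorder score D = 1/(1 + exp(slope*u)) so that u = 0
    maps to 0.5, positive u (foldable) to D < 0.5 and negative u to
    D > 0.5. Edge windows shrink symmetrically.
    """
    import math

    seq = _validate_sequence(sequence)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    hydro = [(_KD.get(aa, 0.0) + 4.5) / 9.0 for aa in seq]
    charge = [_CHARGE.get(aa, 0.0) for aa in seq]
    half = window // 2
    scores = []
    for i in range(len(seq)):
        u = 2.785 * _window_mean(hydro, i, half) - abs(_window_mean(charge, i, half)) - 1.151
        scores.append(1.0 / (1.0 + math.exp(slope * u)))
    return DisorderTrack(scores=tuple(scores), source=FALLBACK)


def build_profile(
    sequence: str,
    ss: SecondaryStructureTrack,
    dis: DisorderTrack,
    sequence_id: str = "",
) -> StructuralProfile:
    """Combine tracks into a profile: H = 1 only for helix (E maps to 0).

    Strand propensity was examined as a protecting feature but carries no
    weight in the model, so E and C are equivalent here.
    """
    seq = _validate_sequence(sequence)
    if len(ss) != len(seq):
        raise ValueError(
            f"secondary-structure track length {len(ss)} does not match "
            f"sequence length {len(seq)}"
        )
    if len(dis) != len(seq):
        raise ValueError(
            f"disorder track length {len(dis)} does not match sequence length {len(seq)}"
        )
    provenance = FALLBACK if FALLBACK in (ss.source, dis.source) else "parsed-external"
    return StructuralProfile(
        sequence_id=sequence_id,
        helix=tuple(1 if s == "H" else 0 for s in ss.states),
        disorder=dis.scores,
        provenance=provenance,
    )


def fallback_profile(sequence: str, sequence_id: str = "") -> StructuralProfile:
    """Profile from the two bundled fallback predictors."""
    return build_profile(
        sequence,
        fallback_helix(sequence),
        fallback_disorder(sequence),
        sequence_id=sequence_id,
    )
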