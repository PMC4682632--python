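"""Kinetic model of spontaneous asparagine deamidation.

Internal Asn residues deamidate through a succinimide intermediate whose
formation rate is set by the identity of the N+1 residue (the residue
immediately C-terminal to the Asn) and slowed by local structure. The
observed half-time is modelled as

    t50 = t50(sequence) * exp(wH * H + wO * (1 - D))

where ``t50(sequence)`` is the half-time of the Asn-(N+1) dipeptide in
unstructured model peptides, ``H`` is 1 when the Asn lies in a predicted
alpha helix, ``D`` is an intrinsic-disorder score in [0, 1] (1 = fully
disordered; used as a proxy for the absence of protecting hydrogen bonds),
and ``wH``, ``wO`` are non-negative empirical weights. The exponential
factor is the *protection factor* P = t50 / t50(sequence) >= 1.

Only internal Asn (positions 2..L-1, 1-based) are modelled: terminal
deamidation follows different chemistry. N-glycosylation sequons
(N[^P][ST]) are flagged, not suppressed, since occupancy cannot be known
from sequence alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "STANDARD_AA",
    "NONSTANDARD_AA",
    "Weights",
    "DEFAULT_WEIGHTS",
    "HalfLifeTable",
    "AsnSite",
    "StructuralProfile",
    "SitePrediction",
    "ProteinPrediction",
    "find_asn_sites",
    "is_sequon",
    "intrinsic_half_time",
    "protection_factor",
    "percent_deamidated",
    "protein_half_time",
    "classify_site",
    "predict_site",
    "predict_protein",
    "hypothetical_scan",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Accepted but never assigned an intrinsic half-time (ambiguity/rare codes).
NONSTANDARD_AA = "XBZUO"
_VALID_AA = frozenset(STANDARD_AA + NONSTANDARD_AA)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Weights:
    """Empirical protection weights of the deamidation model.

    ``helix`` (wH) scales the helix indicator, ``order`` (wO) scales local
    order 1 - D. Both are dimensionless and non-negative: structure can
    only slow deamidation.
    """

    helix: float = 0.571
    order: float = 2.989

    def __post_init__(self) -> None:
        if self.helix < 0 or self.order < 0:
            raise ValueError(
                f"weights must be non-negative, got wH={self.helix}, wO={self.order}"
            )


#: Published averages from the repeated-split training of the model.
DEFAULT_WEIGHTS = Weights(helix=0.571, order=2.989)


class HalfLifeTable:
    """Intrinsic deamidation half-times keyed by the N+1 residue.

    Values are half-times in days of the Asn-X dipeptide in unstructured
    model peptides. Glycine must be the fastest entry when present
    (smallest side chain, least steric hindrance of succinimide
    formation). Lookups of absent residues raise ``KeyError`` explicitly;
    they are never silently defaulted.
    """

    def __init__(self, entries: dict[str, float], source_label: str = "") -> None:
        if not entries:
            raise ValueError("half-life table is empty")
        for res, t50 in entries.items():
            if len(res) != 1 or res not in STANDARD_AA:
                raise ValueError(f"invalid residue code in table: {res!r}")
            if not (t50 > 0):
                raise ValueError(f"half-time for {res} must be > 0, got {t50}")
        if "G" in entries and entries["G"] != min(entries.values()):
            raise ValueError("Gly must have the minimum half-time in the table")
        self.entries = dict(entries)
        self.source_label = source_label

    def __contains__(self, residue: str) -> bool:
        return residue in self.entries

    def __getitem__(self, residue: str) -> float:
        try:
            return self.entries[residue]
        except KeyError:
            raise KeyError(
                f"no intrinsic half-time for N+1 residue {residue!r} "
                f"in table {self.source_label!r}"
            ) from None

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HalfLifeTable":
        """Read a 3-column TSV (residue, t50_days, source); '#' comments."""
        entries: dict[str, float] = {}
        sources: list[str] = []
        text = Path(path).read_text()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected residue<TAB>t50_days")
            res = parts[0].strip()
            t50 = float(parts[1])
            if res in entries:
                raise ValueError(f"{path}:{lineno}: duplicate residue {res!r}")
            entries[res] = t50
            if len(parts) > 2:
                sources.append(parts[2].strip())
        label = sources[0] if sources else str(path)
        return cls(entries, source_label=label)

    @classmethod
    def default(cls) -> "HalfLifeTable":
        """The packaged model-peptide table (see ``data/halftimes.tsv``)."""
        ref = resources.files("ngome.data").joinpath("halftimes.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class AsnSite:
    """An internal asparagine residue (1-based coordinates)."""

    protein_id: str
    position: int
    n_plus_1: str
    is_sequon: bool

    def __post_init__(self) -> None:
        if self.position < 2:
            raise ValueError(f"internal Asn position must be >= 2, got {self.position}")


@dataclass(frozen=True)
class StructuralProfile:
    """Per-residue helix flags and disorder scores aligned to a sequence.

    ``helix`` holds H in {0, 1}; ``disorder`` holds D in [0, 1].
    ``provenance`` records whether the tracks came from external predictor
    files ("parsed-external") or from the bundled fallbacks ("fallback").
    """

    sequence_id: str
    helix: tuple[int, ...]
    disorder: tuple[float, ...]
    provenance: str = "parsed-external"

    def __post_init__(self) -> None:
        if len(self.helix) != len(self.disorder):
            raise ValueError(
                f"track length mismatch: helix {len(self.helix)} vs "
                f"disorder {len(self.disorder)}"
            )
        for h in self.helix:
            if h not in (0, 1):
                raise ValueError(f"helix flags must be 0 or 1, got {h}")
        for d in self.disorder:
            if not (0.0 <= d <= 1.0):
                raise ValueError(f"disorder scores must lie in [0, 1], got {d}")

    def __len__(self) -> int:
        return len(self.helix)

    def at(self, position: int) -> tuple[int, float]:
        """(H, D) at a 1-based position."""
        if not (1 <= position <= len(self)):
            raise ValueError(
                f"position {position} outside profile of length {len(self)}"
            )
        return self.helix[position - 1], self.disorder[position - 1]


@dataclass(frozen=True)
class SitePrediction:
    """Model output for one (possibly hypothetical) Asn site.

    ``t50_sequence``/``t50_ngome`` are ``None`` when the N+1 residue has no
    table entry (Pro, non-standard codes); the site is still reported.
    ``native`` distinguishes real Asn from hypothetical-scan positions.
    """

    site: AsnSite
    t50_sequence: Optional[float]
    t50_ngome: Optional[float]
    protection: float
    percent_deamidated: Optional[float]
    label: Optional[str] = None
    native: bool = True

    def __post_init__(self) -> None:
        if self.protection < 1.0 - 1e-12:
            raise ValueError(f"protection factor must be >= 1, got {self.protection}")
        # < 100 mathematically; == 100 only by floating underflow at t >> t50
        if self.percent_deamidated is not None and not (
            0.0 <= self.percent_deamidated <= 100.0
        ):
            raise ValueError(
                f"percent deamidated must lie in [0, 100], got {self.percent_deamidated}"
            )


@dataclass(frozen=True)
class ProteinPrediction:
    """All site predictions for one protein plus the whole-protein half-time.

    ``t50_protein`` is the half-time of the *first* deamidation event under
    independent first-order site kinetics; ``None`` when no internal Asn
    with a defined half-time exists.
    """

    protein_id: str
    site_predictions: tuple[SitePrediction, ...] = field(default_factory=tuple)
    t50_protein: Optional[float] = None

    @property
    def has_sites(self) -> bool:
        return len(self.site_predictions) > 0


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    for i, aa in enumerate(seq, 1):
        if aa not in _VALID_AA:
            raise ValueError(f"invalid amino-acid character {aa!r} at position {i}")
    return seq


def is_sequon(sequence: str, position: int) -> bool:
    """True when the Asn at 1-based ``position`` sits in an N[^P][ST] motif."""
    seq = sequence.upper()
    if not (1 <= position <= len(seq)):
        raise ValueError(f"position {position} outside sequence of length {len(seq)}")
    if seq[position - 1] != "N":
        raise ValueError(f"residue at position {position} is {seq[position - 1]!r}, not N")
    if position + 2 > len(seq):
        return False
    return seq[position] != "P" and seq[position + 1] in "ST"


def find_asn_sites(sequence: str, protein_id: str = "") -> list[AsnSite]:
    """All internal Asn residues (positions 2..L-1), in ascending order.

    Terminal Asn are excluded: deamidation at the amino or carboxyl
    terminus proceeds through different mechanisms and is out of scope.
    """
    seq = _validate_sequence(sequence)
    sites = []
    for pos in range(2, len(seq)):  # 1-based internal positions
        if seq[pos - 1] == "N":
            sites.append(
                AsnSite(
                    protein_id=protein_id,
                    position=pos,
                    n_plus_1=seq[pos],
                    is_sequon=is_sequon(seq, pos),
                )
            )
    return sites


def intrinsic_half_time(site: AsnSite, table: HalfLifeTable) -> float:
    """Dipeptide half-time t50(sequence) for the site's N+1 residue, in days."""
    return table[site.n_plus_1]


def protection_factor(h: int, d: float, weights: Weights = DEFAULT_WEIGHTS) -> float:
    """exp(wH*H + wO*(1-D)): fold slow-down imposed by local structure.

    Equals 1 (no protection) for a fully disordered coil (H=0, D=1).
    """
    if h not in (0, 1):
        raise ValueError(f"helix flag must be 0 or 1, got {h}")
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"disorder score must lie in [0, 1], got {d}")
    return math.exp(weights.helix * h + weights.order * (1.0 - d))


def percent_deamidated(t50: float, t: float) -> float:
    """Percent converted after ``t`` days of first-order decay: 100*(1 - 2^(-t/t50))."""
    if not (t50 > 0):
        raise ValueError(f"t50 must be > 0, got {t50}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return 100.0 * (1.0 - 2.0 ** (-t / t50))


def protein_half_time(site_t50s: Sequence[float]) -> Optional[float]:
    """Half-time of the first deamidation event among independent sites.

    Independent first-order clocks add rates: 1 / sum(1/t50_i). Returns
    ``None`` for an empty list (no internal Asn — distinct from an error).
    """
    if len(site_t50s) == 0:
        return None
    for t50 in site_t50s:
        if not (t50 > 0):
            raise ValueError(f"site half-times must be > 0, got {t50}")
    return 1.0 / sum(1.0 / t50 for t50 in site_t50s)


def classify_site(t50_ngome: float, threshold: float) -> str:
    """'positive' iff t50 <= threshold (tie counts positive: a degradation
    screen errs on the side of flagging)."""
    if not (threshold > 0):
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return POSITIVE if t50_ngome <= threshold else NEGATIVE


def predict_site(
    site: AsnSite,
    profile: StructuralProfile,
    weights: Weights = DEFAULT_WEIGHTS,
    table: Optional[HalfLifeTable] = None,
    horizon: float = 2.0,
    threshold: Optional[float] = None,
    native: bool = True,
) -> SitePrediction:
    """Evaluate the deamidation model at one site.

    The protection factor uses the H and D tracks at the Asn's own
    position. ``horizon`` is the time (days) for the percent-deamidated
    figure; ``threshold`` (days), when given, yields a positive/negative
    label. An N+1 residue missing from the table produces a prediction
    with ``t50_sequence``/``t50_ngome`` of ``None`` rather than an error.
    """
    if table is None:
        table = HalfLifeTable.default()
    h, d = profile.at(site.position)
    p = protection_factor(h, d, weights)
    if site.n_plus_1 in table:
        t50_seq = table[site.n_plus_1]
        t50 = t50_seq * p
        pct = percent_deamidated(t50, horizon)
        label = classify_site(t50, threshold) if threshold is not None else None
    else:
        t50_seq = t50 = pct = label = None
    return SitePrediction(
        site=site,
        t50_sequence=t50_seq,
        t50_ngome=t50,
        protection=p,
        percent_deamidated=pct,
        label=label,
        native=native,
    )


def predict_protein(
    sequence: str,
    protein_id: str = "",
    profile: Optional[StructuralProfile] = None,
    weights: Weights = DEFAULT_WEIGHTS,
    table: Optional[HalfLifeTable] = None,
    horizon: float = 2.0,
    threshold: Optional[float] = None,
) -> ProteinPrediction:
    """Predict every internal Asn of a protein and the whole-protein t50.

    Sites whose N+1 residue has no table entry contribute no rate to the
    protein half-time (their individual rows still appear, t50 missing).
    """
    seq = _validate_sequence(sequence)
    if profile is None:
        raise ValueError("a StructuralProfile is required")
    if len(profile) != len(seq):
        raise ValueError(
            f"profile length {len(profile)} does not match sequence length {len(seq)}"
        )
    if table is None:
        table = HalfLifeTable.default()
    preds = tuple(
        predict_site(s, profile, weights, table, horizon, threshold)
        for s in find_asn_sites(seq, protein_id)
    )
    defined = [p.t50_ngome for p in preds if p.t50_ngome is not None]
    return ProteinPrediction(
        protein_id=protein_id,
        site_predictions=preds,
        t50_protein=protein_half_time(defined),
    )


def hypothetical_scan(
    sequence: str,
    profile: StructuralProfile,
    weights: Weights = DEFAULT_WEIGHTS,
    table: Optional[HalfLifeTable] = None,
    horizon: float = 2.0,
    threshold: Optional[float] = None,
    protein_id: str = "",
) -> list[SitePrediction]:
    """Predict every internal position as if it held an asparagine.

    Mimics a point-mutation screen: the wild-type H and D tracks are kept
    (structure predictions are robust to a single substitution) and the
    actual residue at position+1 serves as the N+1 residue. Positions that
    already hold Asn are flagged ``native=True`` and reproduce
    ``predict_site`` exactly.
    """
    seq = _validate_sequence(sequence)
    if len(profile) != len(seq):
        raise ValueError(
            f"profile length {len(profile)} does not match sequence length {len(seq)}"
        )
    if table is None:
        table = HalfLifeTable.default()
    out = []
    for pos in range(2, len(seq)):
        mutant = seq[: pos - 1] + "N" + seq[pos:]
        site = AsnSite(
            protein_id=protein_id,
            position=pos,
            n_plus_1=seq[pos],
            is_sequon=is_sequon(mutant, pos),
        )
        out.append(
            predict_site(
                site, profile, weights, table, horizon, threshold,
                native=(seq[pos - 1] == "N"),
            )
        )
    return out
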