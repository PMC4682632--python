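"""Synthetic fixture generation for testing and calibration studies.

The generator plants internal Asn sites inside sequence regions of
controlled structural context and emits everything a full analysis
needs: sequences (FASTA), matched helix/disorder tracks, and a labelled
site table. Labels follow the kinetic model itself — a site is positive
when its model t50 falls below a cutoff — optionally corrupted by label
noise, which makes the fixture suitable for weight-recovery studies:
training on it should return the planted weights.

Contexts
--------
``disordered-coil``  H = 0, D ~ U(0.7, 1)   (essentially unprotected)
``ordered-helix``    H = 1, D ~ U(0, 0.3)   (maximally protected)
``ordered-coil``     H = 0, D ~ U(0, 0.3)   (order protection only)

Everything is driven by one integer seed; regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .evaluation import FeatureSite
from .model import (
    DEFAULT_WEIGHTS,
    HalfLifeTable,
    NEGATIVE,
    POSITIVE,
    StructuralProfile,
    Weights,
    protection_factor,
)
from . import io as ngio
from .structure import write_horizontal_ss, SecondaryStructureTrack

__all__ = [
    "SiteAnnotation",
    "SyntheticFixture",
    "generate_fixture",
    "generate_turnover_records",
    "DEFAULT_CONTEXT_MIX",
]

CONTEXTS = ("disordered-coil", "ordered-helix", "ordered-coil")
#: Helix-enriched mix: helix sites are the only carriers of information
#: about the helix weight, so they get the largest share.
DEFAULT_CONTEXT_MIX = {
    "disordered-coil": 0.35,
    "ordered-helix": 0.40,
    "ordered-coil": 0.25,
}
_D_RANGES = {
    "disordered-coil": (0.7, 1.0),
    "ordered-helix": (0.0, 0.3),
    "ordered-coil": (0.0, 0.3),
}
_H_FLAG = {"disordered-coil": 0, "ordered-helix": 1, "ordered-coil": 0}

#: Background alphabet excludes Asn so every Asn site is a planted one.
_BACKGROUND = "ACDEFGHIKLMQRVWY"  # also excludes P/S/T to keep sequons controlled

#: Context-conditional N+1 pools (see generate_fixture docstring): residues
#: whose intrinsic half-time puts the label boundary inside the context's
#: (1-D) band at the default cutoff, plus clear-class anchors.
DEFAULT_N_PLUS_1_BY_CONTEXT = {
    "disordered-coil": ("F", "N", "Q", "M", "Y", "W", "G", "A"),
    "ordered-helix": ("H", "S", "G"),
    "ordered-coil": ("A", "G", "W"),
}


@dataclass(frozen=True)
class SiteAnnotation:
    sequence_id: str
    position: int
    n_plus_1: str
    context: str
    helix: int
    disorder: float
    t50_days: float
    label: str
    flipped: bool  # noise flip applied to the model-derived label


@dataclass(frozen=True)
class SyntheticFixture:
    sequences: tuple[tuple[str, str], ...]
    helix_tracks: dict[str, str]            # H/C strings per sequence id
    disorder_tracks: dict[str, tuple[float, ...]]
    sites: tuple[SiteAnnotation, ...]
    weights: Weights
    cutoff_days: float
    label_noise: float
    seed: int
    params: dict = field(default_factory=dict)

    def profiles(self) -> dict[str, StructuralProfile]:
        return {
            sid: StructuralProfile(
                sequence_id=sid,
                helix=tuple(1 if s == "H" else 0 for s in self.helix_tracks[sid]),
                disorder=self.disorder_tracks[sid],
                provenance="parsed-external",
            )
            for sid, _ in self.sequences
        }

    def feature_sites(self, table: HalfLifeTable) -> list[FeatureSite]:
        """The fixture as a feature-complete training dataset."""
        return [
            FeatureSite(
                protein_id=s.sequence_id, position=s.position, n_plus_1=s.n_plus_1,
                label=s.label, helix=s.helix, disorder=s.disorder,
                t50_sequence=table[s.n_plus_1],
            )
            for s in self.sites
        ]

    def is_self_consistent(self, table: HalfLifeTable) -> bool:
        """Labels must be recomputable from the emitted tracks (+ flips)."""
        seqs = dict(self.sequences)
        for s in self.sites:
            seq = seqs[s.sequence_id]
            if seq[s.position - 1] != "N" or seq[s.position] != s.n_plus_1:
                return False
            h = 1 if self.helix_tracks[s.sequence_id][s.position - 1] == "H" else 0
            d = self.disorder_tracks[s.sequence_id][s.position - 1]
            if h != s.helix or abs(d - s.disorder) > 1e-12:
                return False
            t50 = table[s.n_plus_1] * protection_factor(h, d, self.weights)
            if abs(t50 - s.t50_days) > 1e-9 * s.t50_days:
                return False
            model_label = POSITIVE if t50 <= self.cutoff_days else NEGATIVE
            expected = (
                {POSITIVE: NEGATIVE, NEGATIVE: POSITIVE}[model_label]
                if s.flipped else model_label
            )
            if s.label != expected:
                return False
        return True

    def write(self, out_dir: str | Path, table: HalfLifeTable) -> dict[str, Path]:
        """Write FASTA + per-sequence track files + the labelled-site TSV."""
        out = Path(out_dir)
        tracks = out / "tracks"
        tracks.mkdir(parents=True, exist_ok=True)
        fasta = out / "sequences.fasta"
        ngio.write_fasta(self.sequences, fasta)
        for sid, _ in self.sequences:
            (tracks / f"{sid}.ss").write_text(
                write_horizontal_ss(SecondaryStructureTrack(self.helix_tracks[sid], "synthetic"))
            )
            seq = dict(self.sequences)[sid]
            with open(tracks / f"{sid}.diso", "w") as fh:
                fh.write("# index residue score\n")
                for i, (aa, d) in enumerate(zip(seq, self.disorder_tracks[sid]), 1):
                    fh.write(f"{i} {aa} {d:.6f}\n")
        sites_tsv = out / "sites.tsv"
        ngio.write_feature_table(self.feature_sites(table), sites_tsv)
        return {"fasta": fasta, "tracks": tracks, "sites": sites_tsv}


def _plant_positions(rng: np.random.Generator, length: int, n_sites: int,
                     min_gap: int = 6) -> list[int]:
    # 1-based Asn positions, internal with room for the N+1 and context window
    candidates = list(range(4, length - 2))
    positions: list[int] = []
    rng.shuffle(candidates)
    for pos in candidates:
        if all(abs(pos - p) >= min_gap for p in positions):
            positions.append(pos)
            if len(positions) == n_sites:
                break
    if len(positions) < n_sites:
        raise ValueError(
            f"cannot place {n_sites} sites with gap {min_gap} in length {length}"
        )
    return sorted(positions)


def generate_fixture(
    n_sequences: int = 40,
    length: int = 120,
    sites_per_sequence: int = 4,
    context_mix: Optional[dict[str, float]] = None,
    label_noise: float = 0.05,
    weights: Weights = Weights(helix=1.0, order=3.0),
    table: Optional[HalfLifeTable] = None,
    cutoff_days: float = 245.0,
    n_plus_1_choices: Sequence[str] | dict[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> SyntheticFixture:
    """Generate a deterministic labelled fixture with planted Asn sites.

    The default composition is chosen so that both protection weights are
    identifiable from rank (AUROC) data alone. Weights enter the label
    rule only through log t50 = log t50(sequence) + wH*H + wO*(1-D), so a
    weight is pinned down exactly when context x N+1 cells *straddle* the
    label cutoff — contain both positives and negatives, with the decision
    boundary inside the cell's (1-D) band. Cells that never change class
    contribute no boundary information; in the spirit of optimal
    experimental design, the default N+1 distribution is therefore
    conditioned on context so that most sites land in straddling cells.
    With the default half-time table, planted weights (1, 3) and cutoff
    245 days (log 245 ~ 5.5): disordered-coil cells with N+1 in
    {F, N, Q, M, Y, W} straddle and interleave to pin the order weight;
    ordered-helix cells {H, S} and the ordered-coil cell {A} straddle to
    pin the helix weight; G, A, W anchor the clear-positive and
    clear-negative extremes. ``n_plus_1_choices`` accepts either one
    residue pool for all contexts or a per-context mapping. Label noise
    (default 5%) flips labels independently of features.
    """
    if table is None:
        table = HalfLifeTable.default()
    mix = dict(DEFAULT_CONTEXT_MIX if context_mix is None else context_mix)
    if set(mix) - set(CONTEXTS):
        raise ValueError(f"unknown contexts: {set(mix) - set(CONTEXTS)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"context fractions must sum to 1, got {total}")
    if not (0.0 <= label_noise < 0.5):
        raise ValueError(f"label_noise must lie in [0, 0.5), got {label_noise}")
    if n_plus_1_choices is None:
        choices_by_context = dict(DEFAULT_N_PLUS_1_BY_CONTEXT)
    elif isinstance(n_plus_1_choices, dict):
        missing = set(CONTEXTS) - set(n_plus_1_choices)
        if missing:
            raise ValueError(f"n_plus_1_choices lacks contexts: {missing}")
        choices_by_context = {c: tuple(v) for c, v in n_plus_1_choices.items()}
    else:
        choices_by_context = {c: tuple(n_plus_1_choices) for c in CONTEXTS}
    for pool in choices_by_context.values():
        for res in pool:
            if res not in table:
                raise ValueError(f"N+1 choice {res!r} missing from the half-time table")

    rng = np.random.default_rng(seed)
    context_names = [c for c in CONTEXTS if mix.get(c, 0.0) > 0]
    context_p = np.array([mix[c] for c in context_names])
    context_p = context_p / context_p.sum()

    sequences: list[tuple[str, str]] = []
    helix_tracks: dict[str, str] = {}
    disorder_tracks: dict[str, tuple[float, ...]] = {}
    annotations: list[SiteAnnotation] = []
    for i in range(n_sequences):
        sid = f"syn{i:04d}"
        residues = list(rng.choice(list(_BACKGROUND), size=length))
        helix = np.zeros(length, dtype=int)
        disorder = rng.uniform(0.0, 1.0, size=length)
        for pos in _plant_positions(rng, length, sites_per_sequence):
            context = str(rng.choice(context_names, p=context_p))
            n1 = str(rng.choice(list(choices_by_context[context])))
            residues[pos - 1] = "N"
            residues[pos] = n1
            lo, hi = _D_RANGES[context]
            d_site = float(rng.uniform(lo, hi))
            h_site = _H_FLAG[context]
            w_lo, w_hi = max(0, pos - 3), min(length, pos + 2)  # 5-residue window
            helix[w_lo:w_hi] = h_site
            disorder[w_lo:w_hi] = d_site
            t50 = table[n1] * protection_factor(h_site, d_site, weights)
            model_label = POSITIVE if t50 <= cutoff_days else NEGATIVE
            flipped = bool(rng.random() < label_noise)
            label = (
                {POSITIVE: NEGATIVE, NEGATIVE: POSITIVE}[model_label]
                if flipped else model_label
            )
            annotations.append(
                SiteAnnotation(
                    sequence_id=sid, position=pos, n_plus_1=n1, context=context,
                    helix=h_site, disorder=d_site, t50_days=t50,
                    label=label, flipped=flipped,
                )
            )
        sequences.append((sid, "".join(residues)))
        helix_tracks[sid] = "".join("H" if h else "C" for h in helix)
        disorder_tracks[sid] = tuple(round(float(d), 6) for d in disorder)

    # disorder values were rounded for clean track files; keep annotations aligned
    def _realign(a: SiteAnnotation) -> SiteAnnotation:
        d = disorder_tracks[a.sequence_id][a.position - 1]
        t50 = table[a.n_plus_1] * protection_factor(a.helix, d, weights)
        model_label = POSITIVE if t50 <= cutoff_days else NEGATIVE
        label = (
            {POSITIVE: NEGATIVE, NEGATIVE: POSITIVE}[model_label]
            if a.flipped else model_label
        )
        return SiteAnnotation(
            sequence_id=a.sequence_id, position=a.position, n_plus_1=a.n_plus_1,
            context=a.context, helix=a.helix, disorder=d, t50_days=t50,
            label=label, flipped=a.flipped,
        )

    annotations = [_realign(a) for a in annotations]
    return SyntheticFixture(
        sequences=tuple(sequences),
        helix_tracks=helix_tracks,
        disorder_tracks=disorder_tracks,
        sites=tuple(annotations),
        weights=weights,
        cutoff_days=cutoff_days,
        label_noise=label_noise,
        seed=seed,
        params={
            "n_sequences": n_sequences,
            "length": length,
            "sites_per_sequence": sites_per_sequence,
            "context_mix": mix,
            "n_plus_1_choices": choices_by_context,
        },
    )


def generate_turnover_records(
    n: int = 3750,
    true_r: float = 0.2,
    seed: int = 0,
    mean_log10_halflife_min: float = 1.7,
    sd_log10_halflife: float = 0.6,
    mean_log10_t50_days: float = 2.0,
    sd_log10_t50: float = 0.5,
):
    """Bivariate log-normal turnover fixture with a known correlation.

    Emulates a proteome-scale comparison of in-vivo protein half-lives
    (minutes, centred near ~50 min for exponential growth) against
    predicted whole-protein deamidation half-times (days): both are
    log-normal, weakly correlated with Pearson r = ``true_r`` on the
    log10 scale. Returned as :class:`~ngome.proteome.TurnoverRecord`
    objects ready for :func:`~ngome.proteome.turnover_correlation`.
    """
    from .proteome import TurnoverRecord

    if not (-1.0 < true_r < 1.0):
        raise ValueError(f"true_r must lie in (-1, 1), got {true_r}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    y = true_r * x + math.sqrt(1.0 - true_r**2) * eps
    halflife = 10.0 ** (mean_log10_halflife_min + sd_log10_halflife * x)
    t50 = 10.0 ** (mean_log10_t50_days + sd_log10_t50 * y)
    return [
        TurnoverRecord(
            protein_id=f"yft{i:04d}",
            experimental_half_life=float(halflife[i]),
            predicted_t50_protein=float(t50[i]),
        )
        for i in range(n)
    ]
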