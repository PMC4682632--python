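"""FASTA ingestion, report tables and the TSV dialects of the package.

Reports mirror a four-table layout: tables 1/2 list the real Asn sites
sorted by position and by predicted t50 respectively; tables 3/4 repeat
the layout for the hypothetical per-position scan. Two track files carry
the per-position log10 t50 values and protection factors (the data
behind position-wise figures). Half-times are printed with 3 significant
figures; a companion ``*_exact`` column keeps full precision.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from pathlib import Path
from typing import Optional, Sequence, TextIO

from Bio import SeqIO

from .evaluation import FeatureSite, RawEvidenceRecord
from .model import ProteinPrediction, SitePrediction

__all__ = [
    "read_fasta",
    "write_fasta",
    "render_reports",
    "site_rows",
    "read_feature_table",
    "write_feature_table",
    "read_evidence_table",
    "read_halflife_table",
]

SITE_COLUMNS = [
    "protein_id", "position", "n_plus_1", "sequon",
    "t50_sequence", "t50_ngome", "protection", "pct_at_horizon", "label",
    "t50_sequence_exact", "t50_ngome_exact", "native",
]

FEATURE_COLUMNS = ["protein_id", "position", "n_plus_1", "label", "H", "D", "t50_sequence"]


def read_fasta(source: str | Path | TextIO) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA into (id, sequence) pairs.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased; '*' stop characters are stripped with a warning.
    Duplicate ids and empty records are errors.
    """
    handle = source if hasattr(source, "read") else _io.StringIO(Path(source).read_text())
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(handle, "fasta"):
        seq_id = record.id
        seq = str(record.seq).upper()
        if "*" in seq:
            warnings.warn(f"stripping '*' stop characters from {seq_id}")
            seq = seq.replace("*", "")
        if not seq:
            raise ValueError(f"empty sequence record {seq_id!r}")
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        out.append((seq_id, seq))
    if not out:
        raise ValueError("no FASTA records found")
    return out


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _fmt(value: Optional[float], sig: int = 3) -> str:
    if value is None:
        return "NA"
    return f"{value:.{sig}g}"


def _fmt_exact(value: Optional[float]) -> str:
    return "NA" if value is None else repr(float(value))


def site_rows(predictions: Sequence[SitePrediction]) -> list[list[str]]:
    """Serialise site predictions into the standard per-site TSV rows."""
    rows = []
    for p in predictions:
        rows.append([
            p.site.protein_id,
            str(p.site.position),
            p.site.n_plus_1,
            "yes" if p.site.is_sequon else "no",
            _fmt(p.t50_sequence),
            _fmt(p.t50_ngome),
            _fmt(p.protection),
            _fmt(p.percent_deamidated),
            p.label if p.label is not None else "NA",
            _fmt_exact(p.t50_sequence),
            _fmt_exact(p.t50_ngome),
            "yes" if p.native else "no",
        ])
    return rows


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _by_t50(predictions: Sequence[SitePrediction]) -> list[SitePrediction]:
    # missing half-times sort last; position breaks ties deterministically
    return sorted(
        predictions,
        key=lambda p: (p.t50_ngome is None, p.t50_ngome, p.site.position),
    )


def render_reports(
    prediction: ProteinPrediction,
    scan: Sequence[SitePrediction],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the four report tables and two track files for one protein.

    Tables 1 and 2 (and 3 and 4) contain identical row sets in different
    orders. Track values derive from the hypothetical scan, with native
    Asn positions marked.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = prediction.protein_id
    sites = list(prediction.site_predictions)
    paths = {
        "table1": out / f"{pid}_table1_asn_by_position.tsv",
        "table2": out / f"{pid}_table2_asn_by_t50.tsv",
        "table3": out / f"{pid}_table3_scan_by_position.tsv",
        "table4": out / f"{pid}_table4_scan_by_t50.tsv",
        "track_t50": out / f"{pid}_track_t50.tsv",
        "track_protection": out / f"{pid}_track_protection.tsv",
    }
    _write_tsv(paths["table1"], SITE_COLUMNS, site_rows(sites))
    _write_tsv(paths["table2"], SITE_COLUMNS, site_rows(_by_t50(sites)))
    _write_tsv(paths["table3"], SITE_COLUMNS, site_rows(scan))
    _write_tsv(paths["table4"], SITE_COLUMNS, site_rows(_by_t50(list(scan))))

    t50_rows, prot_rows = [], []
    for p in scan:
        native = "yes" if p.native else "no"
        t50_rows.append([
            str(p.site.position),
            _fmt(math.log10(p.t50_ngome)) if p.t50_ngome is not None else "NA",
            _fmt(math.log10(p.t50_sequence)) if p.t50_sequence is not None else "NA",
            native,
        ])
        prot_rows.append([str(p.site.position), _fmt(p.protection), native])
    _write_tsv(paths["track_t50"],
               ["position", "log10_t50_ngome", "log10_t50_sequence", "native_asn"], t50_rows)
    _write_tsv(paths["track_protection"], ["position", "protection", "native_asn"], prot_rows)
    return paths


# --------------------------------------------------------------------------
# Training / curation / proteome TSV dialects
# --------------------------------------------------------------------------


def write_feature_table(sites: Sequence[FeatureSite], path: str | Path) -> None:
    rows = [
        [s.protein_id, str(s.position), s.n_plus_1, s.label,
         str(s.helix), repr(float(s.disorder)), repr(float(s.t50_sequence))]
        for s in sites
    ]
    _write_tsv(Path(path), FEATURE_COLUMNS, rows)


def read_feature_table(path: str | Path) -> list[FeatureSite]:
    """Read the feature-complete training table (see FEATURE_COLUMNS)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty feature table")
    header = lines[0].rstrip("\n").split("\t")
    if header != FEATURE_COLUMNS:
        raise ValueError(f"{path}: unexpected header {header}")
    sites = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != len(FEATURE_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected {len(FEATURE_COLUMNS)} columns")
        sites.append(
            FeatureSite(
                protein_id=f[0], position=int(f[1]), n_plus_1=f[2], label=f[3],
                helix=int(f[4]), disorder=float(f[5]), t50_sequence=float(f[6]),
            )
        )
    return sites


def _opt_float(field: str) -> Optional[float]:
    return None if field in ("", "NA") else float(field)


def read_evidence_table(path: str | Path) -> list[RawEvidenceRecord]:
    """Read a raw-evidence TSV: protein_id, position, n_plus_1, ph,
    temperature_k, conversion_percent, half_time_days,
    deamidation_observed (yes/no/NA), sample_age_known (yes/no), source."""
    records = []
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip() or line.startswith("#") or line.startswith("protein_id\t"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ValueError(f"{path}:{lineno}: expected at least 9 columns")
        observed = {"yes": True, "no": False, "NA": None, "": None}[f[7]]
        records.append(
            RawEvidenceRecord(
                protein_id=f[0], position=int(f[1]), n_plus_1=f[2],
                ph=float(f[3]), temperature_k=float(f[4]),
                conversion_percent=_opt_float(f[5]),
                half_time_days=_opt_float(f[6]),
                deamidation_observed=observed,
                sample_age_known=f[8] == "yes",
                source=f[9] if len(f) > 9 else "",
            )
        )
    return records


def read_halflife_table(path: str | Path) -> dict[str, float]:
    """Two-column experimental half-life TSV: protein_id, half_life_minutes."""
    out: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("protein_id\t"):
            continue
        f = line.split("\t")
        if len(f) < 2:
            raise ValueError(f"{path}:{lineno}: expected protein_id<TAB>half_life_minutes")
        if f[0] in out:
            raise ValueError(f"{path}:{lineno}: duplicate protein id {f[0]!r}")
        out[f[0]] = float(f[1])
    return out
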