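"""I/O for proteomes, observation tables, transition lists and libraries.

All tabular formats are plain CSV with a required header row. Lines
starting with ``#`` are treated as comments (output files carry a
provenance header written this way). FASTA is read through Bio.SeqIO;
the accession is the header token before the first whitespace and the
description is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import CANONICAL_RESIDUES

logger = logging.getLogger(__name__)


class Category(str, Enum):
    """Taxon category of a background/target proteome."""

    TARGET = "target"
    RELATED_OHRB = "related_ohrb"  # related organohalide-respiring bacteria
    OTHER = "other"


@dataclass
class Proteome:
    """A labeled collection of protein sequences.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"Dhc195"``.
    taxon_name : str
        Organism name.
    category : Category
        ``target`` for the assayed organism, ``related_ohrb`` for other
        organohalide-respiring bacteria, ``other`` for everything else.
    proteins : list of (accession, sequence)
        Uppercase amino-acid sequences, canonical residues only.
    """

    id: str
    taxon_name: str
    category: Category
    proteins: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.category = Category(self.category)
        seen: set[str] = set()
        for acc, _ in self.proteins:
            if acc in seen:
                raise ValueError(f"duplicate accession {acc!r} in proteome {self.id!r}")
            seen.add(acc)

    def __len__(self) -> int:
        return len(self.proteins)

    def sequences(self) -> dict[str, str]:
        return dict(self.proteins)


def _check_residues(accession: str, sequence: str) -> list[tuple[int, str]]:
    """Return (position, letter) for every non-canonical residue."""
    return [(i, c) for i, c in enumerate(sequence) if c not in CANONICAL_RESIDUES]


def read_proteome(
    path: str | Path,
    id: str,
    taxon_name: str,
    category: Category | str,
    residue_policy: str = "strict",
) -> Proteome:
    """Read a FASTA proteome.

    ``residue_policy`` is ``"strict"`` (raise on any non-canonical letter,
    naming accession and position) or ``"mask"`` (drop proteins containing
    non-canonical letters, with a log message per dropped protein).
    """
    if residue_policy not in ("strict", "mask"):
        raise ValueError(f"unknown residue policy {residue_policy!r}")
    path = Path(path)
    proteins: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id  # token before first whitespace
        seq = str(record.seq).upper()
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in {path}")
        bad = _check_residues(acc, seq)
        if bad:
            if residue_policy == "strict":
                pos, letter = bad[0]
                raise ValueError(
                    f"non-canonical residue {letter!r} at position {pos} "
                    f"in {acc!r} ({len(bad)} offending position(s) total)"
                )
            logger.warning(
                "masking protein %s: %d non-canonical residue(s)", acc, len(bad)
            )
            continue
        seen.add(acc)
        proteins.append((acc, seq))
    if not proteins:
        raise ValueError(f"no usable FASTA records in {path}")
    return Proteome(id=id, taxon_name=taxon_name, category=Category(category), proteins=proteins)


def write_proteome(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteome.proteins:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# candidate observation tables
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "peptide_sequence",
    "protein_accession",
    "strain_id",
    "fragment_label",
    "integrated_area",
    "run_id",
]


def parse_fragment_label(label: str) -> int:
    """``"y7" -> 7``; raises ValueError on anything but a y-ion label."""
    label = str(label).strip()
    if not label.startswith("y"):
        raise ValueError(f"unsupported fragment label {label!r} (only y-ions)")
    try:
        idx = int(label[1:])
    except ValueError:
        raise ValueError(f"malformed fragment label {label!r}") from None
    if idx < 1:
        raise ValueError(f"fragment index must be >= 1, got {label!r}")
    return idx


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    """Read a discovery-run candidate observation table.

    Every malformed row is reported (line number + reason), not just the
    first; a single ValueError aggregates them.
    """
    df = _read_csv(path)
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table {path} missing column(s): {', '.join(missing)}")
    problems: list[str] = []
    areas = pd.to_numeric(df["integrated_area"], errors="coerce")
    for i, row in df.iterrows():
        line = i + 2  # 1-based + header
        area = areas.iloc[i]
        if np.isnan(area):
            problems.append(f"line {line}: non-numeric area {row['integrated_area']!r}")
        elif area < 0:
            problems.append(f"line {line}: negative area {area}")
        try:
            y = parse_fragment_label(row["fragment_label"])
        except ValueError as exc:
            problems.append(f"line {line}: {exc}")
            continue
        # terminal y-ion convention: largest monitored fragment is y(n-1)
        if y > len(str(row["peptide_sequence"])) - 1:
            problems.append(
                f"line {line}: fragment {row['fragment_label']} impossible for "
                f"{len(str(row['peptide_sequence']))}-residue peptide "
                f"{row['peptide_sequence']} (max y{len(str(row['peptide_sequence'])) - 1})"
            )
    if problems:
        raise ValueError("invalid candidate table rows:\n" + "\n".join(problems))
    df = df.copy()
    df["integrated_area"] = areas.astype(float)
    return df


# ---------------------------------------------------------------------------
# transition lists
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = [
    "protein",
    "peptide",
    "precursor_mz",
    "product_mz",
    "fragment_label",
    "collision_energy",
    "charge",
]


def write_transition_list(
    rows: Sequence[dict],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    """Write a transition-list CSV.

    One row per transition; m/z and CE printed with fixed 4-decimal
    precision; rows ordered by (protein, peptide, ascending y-index) so
    repeated runs produce byte-identical files.
    """
    if not rows:
        raise ValueError("refusing to write an empty transition list")
    df = pd.DataFrame(list(rows))
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transition rows missing key(s): {', '.join(missing)}")
    df["_y"] = df["fragment_label"].map(parse_fragment_label)
    df = df.sort_values(["protein", "peptide", "_y"], kind="mergesort").drop(columns="_y")
    extra = [c for c in df.columns if c not in TRANSITION_COLUMNS]
    df = df[TRANSITION_COLUMNS + extra]
    for col in ("precursor_mz", "product_mz", "collision_energy"):
        df[col] = df[col].map(lambda v: f"{float(v):.4f}")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_transition_list(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transition list {path} missing column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# reference spectral libraries
# ---------------------------------------------------------------------------


@dataclass
class ReferencePattern:
    """Reference transition intensity ratios + retention time for one peptide.

    Ratios are stored normalized to unit sum, one per retained transition,
    ordered to match ``fragment_labels``.
    """

    peptide: str
    fragment_labels: list[str]
    ratios: np.ndarray
    reference_rt: float  # minutes

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if len(self.fragment_labels) != self.ratios.size:
            raise ValueError("one ratio per fragment label required")
        if self.ratios.size < 2:
            raise ValueError(f"reference for {self.peptide} needs >=2 transitions")
        if np.any(self.ratios < 0):
            raise ValueError("reference ratios must be nonnegative")
        total = float(self.ratios.sum())
        if total <= 0:
            raise ValueError(f"reference for {self.peptide} has no signal")
        self.ratios = self.ratios / total
        if not self.reference_rt > 0:
            raise ValueError("reference RT must be positive (minutes)")


REFERENCE_COLUMNS = ["peptide_sequence", "fragment_label", "ratio", "reference_rt_min"]


def read_reference_library(path: str | Path) -> dict[str, ReferencePattern]:
    df = _read_csv(path)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference library {path} missing column(s): {', '.join(missing)}")
    out: dict[str, ReferencePattern] = {}
    for pep, grp in df.groupby("peptide_sequence", sort=True):
        grp = grp.assign(_y=grp["fragment_label"].map(parse_fragment_label)).sort_values("_y")
        rts = grp["reference_rt_min"].unique()
        if len(rts) != 1:
            raise ValueError(f"inconsistent reference RT for {pep}: {sorted(rts)}")
        out[str(pep)] = ReferencePattern(
            peptide=str(pep),
            fragment_labels=list(grp["fragment_label"]),
            ratios=grp["ratio"].to_numpy(float),
            reference_rt=float(rts[0]),
        )
    if not out:
        raise ValueError(f"reference library {path} is empty")
    return out


def write_reference_library(
    patterns: Iterable[ReferencePattern],
    path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    rows = []
    for p in sorted(patterns, key=lambda p: p.peptide):
        for label, ratio in zip(p.fragment_labels, p.ratios):
            rows.append(
                {
                    "peptide_sequence": p.peptide,
                    "fragment_label": label,
                    "ratio": f"{ratio:.6f}",
                    "reference_rt_min": f"{p.reference_rt:.4f}",
                }
            )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# chromatogram traces / peak-group summaries
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["run_id", "peptide", "fragment_label", "time_min", "intensity"]
PEAK_COLUMNS = ["run_id", "peptide", "fragment_label", "area", "apex_rt_min"]


def read_trace_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table {path} missing column(s): {', '.join(missing)}")
    return df


def write_trace_table(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df[TRACE_COLUMNS].to_csv(fh, index=False)
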