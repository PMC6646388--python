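"""In-silico tryptic digestion and proteotypic-candidate filtering.

Trypsin cleaves C-terminal to K or R; with the proline rule active
(default), a K/R immediately followed by P is not cleaved. Candidate
filtering keeps peptides of 7-18 residues containing no methionine,
the standard constraints for robust triple-quadrupole targets
(methionine oxidizes unpredictably; very short peptides are rarely
unique, very long ones fragment poorly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .constants import CANONICAL_RESIDUES
from .proteome_io import Proteome

REASON_TOO_SHORT = "too_short"
REASON_TOO_LONG = "too_long"
REASON_EXCLUDED_RESIDUE = "excluded_residue"


@dataclass(frozen=True)
class DigestParams:
    """Digestion + candidate-filter settings.

    missed_cleavages : internal cleavage sites allowed per product (0 for
        peptidome building; up to 2 when reconciling discovery tables).
    proline_rule : suppress cleavage of K/R-P bonds (classic trypsin).
    min_len, max_len : candidate length bounds in residues.
    exclude_residues : letters that disqualify a candidate (default {M}).
    il_equate : fold I onto L when building peptidome sets (MS cannot
        distinguish leucine from isoleucine).
    """

    enzyme: str = "trypsin"
    missed_cleavages: int = 0
    proline_rule: bool = True
    min_len: int = 7
    max_len: int = 18
    exclude_residues: frozenset[str] = frozenset("M")
    il_equate: bool = False

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ValueError("only trypsin is supported")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")


@dataclass
class PeptideCandidate:
    """A digest product annotated with filter status and provenance."""

    sequence: str
    parent_accessions: set[str] = field(default_factory=set)
    strain_ids: set[str] = field(default_factory=set)
    filter_pass: bool = True
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if bool(self.reasons) == self.filter_pass:
            raise ValueError("reason codes must be empty iff filter_pass")


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions *after* which trypsin cuts."""
    sites = []
    n = len(sequence)
    for i, c in enumerate(sequence):
        if c in "KR" and i < n - 1:
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[tuple[str, int, int]]:
    """Tryptic digest with positions.

    Returns ``(peptide, start, end)`` triples (0-based half-open),
    including products spanning up to ``params.missed_cleavages``
    internal sites, ordered by start position then length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"non-canonical residue(s) {sorted(bad)} in sequence")
    cuts = cleavage_sites(sequence, params.proline_rule)
    # fully-tryptic fragment boundaries
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(sequence)]
    out: list[tuple[str, int, int]] = []
    nfrag = len(starts)
    for i in range(nfrag):
        for mc in range(params.missed_cleavages + 1):
            j = i + mc
            if j >= nfrag:
                break
            s, e = starts[i], ends[j]
            out.append((sequence[s:e], s, e))
    out.sort(key=lambda t: (t[1], t[2] - t[1]))
    return out


def filter_candidates(
    peptides: Iterable[str], params: DigestParams = DigestParams()
) -> list[PeptideCandidate]:
    """Apply the length/composition candidate filter to peptide sequences."""
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides to filter")
    out = []
    for pep in peptides:
        reasons: list[str] = []
        if len(pep) < params.min_len:
            reasons.append(REASON_TOO_SHORT)
        if len(pep) > params.max_len:
            reasons.append(REASON_TOO_LONG)
        if set(pep) & params.exclude_residues:
            reasons.append(REASON_EXCLUDED_RESIDUE)
        out.append(
            PeptideCandidate(sequence=pep, filter_pass=not reasons, reasons=tuple(reasons))
        )
    return out


def canonical_form(peptide: str, il_equate: bool) -> str:
    return peptide.replace("I", "L") if il_equate else peptide


def build_peptidome(proteome: Proteome, params: DigestParams = DigestParams()) -> set[str]:
    """Filtered tryptic peptide set (union over all proteins, set semantics)."""
    peps: set[str] = set()
    for _, seq in proteome.proteins:
        for pep, _, _ in digest(seq, params):
            if params.min_len <= len(pep) <= params.max_len and not (
                set(pep) & params.exclude_residues
            ):
                peps.add(canonical_form(pep, params.il_equate))
    return peps


def peptide_parent_map(
    proteome: Proteome, params: DigestParams = DigestParams()
) -> dict[str, set[str]]:
    """Map each filtered tryptic peptide to the accessions producing it."""
    out: dict[str, set[str]] = {}
    for acc, seq in proteome.proteins:
        for pep, _, _ in digest(seq, params):
            if params.min_len <= len(pep) <= params.max_len and not (
                set(pep) & params.exclude_residues
            ):
                out.setdefault(canonical_form(pep, params.il_equate), set()).add(acc)
    return out
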