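"""Peptide specificity screening against labeled background proteomes.

A candidate peptide is classified into one of three tiers by where it
occurs besides the target organism:

* ``specific`` — found only in target-category proteomes; kept.
* ``semi_specific`` — also found in related organohalide-respiring
  bacteria; kept with a caveat (its signal cannot distinguish the target
  from those relatives).
* ``non_specific`` — found in any unrelated ("other") proteome; removed
  from the panel.

Precedence is non_specific > semi_specific > specific: a single hit in
an unrelated proteome disqualifies the peptide regardless of other hits.

Match semantics are configurable: membership in the background's tryptic
peptidome (default, mirrors tryptic-peptide database lookups) or raw
substring search against undigested protein sequences (mirrors
protein-level homology screening).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import pandas as pd

from .constants import CANONICAL_RESIDUES
from .digestion import DigestParams, canonical_form, peptide_parent_map
from .proteome_io import Category, Proteome


class Tier(str, Enum):
    SPECIFIC = "specific"
    SEMI_SPECIFIC = "semi_specific"
    NON_SPECIFIC = "non_specific"


class Action(str, Enum):
    KEEP = "keep"
    KEEP_WITH_CAVEAT = "keep_with_caveat"
    REMOVE = "remove"


TIER_ACTION = {
    Tier.SPECIFIC: Action.KEEP,
    Tier.SEMI_SPECIFIC: Action.KEEP_WITH_CAVEAT,
    Tier.NON_SPECIFIC: Action.REMOVE,
}


@dataclass
class SpecificityReport:
    peptide: str
    tier: Tier
    hits: list[tuple[str, str]]  # (proteome_id, accession)
    action: Action


class ProteomeRegistry:
    """Labeled proteomes plus cached tryptic peptidomes / parent maps."""

    def __init__(
        self,
        proteomes: list[Proteome],
        digest_params: DigestParams = DigestParams(),
        match_mode: str = "peptidome",
    ):
        if match_mode not in ("peptidome", "substring"):
            raise ValueError(f"unknown match mode {match_mode!r}")
        if not any(p.category is Category.TARGET for p in proteomes):
            raise ValueError("registry needs at least one target-category proteome")
        ids = [p.id for p in proteomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate proteome ids in registry")
        self.proteomes = list(proteomes)
        self.digest_params = digest_params
        self.match_mode = match_mode
        self._parent_maps: dict[str, dict[str, set[str]]] = {}

    def parent_map(self, proteome: Proteome) -> dict[str, set[str]]:
        if proteome.id not in self._parent_maps:
            self._parent_maps[proteome.id] = peptide_parent_map(proteome, self.digest_params)
        return self._parent_maps[proteome.id]

    def peptidome(self, proteome: Proteome) -> set[str]:
        return set(self.parent_map(proteome))

    def hits_for(self, peptide: str, proteome: Proteome) -> list[str]:
        """Accessions in ``proteome`` containing ``peptide`` under the match mode."""
        if self.match_mode == "substring":
            query = canonical_form(peptide, self.digest_params.il_equate)
            out = []
            for acc, seq in proteome.proteins:
                hay = canonical_form(seq, self.digest_params.il_equate)
                if query in hay:
                    out.append(acc)
            return sorted(out)
        query = canonical_form(peptide, self.digest_params.il_equate)
        return sorted(self.parent_map(proteome).get(query, ()))


def classify_specificity(peptide: str, registry: ProteomeRegistry) -> SpecificityReport:
    """Assign a specificity tier to one peptide against the whole registry."""
    bad = set(peptide) - CANONICAL_RESIDUES
    if bad:
        raise ValueError(f"peptide {peptide!r} has non-canonical residue(s) {sorted(bad)}")
    hits: list[tuple[str, str]] = []
    categories_hit: set[Category] = set()
    for proteome in registry.proteomes:
        for acc in registry.hits_for(peptide, proteome):
            hits.append((proteome.id, acc))
            categories_hit.add(proteome.category)
    if Category.OTHER in categories_hit:
        tier = Tier.NON_SPECIFIC
    elif Category.RELATED_OHRB in categories_hit:
        tier = Tier.SEMI_SPECIFIC
    else:
        tier = Tier.SPECIFIC
    return SpecificityReport(
        peptide=peptide, tier=tier, hits=sorted(hits), action=TIER_ACTION[tier]
    )


def screen_panel(
    candidates: list[str], registry: ProteomeRegistry
) -> tuple[list[SpecificityReport], dict[str, int]]:
    """Classify every candidate; return reports (sorted by peptide) + tier counts.

    Peptides tiered non_specific carry action ``remove`` and should be
    excluded from the downstream panel by the caller.
    """
    reports = [classify_specificity(p, registry) for p in sorted(set(candidates))]
    summary = {t.value: 0 for t in Tier}
    for r in reports:
        summary[r.tier.value] += 1
    summary["removed"] = summary[Tier.NON_SPECIFIC.value]
    summary["kept"] = len(reports) - summary["removed"]
    return reports, summary


def peptidome_similarity(
    peptidome_a: set[str], peptidome_b: set[str], method: str = "jaccard"
) -> float:
    """Pairwise peptidome similarity as a percentage.

    ``jaccard`` (default): 100 * |A n B| / |A u B|.
    ``overlap``: 100 * |A n B| / min(|A|, |B|).
    """
    if not peptidome_a or not peptidome_b:
        raise ValueError("peptidomes must be non-empty")
    inter = len(peptidome_a & peptidome_b)
    if method == "jaccard":
        return 100.0 * inter / len(peptidome_a | peptidome_b)
    if method == "overlap":
        return 100.0 * inter / min(len(peptidome_a), len(peptidome_b))
    raise ValueError(f"unknown similarity method {method!r}")


def similarity_matrix(
    registry: ProteomeRegistry, method: str = "jaccard"
) -> pd.DataFrame:
    """Symmetric percentage similarity matrix over all registry proteomes."""
    ids = [p.id for p in registry.proteomes]
    peps = {p.id: registry.peptidome(p) for p in registry.proteomes}
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        v = peptidome_similarity(peps[a], peps[b], method)
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def reports_to_frame(reports: list[SpecificityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [r.peptide for r in reports],
            "tier": [r.tier.value for r in reports],
            "action": [r.action.value for r in reports],
            "n_hits": [len(r.hits) for r in reports],
            "hits": [";".join(f"{pid}:{acc}" for pid, acc in r.hits) for r in reports],
        }
    )
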