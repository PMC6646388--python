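"""Transition refinement: AUC ranking, cross-strain merging, load linearity.

From discovery-run integrated areas, each peptide keeps its top-k
transitions ranked by fractional contribution to the peptide's total
chromatographic AUC (k=5 by default). Per-strain panels are then merged
into one cross-strain panel: identical peptide sequences collapse to a
single entry carrying the union of strain ids. Retention may be ragged —
a peptide with fewer than k usable transitions keeps them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import parse_fragment_label


@dataclass(frozen=True)
class RetainedTransition:
    fragment_label: str
    area: float
    contribution: float  # fraction of the peptide's total AUC


@dataclass
class PanelEntry:
    peptide: str
    strain_ids: set[str]
    transitions: list[RetainedTransition]
    total_auc: float

    def __post_init__(self) -> None:
        if len(self.transitions) > 5:
            raise ValueError(f"{self.peptide}: more than 5 retained transitions")


@dataclass
class RankedPanel:
    entries: list[PanelEntry] = field(default_factory=list)

    @property
    def n_peptides_unique(self) -> int:
        return len({e.peptide for e in self.entries})

    @property
    def n_transitions(self) -> int:
        return sum(len(e.transitions) for e in self.entries)


def rank_transitions(
    observations: pd.DataFrame, k: int = 5
) -> list[RetainedTransition]:
    """Retain the top-k transitions of one peptide by AUC contribution.

    ``observations`` holds columns ``fragment_label`` and
    ``integrated_area`` for a single peptide (areas summed over rows with
    the same fragment). Ties in contribution break toward the lower
    y-index. Raises on an all-zero signal, which cannot be ranked.
    """
    if observations.empty:
        raise ValueError("no observations to rank")
    if (observations["integrated_area"] < 0).any():
        raise ValueError("negative integrated areas")
    per_frag = observations.groupby("fragment_label")["integrated_area"].sum()
    total = float(per_frag.sum())
    if total <= 0:
        raise ValueError("all-zero areas: no rankable signal")
    rows = sorted(
        per_frag.items(),
        key=lambda kv: (-kv[1] / total, parse_fragment_label(kv[0])),
    )
    return [
        RetainedTransition(fragment_label=label, area=float(a), contribution=float(a) / total)
        for label, a in rows[: min(k, len(rows))]
    ]


def build_strain_panel(
    candidate_table: pd.DataFrame, strain_id: str, k: int = 5
) -> list[PanelEntry]:
    """Rank transitions for every peptide observed in one strain's runs."""
    sub = candidate_table[candidate_table["strain_id"] == strain_id]
    entries = []
    for pep, grp in sub.groupby("peptide_sequence", sort=True):
        retained = rank_transitions(grp, k=k)
        entries.append(
            PanelEntry(
                peptide=str(pep),
                strain_ids={strain_id},
                transitions=retained,
                total_auc=float(grp["integrated_area"].sum()),
            )
        )
    return entries


def merge_across_strains(
    per_strain: dict[str, list[PanelEntry]], mode: str = "best_auc"
) -> RankedPanel:
    """Merge per-strain panels into a single cross-strain panel.

    Shared peptide sequences appear once with unioned strain ids. When
    strains retained different transition sets for the same peptide,
    ``best_auc`` (default) takes the set from the strain with the highest
    total AUC; ``intersection`` keeps only transitions retained by every
    strain. Entries are ordered by peptide sequence.
    """
    if mode not in ("best_auc", "intersection"):
        raise ValueError(f"unknown merge mode {mode!r}")
    by_pep: dict[str, list[PanelEntry]] = {}
    for entries in per_strain.values():
        for e in entries:
            by_pep.setdefault(e.peptide, []).append(e)
    merged: list[PanelEntry] = []
    for pep in sorted(by_pep):
        group = by_pep[pep]
        strains = set().union(*(e.strain_ids for e in group))
        if mode == "best_auc":
            winner = max(group, key=lambda e: (e.total_auc, sorted(e.strain_ids)))
            transitions = list(winner.transitions)
        else:
            labels = set.intersection(*({t.fragment_label for t in e.transitions} for e in group))
            winner = max(group, key=lambda e: (e.total_auc, sorted(e.strain_ids)))
            transitions = [t for t in winner.transitions if t.fragment_label in labels]
        merged.append(
            PanelEntry(
                peptide=pep,
                strain_ids=strains,
                transitions=transitions,
                total_auc=max(e.total_auc for e in group),
            )
        )
    return RankedPanel(entries=merged)


@dataclass
class LoadConsistencyFlag:
    peptide: str
    status: str  # pass | fail | not_evaluable
    pearson_r: float | None
    monotone_increasing: bool | None


def multi_load_consistency(
    load_table: pd.DataFrame, r_threshold: float = 0.9
) -> list[LoadConsistencyFlag]:
    """Flag peptides whose total AUC scales with column load.

    ``load_table`` columns: ``peptide_sequence``, ``load_amount`` (same
    mass unit throughout, e.g. µg on column) and ``total_auc``. A peptide
    passes when the Pearson correlation of AUC against load reaches
    ``r_threshold`` *and* AUC strictly increases with load; peptides
    measured at a single load are flagged ``not_evaluable``. Flags are
    always returned, never silently dropped.
    """
    flags = []
    for pep, grp in load_table.groupby("peptide_sequence", sort=True):
        grp = grp.sort_values("load_amount")
        loads = grp["load_amount"].to_numpy(float)
        aucs = grp["total_auc"].to_numpy(float)
        if len(np.unique(loads)) < 2:
            flags.append(LoadConsistencyFlag(str(pep), "not_evaluable", None, None))
            continue
        if np.allclose(aucs, aucs[0]):
            # constant response: correlation undefined, clearly not scaling
            flags.append(LoadConsistencyFlag(str(pep), "fail", 0.0, False))
            continue
        r = float(stats.pearsonr(loads, aucs).statistic)
        increasing = bool(np.all(np.diff(aucs) > 0))
        status = "pass" if (r >= r_threshold and increasing) else "fail"
        flags.append(LoadConsistencyFlag(str(pep), status, r, increasing))
    return flags


def panel_to_frame(panel: RankedPanel) -> pd.DataFrame:
    rows = []
    for e in panel.entries:
        for t in e.transitions:
            rows.append(
                {
                    "peptide": e.peptide,
                    "strain_ids": ";".join(sorted(e.strain_ids)),
                    "fragment_label": t.fragment_label,
                    "area": t.area,
                    "contribution": t.contribution,
                }
            )
    return pd.DataFrame(rows)
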