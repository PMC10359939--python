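"""Target-space expansion, representative picking, availability substitution,
and coverage accounting for the screening-set construction.

The goal is a minimal compound set covering a maximal target space: one
(most potent) compound per target, with unavailable picks replaced by the
next most potent purchasable compound, and first-neighbour / influencer
expansion of the cancer-associated seed targets over a protein-interaction
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .core_io import ASSAY_TYPES, BioactivityTable, ValidationError

_ASSAY_RANK = {a: i for i, a in enumerate(ASSAY_TYPES)}

_ENTRY_COLUMNS = ["target_id", "compound_id", "assay_type", "value_nM", "substituted"]


@dataclass
class LibrarySelection:
    """At most one chosen compound per target, plus targets left uncovered."""

    entries: pd.DataFrame  # columns: target_id, compound_id, assay_type, value_nM, substituted
    uncovered_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.entries.columns) != _ENTRY_COLUMNS:
            self.entries = self.entries[_ENTRY_COLUMNS]
        if self.entries["target_id"].duplicated().any():
            raise ValidationError("more than one entry for a target")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CoverageStats:
    n_compounds: int
    n_targets_covered: int
    coverage_fraction: float
    targets_per_compound: dict[str, int]
    compounds_per_target: dict[str, int]


def expand_target_space(seed_targets: Iterable[str],
                        edges: Iterable[tuple[str, str]],
                        ) -> tuple[set[str], set[str]]:
    """First-neighbour / influencer expansion of a seed target set.

    Edges are symmetrised and self-loops dropped.  First neighbours interact
    directly with a seed; influencers interact directly with a first
    neighbour without being a seed or a first neighbour themselves.  The two
    returned sets are disjoint from each other and from the seeds.
    """
    seeds = set(seed_targets)
    if not seeds:
        raise ValidationError("seed target set is empty")
    g = nx.Graph()
    g.add_nodes_from(seeds)
    for a, b in edges:
        if a != b:
            g.add_edge(a, b)
    first = set()
    for s in seeds:
        first.update(g.neighbors(s))
    first -= seeds
    influencers = set()
    for f in first:
        influencers.update(g.neighbors(f))
    influencers -= seeds | first
    return first, influencers


def _ranked(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by potency with the deterministic tie-break chain."""
    out = df.assign(_rank=df["assay_type"].map(_ASSAY_RANK))
    out = out.sort_values(["value_nM", "compound_id", "_rank"],
                          kind="mergesort")
    return out.drop(columns="_rank")


def pick_representative_per_target(table: BioactivityTable) -> LibrarySelection:
    """Pick, per target, the single most potent compound.

    All four assay types are pooled and treated equally; ties break by
    lexicographically smaller compound_id, then assay-type enum order.
    """
    df = _ranked(table.df)
    best = df.groupby("target_id", as_index=False).head(1)
    entries = best.assign(substituted=False)[_ENTRY_COLUMNS]
    return LibrarySelection(entries=entries.sort_values("target_id")
                            .reset_index(drop=True))


def substitute_unavailable(selection: LibrarySelection,
                           table: BioactivityTable,
                           availability: Mapping[str, bool],
                           ) -> LibrarySelection:
    """Replace unavailable representatives by the next most potent available one.

    Unknown availability counts as unavailable.  Targets with no available
    compound at all are moved to ``uncovered_targets``.
    """
    ranked = _ranked(table.df)
    by_target = dict(tuple(ranked.groupby("target_id")))
    rows, uncovered = [], list(selection.uncovered_targets)
    for entry in selection.entries.itertuples(index=False):
        if availability.get(entry.compound_id, False):
            rows.append(entry)
            continue
        cands = by_target.get(entry.target_id)
        repl = None
        if cands is not None:
            avail_mask = cands["compound_id"].map(
                lambda c: bool(availability.get(c, False)))
            avail = cands[avail_mask]
            if not avail.empty:
                repl = avail.iloc[0]
        if repl is None:
            uncovered.append(entry.target_id)
        else:
            rows.append((entry.target_id, repl["compound_id"],
                         repl["assay_type"], repl["value_nM"], True))
    entries = pd.DataFrame(rows, columns=_ENTRY_COLUMNS)
    return LibrarySelection(entries=entries.reset_index(drop=True),
                            uncovered_targets=sorted(set(uncovered)))


def coverage_summary(selection: LibrarySelection,
                     table: BioactivityTable,
                     target_universe: Iterable[str],
                     potency_cutoff_nM: float = 1000.0,
                     ) -> CoverageStats:
    """Coverage accounting at the configured activity ceiling.

    Targets-per-compound and compounds-per-target counts are computed from
    the bioactivity table restricted to records with potency <= the cutoff
    (so "covers" means "is active against at the library's own activity
    bar"), for the selected compounds and the given target universe.
    """
    universe = set(target_universe)
    selected = set(selection.entries["compound_id"])
    df = table.df
    df = df[(df["value_nM"] <= potency_cutoff_nM)
            & df["target_id"].isin(universe)
            & df["compound_id"].isin(selected)]
    tpc = df.groupby("compound_id")["target_id"].nunique().to_dict()
    cpt = df.groupby("target_id")["compound_id"].nunique().to_dict()
    covered = set(df["target_id"])
    return CoverageStats(
        n_compounds=len(selected),
        n_targets_covered=len(covered),
        coverage_fraction=len(covered) / len(universe) if universe else 0.0,
        targets_per_compound={c: tpc.get(c, 0) for c in selected},
        compounds_per_target=cpt,
    )
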