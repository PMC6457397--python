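"""Single-copy orthogroup selection, paralogue screening and duplication-ratio QC.

The screening protocol mirrors standard phylogenomic practice: orthogroups
that are single copy in nearly all species are selected (with a two-copy
allowance for taxa whose assemblies contain uncollapsed haplotypes or that
are represented only by transcriptomes); each orthogroup's gene tree is then
screened for paralogy after collapsing weakly supported nodes, discarding
orthogroups whose species are demonstrably non-monophyletic and resolving
in-paralogue pairs by keeping the longer sequence.  The duplication ratio
(total sequences per species / orthogroups containing the species) flags
assemblies inflated by uncollapsed heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .trees import Phylo, collapse_low_support

__all__ = [
    "OrthogroupTable",
    "SelectionPolicy",
    "ScreenResult",
    "QCReport",
    "select_single_copy",
    "screen_paralogs",
    "duplication_ratio",
    "qc_screen",
]

_COLUMNS = ["orthogroup_id", "species", "sequence_id", "length_aa"]


class OrthogroupTable:
    """Orthogroup membership records.

    Wraps a DataFrame with columns ``orthogroup_id, species, sequence_id,
    length_aa`` (amino acids).  Sequence IDs must be globally unique and
    lengths positive.
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"orthogroup table missing columns {missing}")
        df = records[_COLUMNS].copy()
        if df.empty:
            raise ValueError("orthogroup table is empty")
        if (df["length_aa"] <= 0).any():
            raise ValueError("sequence lengths must be positive")
        if df["sequence_id"].duplicated().any():
            dup = df.loc[df["sequence_id"].duplicated(), "sequence_id"].iloc[0]
            raise ValueError(f"duplicate sequence_id {dup!r}")
        self.df = df

    @classmethod
    def read_tsv(cls, path) -> "OrthogroupTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    @property
    def orthogroups(self) -> list[str]:
        return sorted(self.df["orthogroup_id"].unique())

    def counts(self) -> pd.DataFrame:
        """Per (orthogroup, species) sequence counts, wide, 0-filled."""
        return (
            self.df.groupby(["orthogroup_id", "species"])
            .size()
            .unstack(fill_value=0)
        )

    def records_for(self, orthogroup_id: str) -> pd.DataFrame:
        sub = self.df[self.df["orthogroup_id"] == orthogroup_id]
        if sub.empty:
            raise KeyError(f"unknown orthogroup {orthogroup_id!r}")
        return sub


@dataclass(frozen=True)
class SelectionPolicy:
    """Thresholds for single-copy orthogroup selection.

    ``min_present`` species must carry the locus; every species must be
    single copy except those in ``double_allowed_species``, which may carry
    up to two copies.  ``support_threshold`` is the bootstrap value below
    which gene-tree nodes are collapsed before the paralogy check.
    """

    n_species_total: int
    min_present: int = 27
    double_allowed_species: frozenset = frozenset()
    support_threshold: int = 50

    def __post_init__(self):
        if not 1 <= self.min_present <= self.n_species_total:
            raise ValueError("need 1 <= min_present <= n_species_total")


def select_single_copy(table: OrthogroupTable, policy: SelectionPolicy) -> list[str]:
    """Orthogroups present in >= min_present species and single copy
    everywhere (<= 2 copies in double-allowed species).  Sorted by ID."""
    unknown = set(policy.double_allowed_species) - set(table.species)
    if unknown:
        raise ValueError(f"policy names unknown species: {sorted(unknown)}")
    counts = table.counts()
    selected = []
    for og, row in counts.iterrows():
        present = int((row > 0).sum())
        if present < policy.min_present:
            continue
        ok = True
        for sp, c in row.items():
            limit = 2 if sp in policy.double_allowed_species else 1
            if c > limit:
                ok = False
                break
        if ok:
            selected.append(og)
    return sorted(selected)


@dataclass
class ScreenResult:
    decision: str  # "keep" | "discard"
    retained: tuple[str, ...] = ()
    reason: str = ""


def _monophyly_compatible(tree: Phylo, leaves: set) -> bool:
    """Can ``leaves`` form a clade in some refinement of ``tree``?

    True iff every child subtree of their MRCA is entirely inside or entirely
    outside the set (polytomy children are mutually compatible and can be
    regrouped under a new node).
    """
    if len(leaves) <= 1:
        return True
    m = tree.mrca(sorted(leaves))
    for child in m.children:
        below = tree.leaf_set(child)
        if below & leaves and not below <= leaves:
            return False
    return True


def screen_paralogs(
    og_tree: Phylo,
    og_records: Mapping[str, tuple[str, int]] | pd.DataFrame,
    policy: SelectionPolicy,
) -> ScreenResult:
    """Screen one orthogroup's gene tree for paralogy.

    ``og_records`` maps sequence_id -> (species, length_aa) (or a DataFrame
    with those columns).  Nodes with support below the policy threshold are
    collapsed first; the orthogroup is discarded if any species' sequences
    cannot be monophyletic on the collapsed tree, or if a species has more
    than two sequences.  Otherwise in-paralogue pairs are resolved by keeping
    the longer sequence (ties: lexicographically smaller ID); the retained
    set has exactly one sequence per represented species.
    """
    if isinstance(og_records, pd.DataFrame):
        og_records = {
            r.sequence_id: (r.species, int(r.length_aa))
            for r in og_records.itertuples()
        }
    leaf_labels = og_tree.leaf_labels()
    missing = [l for l in leaf_labels if l not in og_records]
    if missing:
        raise ValueError(f"gene-tree leaves without records: {missing}")

    collapsed = collapse_low_support(og_tree, policy.support_threshold)
    by_species: dict[str, list[str]] = {}
    for seq_id in leaf_labels:
        by_species.setdefault(og_records[seq_id][0], []).append(seq_id)

    for sp, seqs in sorted(by_species.items()):
        if len(seqs) > 2:
            return ScreenResult("discard", reason=f"{sp} has {len(seqs)} sequences")
        if len(seqs) == 2 and not _monophyly_compatible(collapsed, set(seqs)):
            return ScreenResult("discard", reason=f"{sp} sequences not monophyletic")

    retained = []
    for sp, seqs in sorted(by_species.items()):
        # longest sequence wins; ties broken by the lexicographically
        # smaller sequence ID for determinism
        best = min(seqs, key=lambda s: (-og_records[s][1], s))
        retained.append(best)
    return ScreenResult("keep", retained=tuple(sorted(retained)))


def duplication_ratio(
    table: OrthogroupTable, og_subset: Iterable[str], species: str
) -> float:
    """Total sequence count for ``species`` across ``og_subset`` divided by
    the number of those orthogroups containing the species."""
    og_subset = set(og_subset)
    if not og_subset:
        raise ValueError("og_subset is empty")
    sub = table.df[
        table.df["orthogroup_id"].isin(og_subset) & (table.df["species"] == species)
    ]
    n_ogs = sub["orthogroup_id"].nunique()
    if n_ogs == 0:
        raise ValueError(f"species {species!r} absent from every selected orthogroup")
    return len(sub) / n_ogs


@dataclass
class QCReport:
    """Per-species duplication-ratio report with the parameters used."""

    table: pd.DataFrame  # species, n_OGs, n_seqs, duplication_ratio, excluded
    presence_min: int
    mean_count_max: float
    threshold: float
    n_selected_ogs: int
    note: str = ""

    @property
    def excluded_species(self) -> list[str]:
        return sorted(self.table.loc[self.table["excluded"], "species"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def qc_screen(
    table: OrthogroupTable,
    species: Optional[Sequence[str]] = None,
    presence_min: int = 22,
    mean_count_max: float = 1.5,
    threshold: float = 1.2,
) -> QCReport:
    """Assembly-QC screen: select near-universal, on-average-single-copy
    orthogroups, compute each species' duplication ratio over them, and flag
    species whose ratio strictly exceeds ``threshold``."""
    if presence_min <= 0 or mean_count_max <= 0 or threshold <= 0:
        raise ValueError("parameters must be positive")
    if species is None:
        species = table.species
    counts = table.counts().reindex(columns=species, fill_value=0)
    present = counts > 0
    n_present = present.sum(axis=1)
    mean_count = counts.sum(axis=1) / n_present.clip(lower=1)
    chosen = counts.index[(n_present >= presence_min) & (mean_count <= mean_count_max)]
    if len(chosen) == 0:
        return QCReport(
            table=pd.DataFrame(
                columns=["species", "n_OGs", "n_seqs", "duplication_ratio", "excluded"]
            ),
            presence_min=presence_min,
            mean_count_max=mean_count_max,
            threshold=threshold,
            n_selected_ogs=0,
            note="no orthogroup passed selection",
        )
    sel = counts.loc[chosen]
    rows = []
    for sp in species:
        n_ogs = int((sel[sp] > 0).sum())
        n_seqs = int(sel[sp].sum())
        ratio = n_seqs / n_ogs if n_ogs else float("nan")
        rows.append(
            {
                "species": sp,
                "n_OGs": n_ogs,
                "n_seqs": n_seqs,
                "duplication_ratio": ratio,
                "excluded": bool(n_ogs and ratio > threshold),
            }
        )
    return QCReport(
        table=pd.DataFrame(rows),
        presence_min=presence_min,
        mean_count_max=mean_count_max,
        threshold=threshold,
        n_selected_ogs=len(chosen),
    )
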