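"""Scaffold taxonomy by rank-wise strict-majority vote over protein lineages.

Each protein on a scaffold carries a ranked lineage (possibly truncated or
entirely unannotated). Proceeding from superkingdom downward, a rank is
assigned the label supported by strictly more than 50% of the proteins on the
scaffold; the vote stops at the first rank where no label reaches a strict
majority. By default unannotated proteins count toward the denominator (the
conservative reading); set ``count_unannotated=False`` to vote over annotated
proteins only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """Ranked labels with the no-gap invariant: once a rank is absent, all
    lower ranks are absent too."""

    labels: tuple[str | None, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels) + (None,) * (len(RANKS) - len(self.labels))
        if len(labels) != len(RANKS):
            raise ValueError(f"expected at most {len(RANKS)} ranks")
        seen_gap = False
        for lab in labels:
            if lab is None or (isinstance(lab, float) and pd.isna(lab)) or lab == "":
                seen_gap = True
            elif seen_gap:
                raise ValueError("lineage has a gap: absent rank above a present one")
        object.__setattr__(self, "labels", tuple(
            None if (lab is None or lab == "" or (isinstance(lab, float) and pd.isna(lab)))
            else str(lab)
            for lab in labels
        ))

    @classmethod
    def unclassified(cls) -> "Lineage":
        return cls((None,) * len(RANKS))

    @classmethod
    def from_row(cls, row: Mapping) -> "Lineage":
        return cls(tuple(row.get(r) for r in RANKS))

    def at(self, rank: str) -> str | None:
        return self.labels[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        return sum(lab is not None for lab in self.labels)

    def __iter__(self):
        return iter(self.labels)


@dataclass(frozen=True)
class VoteResult:
    lineage: Lineage
    support: tuple[float, ...]        # winner support fraction per assigned rank
    n_proteins: int


def vote_lineage(
    protein_lineages: Sequence[Lineage | None],
    count_unannotated: bool = True,
) -> VoteResult:
    """Strict-majority vote, rank by rank from superkingdom downward.

    A label wins a rank only with support > 50% of the denominator (all
    proteins by default); exactly 50% never wins. The returned lineage is the
    path of winners down to the first rank without a strict majority.
    """
    lineages = [l if l is not None else Lineage.unclassified()
                for l in protein_lineages]
    if count_unannotated:
        denominator = len(lineages)
    else:
        denominator = sum(l.depth > 0 for l in lineages)
    if denominator == 0:
        return VoteResult(Lineage.unclassified(), (), len(lineages))

    winners: list[str | None] = []
    support: list[float] = []
    for idx, _rank in enumerate(RANKS):
        tally = Counter(l.labels[idx] for l in lineages if l.labels[idx] is not None)
        if not tally:
            break
        label, votes = tally.most_common(1)[0]
        if votes * 2 > denominator:  # strictly more than 50%
            winners.append(label)
            support.append(votes / denominator)
        else:
            break
    winners += [None] * (len(RANKS) - len(winners))
    return VoteResult(Lineage(tuple(winners)), tuple(support), len(lineages))


def classify_assembly(
    lineage_table: pd.DataFrame,
    scaffold_membership: Iterable[str] | Mapping[str, str] | None = None,
    count_unannotated: bool = True,
) -> pd.DataFrame:
    """Apply the majority vote independently to every scaffold.

    ``lineage_table`` holds one row per protein with columns ``protein_id``,
    ``scaffold_id`` (optional if a protein->scaffold mapping is supplied) and
    the seven canonical ranks (blank = unannotated at that rank).
    ``scaffold_membership`` may list scaffolds with no proteins (returned as
    unclassified) or map proteins to scaffolds; proteins referencing unknown
    scaffolds raise an error naming the offenders.
    """
    table = lineage_table.copy()
    if isinstance(scaffold_membership, Mapping):
        table["scaffold_id"] = table["protein_id"].map(scaffold_membership)
        if table["scaffold_id"].isna().any():
            bad = table.loc[table["scaffold_id"].isna(), "protein_id"].tolist()
            raise ValueError(f"proteins without scaffold membership: {bad}")
        known = set(scaffold_membership.values())
    elif scaffold_membership is not None:
        known = set(scaffold_membership)
        bad = sorted(set(table["scaffold_id"]) - known)
        if bad:
            raise ValueError(f"proteins reference unknown scaffolds: {bad}")
    else:
        known = set(table["scaffold_id"])

    rows = []
    grouped = {sid: grp for sid, grp in table.groupby("scaffold_id", sort=False)}
    for sid in sorted(known):
        grp = grouped.get(sid)
        if grp is None or grp.empty:
            res = VoteResult(Lineage.unclassified(), (), 0)
        else:
            res = vote_lineage([Lineage.from_row(r) for _, r in grp.iterrows()],
                               count_unannotated=count_unannotated)
        row = {"scaffold_id": sid, "n_proteins": res.n_proteins}
        for rank, lab in zip(RANKS, res.lineage):
            row[rank] = lab
        for i, rank in enumerate(RANKS):
            row[f"support_{rank}"] = res.support[i] if i < len(res.support) else None
        rows.append(row)
    return pd.DataFrame(rows)
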