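"""Pan-DEG construction: the union of DEG calls over all pairwise comparisons.

Testing every pair of time points — not only consecutive ones — catches
genes whose expression drifts gradually: a change of 0.7 log2 units per
step never clears a |log2FC| > 1 cutoff between neighbours yet exceeds it
over two or three steps.  The pan-DEG set is the non-redundant union of
the per-comparison up/down calls, with the full per-comparison status kept
as provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .de import DEGCall, DOWN, NOT_DE, UP


def enumerate_pairs(timepoints: list[str]) -> list[tuple[str, str]]:
    """All C(T, 2) time-point pairs, each oriented (earlier, later).

    Orientation and listing order follow the input order, so log2FC signs
    downstream always mean "change over time".
    """
    if len(set(timepoints)) != len(timepoints):
        raise ValueError("duplicate time-point labels")
    if len(timepoints) < 2:
        raise ValueError("need at least two time points")
    return list(combinations(timepoints, 2))


@dataclass
class PanDEGSet:
    """Non-redundant union of per-comparison DEG calls with provenance."""

    provenance: pd.DataFrame  # index gene (members only); one status column per comparison
    comparisons: list[tuple[str, str]]

    @property
    def genes(self) -> list[str]:
        return list(self.provenance.index)

    @property
    def ever_up(self) -> pd.Series:
        return (self.provenance == UP).any(axis=1)

    @property
    def ever_down(self) -> pd.Series:
        return (self.provenance == DOWN).any(axis=1)

    def __len__(self) -> int:
        return len(self.provenance)


def _column(comparison: tuple[str, str]) -> str:
    return f"{comparison[0]}_vs_{comparison[1]}"


def build_pan_deg(calls: list[DEGCall]) -> PanDEGSet:
    """Merge per-comparison calls into one provenance table of members.

    A gene enters the set iff it is up- or down-regulated in at least one
    comparison; a gene up in one comparison and down in another keeps both
    statuses.  All calls must share one gene universe.
    """
    if not calls:
        raise ValueError("no DEG calls supplied")
    universe = list(calls[0].status.index)
    for c in calls[1:]:
        if list(c.status.index) != universe:
            raise ValueError("DEG calls have inconsistent gene universes")
    prov = pd.DataFrame(
        {_column(c.comparison): c.status for c in calls},
        index=pd.Index(universe, name="gene"),
    )
    member = (prov != NOT_DE).any(axis=1)
    return PanDEGSet(prov[member], [c.comparison for c in calls])


def pan_deg_summary(pd_set: PanDEGSet) -> pd.DataFrame:
    """Up/down counts per comparison; union size in ``attrs['union_size']``."""
    rows = []
    for comp in pd_set.comparisons:
        col = pd_set.provenance[_column(comp)]
        rows.append(
            {
                "comparison": _column(comp),
                "up": int((col == UP).sum()),
                "down": int((col == DOWN).sum()),
            }
        )
    out = pd.DataFrame(rows, columns=["comparison", "up", "down"])
    out.attrs["union_size"] = len(pd_set)
    return out


def write_pan_deg_tsv(pd_set: PanDEGSet, path) -> None:
    out = pd_set.provenance.copy()
    out["ever_up"] = pd_set.ever_up
    out["ever_down"] = pd_set.ever_down
    out.to_csv(path, sep="\t")
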