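"""Three-set role decomposition of compounds and targets.

The monarch (Jun), minister (Chen), and adjuvant/guide (Zuo-Shi) herb
groups induce three overlapping sets of compounds (by herb membership) and
of targets (by compound association).  ``venn7`` partitions any such triple
into the seven disjoint overlap regions of a three-set Venn diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import Compound, Herb, Role, normalize_symbol

__all__ = [
    "REGIONS",
    "RegionDecomposition",
    "role_set_of_compounds",
    "role_set_of_targets",
    "venn7",
]

REGIONS = (
    "JUN-only",
    "CHEN-only",
    "ZUOSHI-only",
    "JUN∩CHEN",
    "JUN∩ZUOSHI",
    "CHEN∩ZUOSHI",
    "JUN∩CHEN∩ZUOSHI",
)


@dataclass
class RegionDecomposition:
    """Disjoint 7-region partition of three overlapping sets."""

    regions: dict[str, set]
    kind: str = "compound"

    @property
    def universe(self) -> set:
        out: set = set()
        for members in self.regions.values():
            out |= members
        return out

    def sizes(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element": e, "region": r}
            for r in REGIONS
            for e in sorted(self.regions[r], key=str)
        ]
        return pd.DataFrame(rows, columns=["element", "region"])

    def validate(self) -> None:
        total = sum(len(m) for m in self.regions.values())
        if total != len(self.universe):
            raise AssertionError("Venn regions are not disjoint")


def role_set_of_compounds(
    compounds: dict[str, Compound] | list[Compound], herbs: set[Herb]
) -> dict[Role, set[str]]:
    """Map each role to the ids of compounds contained in a herb of that role."""
    comps = list(compounds.values()) if isinstance(compounds, dict) else list(compounds)
    role_of = {h.name: h.role for h in herbs}
    out: dict[Role, set[str]] = {r: set() for r in Role}
    for c in comps:
        for h in c.herbs:
            if h not in role_of:
                raise KeyError(f"herb {h!r} has no role assignment")
            out[role_of[h]].add(c.id)
    return out


def role_set_of_targets(
    assoc: pd.DataFrame, role_compounds: dict[Role, set[str]]
) -> dict[Role, set[str]]:
    """Map each role to the targets hit by any compound of that role.

    ``assoc`` is an association table with columns compound_id, target.
    Associations referencing compounds outside every role set are orphans.
    """
    known = set().union(*role_compounds.values()) if role_compounds else set()
    orphans = set(assoc["compound_id"]) - known
    if orphans:
        raise KeyError(f"associations reference unknown compounds: {sorted(orphans)[:5]}")
    out: dict[Role, set[str]] = {r: set() for r in Role}
    for r, comp_ids in role_compounds.items():
        hit = assoc[assoc["compound_id"].isin(comp_ids)]["target"]
        out[r] = {normalize_symbol(t) for t in hit}
    return out


def venn7(a: set, b: set, c: set, kind: str = "compound") -> RegionDecomposition:
    """Partition three sets into the 7 disjoint Venn regions.

    Region order follows ``REGIONS``: the three single-set regions, the
    three pairwise-only intersections, and the triple intersection.
    """
    a, b, c = set(a), set(b), set(c)
    regions = {
        "JUN-only": a - b - c,
        "CHEN-only": b - a - c,
        "ZUOSHI-only": c - a - b,
        "JUN∩CHEN": (a & b) - c,
        "JUN∩ZUOSHI": (a & c) - b,
        "CHEN∩ZUOSHI": (b & c) - a,
        "JUN∩CHEN∩ZUOSHI": a & b & c,
    }
    out = RegionDecomposition(regions=regions, kind=kind)
    out.validate()
    return out
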