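"""ADME screening: the Tanimoto drug-likeness index and the OB/DL gate.

A compound passes the screen iff OB >= ob_min and DL >= dl_min (both
inclusive), or its name sits on an explicit whitelist of literature-supported
exceptions (e.g. amygdalin, hydroxysafflor yellow A).  The module also
computes role-wise descriptor statistics (mean, SD, one-way ANOVA across
the monarch/minister/adjuvant-guide groups, and unadjusted pairwise t-tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DESCRIPTOR_COLUMNS, Compound, Role
from .stats import one_way_anova

__all__ = ["ScreenConfig", "tanimoto_dl", "screen_compounds", "group_descriptor_stats"]

DEFAULT_WHITELIST = frozenset({"amygdalin", "hydroxysafflor yellow a"})


@dataclass(frozen=True)
class ScreenConfig:
    """Screening gate: OB in percent, DL unitless in [0, 1]."""

    ob_min: float = 30.0
    dl_min: float = 0.18
    whitelist: frozenset[str] = DEFAULT_WHITELIST

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValueError("ob_min must be >= 0")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError("dl_min must lie in [0, 1]")
        object.__setattr__(
            self, "whitelist", frozenset(w.strip().lower() for w in self.whitelist)
        )


def tanimoto_dl(x, y_ref) -> float:
    """Tanimoto similarity T(x, y) = x.y / (|x|^2 + |y|^2 - x.y).

    ``x`` is a compound's descriptor vector and ``y_ref`` the average
    descriptor vector of a reference drug library; T(x, x) = 1 and T = 0
    for orthogonal non-negative vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_ref, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    dot = float(x @ y)
    denom = float(x @ x) + float(y @ y) - dot
    if denom == 0.0:
        raise ZeroDivisionError("Tanimoto undefined for two all-zero vectors")
    return dot / denom


def screen_compounds(
    compounds: dict[str, Compound] | list[Compound],
    cfg: ScreenConfig = ScreenConfig(),
) -> tuple[dict[str, Compound], pd.DataFrame]:
    """Apply the OB/DL gate; return passing compounds and a verdict audit.

    The audit table has one row per compound with columns compound, name,
    OB, DL, verdict (pass/fail), clause (threshold | whitelist | '').
    """
    if isinstance(compounds, dict):
        comps = list(compounds.values())
    else:
        comps = list(compounds)
    rows = []
    passed: dict[str, Compound] = {}
    for c in comps:
        if c.OB is None or c.DL is None or np.isnan(c.OB) or np.isnan(c.DL):
            raise ValueError(f"compound {c.id!r} ({c.name}): missing OB or DL")
        by_threshold = c.OB >= cfg.ob_min and c.DL >= cfg.dl_min
        by_whitelist = c.name.strip().lower() in cfg.whitelist
        ok = by_threshold or by_whitelist
        clause = "threshold" if by_threshold else ("whitelist" if by_whitelist else "")
        rows.append(
            {
                "compound": c.id,
                "name": c.name,
                "OB": c.OB,
                "DL": c.DL,
                "verdict": "pass" if ok else "fail",
                "clause": clause,
            }
        )
        if ok:
            passed[c.id] = c
    audit = pd.DataFrame(
        rows, columns=["compound", "name", "OB", "DL", "verdict", "clause"]
    )
    return passed, audit


@dataclass
class GroupDescriptorStats:
    """Role-wise descriptor summary plus ANOVA and pairwise tests."""

    summary: pd.DataFrame  # role x descriptor mean/sd/n
    anova: pd.DataFrame  # descriptor, F, p
    pairwise: pd.DataFrame  # descriptor, role_a, role_b, t, p
    warnings: list[str] = field(default_factory=list)


def group_descriptor_stats(
    compounds: dict[str, Compound] | list[Compound],
    role_of: dict[str, Role],
    descriptors: list[str] | None = None,
    welch: bool = False,
) -> GroupDescriptorStats:
    """Per-role descriptor means/SDs with one-way ANOVA across roles.

    A compound contained in herbs of several roles contributes to each such
    role's group (the groups overlap).  SD is the sample SD (ddof=1).
    Pairwise comparisons are pooled-variance two-sample t-tests unless
    ``welch`` is set.  Roles with fewer than two compounds are excluded
    from the tests with a warning.
    """
    descriptors = descriptors or DESCRIPTOR_COLUMNS
    comps = list(compounds.values()) if isinstance(compounds, dict) else list(compounds)

    groups: dict[Role, list[Compound]] = {r: [] for r in Role}
    for c in comps:
        seen: set[Role] = set()
        for h in c.herbs:
            if h not in role_of:
                raise KeyError(f"herb {h!r} has no role assignment")
            seen.add(role_of[h])
        for r in seen:
            groups[r].append(c)

    warns: list[str] = []
    usable = {}
    for r, members in groups.items():
        if len(members) < 2:
            warns.append(f"role {r.value}: fewer than 2 compounds; statistics suppressed")
        else:
            usable[r] = members

    summary_rows = []
    for r, members in groups.items():
        for d in descriptors:
            vals = np.array([getattr(c, d) for c in members], dtype=float)
            summary_rows.append(
                {
                    "role": r.value,
                    "descriptor": d,
                    "n": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    summary = pd.DataFrame(summary_rows)

    anova_rows, pair_rows = [], []
    for d in descriptors:
        samples = {
            r: np.array([getattr(c, d) for c in members], dtype=float)
            for r, members in usable.items()
        }
        if len(samples) >= 2:
            F, p = one_way_anova(list(samples.values()))
            anova_rows.append({"descriptor": d, "F": F, "p": p})
            for ra, rb in combinations(samples, 2):
                t, pt = sps.ttest_ind(samples[ra], samples[rb], equal_var=not welch)
                pair_rows.append(
                    {
                        "descriptor": d,
                        "role_a": ra.value,
                        "role_b": rb.value,
                        "t": float(t),
                        "p": float(pt),
                    }
                )
    return GroupDescriptorStats(
        summary=summary,
        anova=pd.DataFrame(anova_rows, columns=["descriptor", "F", "p"]),
        pairwise=pd.DataFrame(
            pair_rows, columns=["descriptor", "role_a", "role_b", "t", "p"]
        ),
        warnings=warns,
    )
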