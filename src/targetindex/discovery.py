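"""Co-expression discovery of target-associated probe sets.

Per discovery cohort, every probe is Pearson-correlated against the target
probe's expression row, the extreme tails (default the most and least 1%
of probes) are taken as that cohort's positive and negative candidate
sets, and the per-cohort sets are intersected into a consensus signed
index: a probe enters the index only if it falls in the same tail in every
cohort. Pearson correlation is invariant to per-probe affine rescaling, so
discovery may run on raw log2 intensities or z-scores interchangeably.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from math import floor
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationTable:
    """Pearson r of every probe against one target probe, in one cohort."""

    cohort_id: str
    target_probe_id: str
    entries: pd.Series = field(repr=False)  # probe_id -> r

    def __post_init__(self) -> None:
        r = self.entries.to_numpy()
        if r.size and (not np.isfinite(r).all() or np.abs(r).max() > 1 + 1e-12):
            raise ValueError("correlations must be finite and in [-1, 1]")


@dataclass
class TargetIndexDefinition:
    """A signed index: disjoint positive (P) and negative (N) probe sets
    around a target probe, with optional per-cohort provenance."""

    target_probe_id: str
    positive_set: frozenset[str]
    negative_set: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positive_set = frozenset(self.positive_set)
        self.negative_set = frozenset(self.negative_set)
        if self.positive_set & self.negative_set:
            raise ValueError("P and N must be disjoint")
        if not (self.positive_set or self.negative_set):
            raise ValueError("no consensus probes: both P and N are empty")

    @property
    def contains_target(self) -> bool:
        return self.target_probe_id in (self.positive_set | self.negative_set)

    def all_probes(self) -> set[str]:
        return set(self.positive_set) | set(self.negative_set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_probe": self.target_probe_id,
            "positive": sorted(self.positive_set),
            "negative": sorted(self.negative_set),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetIndexDefinition":
        d = json.loads(Path(path).read_text())
        return cls(
            target_probe_id=d["target_probe"],
            positive_set=frozenset(d["positive"]),
            negative_set=frozenset(d["negative"]),
            provenance=d.get("provenance", {}),
        )


def correlate_all_probes(m: ExpressionMatrix, target_probe: str) -> CorrelationTable:
    """Pearson r of every probe row against the target row.

    Zero-variance probes have no defined correlation and are excluded with
    a warning. Requires at least 3 samples.
    """
    if target_probe not in m.values.index:
        raise KeyError(f"target probe {target_probe!r} not in cohort {m.cohort_id!r}")
    if m.n_samples < 3:
        raise ValueError(f"need >=3 samples for correlation, got {m.n_samples}")
    X = m.values.to_numpy()
    t = m.values.loc[target_probe].to_numpy()
    tc = t - t.mean()
    t_norm = np.sqrt((tc**2).sum())
    if t_norm == 0:
        raise ValueError(f"target probe {target_probe!r} has zero variance")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        logger.warning(
            "cohort %s: excluding %d zero-variance probes from correlation",
            m.cohort_id, int(flat.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ tc) / (norms * t_norm)
    r = np.clip(r, -1.0, 1.0)
    entries = pd.Series(r, index=m.values.index)[~flat]
    return CorrelationTable(cohort_id=m.cohort_id, target_probe_id=target_probe, entries=entries)


def select_extremes(ct: CorrelationTable, fraction: float) -> tuple[set[str], set[str]]:
    """Top and bottom correlation tails of size ``k = max(1, floor(fraction * n))``.

    All probes are ranked once by (r, probe id); the bottom set is the
    first k and the top set the last k of that ranking, so boundary ties
    resolve deterministically by probe id and the two sets are always
    disjoint (fraction < 0.5 forces 2k <= n).
    """
    if not (0.0 < fraction < 0.5):
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    if ct.entries.empty:
        raise ValueError("empty correlation table")
    n = len(ct.entries)
    k = max(1, floor(fraction * n))
    order = sorted(ct.entries.items(), key=lambda kv: (kv[1], kv[0]))
    bottom = {probe for probe, _ in order[:k]}
    top = {probe for probe, _ in order[-k:]}
    return top, bottom


def build_index(
    per_cohort: list[tuple[set[str], set[str]]],
    target_probe: str,
    include_target: bool = True,
) -> TargetIndexDefinition:
    """Intersect per-cohort tails into a consensus signed index.

    P is the intersection of all top sets, N of all bottom sets. A probe
    landing in the top tail of one cohort and the bottom tail of another is
    a sign conflict and is excluded from both (logged). The target probe
    correlates 1 with itself so it always survives P; ``include_target``
    controls whether it is kept.
    """
    if not per_cohort:
        raise ValueError("need at least one cohort")
    P = set(per_cohort[0][0])
    N = set(per_cohort[0][1])
    any_top: set[str] = set()
    any_bottom: set[str] = set()
    for top, bottom in per_cohort:
        any_top |= set(top)
        any_bottom |= set(bottom)
    for top, bottom in per_cohort[1:]:
        P &= set(top)
        N &= set(bottom)
    # a probe in the top tail of one cohort and the bottom tail of another
    # has no consistent sign and is dropped from both sets
    conflicts = any_top & any_bottom
    if conflicts:
        logger.warning("excluding %d sign-conflicted probes: %s", len(conflicts), sorted(conflicts))
        P -= conflicts
        N -= conflicts
    if not include_target:
        P.discard(target_probe)
        N.discard(target_probe)
    provenance = {
        "n_cohorts": len(per_cohort),
        "per_cohort": [
            {"top": sorted(top), "bottom": sorted(bottom)} for top, bottom in per_cohort
        ],
        "sign_conflicts": sorted(conflicts),
        "include_target": include_target,
    }
    return TargetIndexDefinition(
        target_probe_id=target_probe,
        positive_set=frozenset(P),
        negative_set=frozenset(N),
        provenance=provenance,
    )


def signature_overlap(idx: TargetIndexDefinition, other: list[str]) -> int:
    """Number of index probes shared with another signature's probe list."""
    return len(idx.all_probes() & set(other))
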