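"""Per-patient index scores.

The index score of a patient is the mean z-scored expression over the
positive probe set minus the mean over the negative set:

    score = (1/n_P) * sum_{i in P} x_i  -  (1/n_N) * sum_{j in N} x_j

where x is per-dataset z-scored expression and n_P, n_N count the set
members actually present on the platform. Because inputs are z-scores the
score is centered near 0 over a standardization cohort; higher values mean
transcription consistent with higher target activity. No responder
threshold is attached to the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import TargetIndexDefinition
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class IndexScores:
    """Scalar index values per sample."""

    index_name: str
    scores: pd.Series = field(repr=False)  # sample_id -> score

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in scores")
        if len(self.scores) and not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("scores must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def score_index(
    m: ExpressionMatrix,
    idx: TargetIndexDefinition,
    index_name: str | None = None,
    min_coverage: float = 0.5,
) -> IndexScores:
    """Compute the index score for every sample of a standardized matrix.

    Set members absent from the platform are dropped and the achieved
    coverage fraction logged. A set that is present but below
    ``min_coverage`` aborts (likely the wrong matrix); a set entirely
    absent contributes 0 with a warning (a platform without those probes
    can still be scored by the other set). Both sets absent is an error, as
    is an unstandardized matrix — the formula presumes z-scores.
    """
    if not m.standardized:
        raise ValueError("score_index requires a standardized matrix (z-scores)")
    name = index_name or f"{idx.target_probe_id}-index"

    def set_term(members: frozenset[str], label: str) -> pd.Series | None:
        if not members:
            return None
        present = m.values.index[m.values.index.isin(members)]
        coverage = len(present) / len(members)
        if coverage == 0.0:
            logger.warning("%s: %s set entirely absent from %s; term set to 0",
                           name, label, m.cohort_id)
            return None
        if coverage < min_coverage:
            raise ValueError(
                f"{name}: {label} set coverage {coverage:.2f} below minimum {min_coverage}"
            )
        if coverage < 1.0:
            logger.info("%s: %s set coverage %.2f (%d/%d probes)",
                        name, label, coverage, len(present), len(members))
        return m.values.loc[present].mean(axis=0)

    pos = set_term(idx.positive_set, "positive")
    neg = set_term(idx.negative_set, "negative")
    if pos is None and neg is None:
        raise ValueError(f"{name}: no index probes present in cohort {m.cohort_id!r}")
    zero = pd.Series(0.0, index=m.values.columns)
    scores = (pos if pos is not None else zero) - (neg if neg is not None else zero)
    return IndexScores(index_name=name, scores=scores.astype(float))


def combine_indices(parts: list[IndexScores], rule: str = "sum") -> IndexScores:
    """Combine single-target indices into a multi-agent index.

    The default rule is the unweighted per-sample sum; ``"mean"`` averages
    instead. All parts must cover exactly the same samples.
    """
    if not parts:
        raise ValueError("nothing to combine")
    if rule not in {"sum", "mean"}:
        raise ValueError(f"unknown combination rule {rule!r}")
    base = set(parts[0].scores.index)
    for p in parts[1:]:
        diff = base ^ set(p.scores.index)
        if diff:
            raise ValueError(f"sample mismatch between indices: {sorted(diff)[:5]}")
    total = parts[0].scores.copy()
    for p in parts[1:]:
        total = total + p.scores.reindex(total.index)
    if rule == "mean":
        total = total / len(parts)
    return IndexScores(index_name=" + ".join(p.index_name for p in parts), scores=total)


def write_scores(s: IndexScores, path: str | Path) -> None:
    df = pd.DataFrame({
        "sample_id": s.scores.index,
        "index_name": s.index_name,
        "score": [repr(float(v)) for v in s.scores],
    })
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> IndexScores:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["score"] = df["score"].astype(float)
    names = df["index_name"].unique()
    if len(names) != 1:
        raise ValueError(f"expected one index per file, found {list(names)}")
    return IndexScores(
        index_name=str(names[0]),
        scores=pd.Series(df["score"].to_numpy(), index=pd.Index(df["sample_id"], name="sample_id")),
    )
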