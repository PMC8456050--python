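"""Connectivity-style single-agent ranking against a disease pathway signature.

The disease's significantly dysregulated pathways are selected with a
two-sided z cutoff (2.58, the normal quantile for p < 0.01), and every
compound instance is scored by the Pearson correlation of its pathway
z-scores with the disease's on that subset. Strong *anticorrelation*
(score near -1) marks a compound whose transcriptional response reverses
the disease signature — the therapeutic candidates — so the ranking is
ascending by score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .enrichment import PathwaySignature

__all__ = [
    "DEFAULT_Z_THRESHOLD",
    "DiseasePathwaySet",
    "RankedCompounds",
    "RankedRow",
    "select_disease_pathways",
    "single_agent_score",
    "rank_compounds",
    "pearson_on_pathways",
]

#: two-sided normal cutoff for p < 0.01 (Phi^-1(0.995) = 2.5758... -> 2.58)
DEFAULT_Z_THRESHOLD = 2.58

#: minimum number of overlapping pathways for a Pearson score to be defined
MIN_PATHWAYS = 3


@dataclass(frozen=True)
class DiseasePathwaySet:
    """Significantly dysregulated pathways of a disease signature."""

    disease_id: str
    selected: tuple[str, ...]
    z_disease: Mapping[str, float]
    threshold: float = DEFAULT_Z_THRESHOLD

    def __post_init__(self) -> None:
        bad = [p for p in self.selected if abs(self.z_disease[p]) < self.threshold]
        if bad:
            raise ValueError(f"selected pathways below threshold: {bad[:5]}")


class RankedRow(NamedTuple):
    rank: int
    id: str
    cell_context: str
    score: float


@dataclass(frozen=True)
class RankedCompounds:
    """Compound instances sorted ascending by score (rank 1 = most anticorrelated)."""

    rows: tuple[RankedRow, ...]
    skipped: Mapping[str, str] = field(default_factory=dict)

    def rank_of(self, signature_id: str) -> int:
        for row in self.rows:
            if row.id == signature_id:
                return row.rank
        raise KeyError(signature_id)

    def score_of(self, signature_id: str) -> float:
        for row in self.rows:
            if row.id == signature_id:
                return row.score
        raise KeyError(signature_id)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=RankedRow._fields)


def select_disease_pathways(
    disease_sig: PathwaySignature, threshold: float = DEFAULT_Z_THRESHOLD
) -> DiseasePathwaySet:
    """Pathways of the disease signature with ``|z_net| >= threshold``."""
    selected = tuple(
        sorted(p for p, z in disease_sig.z_net.items() if abs(z) >= threshold)
    )
    if not selected:
        raise ValueError(
            f"no pathway reaches |z| >= {threshold}; "
            "review the threshold or the disease signature"
        )
    return DiseasePathwaySet(
        disease_id=disease_sig.owner,
        selected=selected,
        z_disease=dict(disease_sig.z_net),
        threshold=threshold,
    )


def pearson_on_pathways(
    compound_z: Mapping[str, float],
    disease_z: Mapping[str, float],
    pathways: Sequence[str],
    min_pathways: int = MIN_PATHWAYS,
) -> tuple[float | None, str]:
    """Pearson r of compound vs disease z restricted to ``pathways``.

    Pathways missing from the compound signature (dropped as zero-variance
    during enrichment) contribute z = 0 so every compound is scored on the
    same vector. Returns ``(score, reason)``; ``score`` is ``None`` with a
    reason when fewer than ``min_pathways`` of the subset carry a disease
    value or when either restricted vector has zero variance.
    """
    usable = [p for p in pathways if p in disease_z]
    if len(usable) < min_pathways:
        return None, f"only {len(usable)} of >= {min_pathways} required pathways"
    x = np.array([compound_z.get(p, 0.0) for p in usable])
    y = np.array([disease_z[p] for p in usable])
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None, "zero variance on the restricted pathway vector"
    r = float(np.corrcoef(x, y)[0, 1])
    return r, ""


def _score_vector(sig: PathwaySignature, directional: bool) -> Mapping[str, float]:
    if not directional:
        return sig.z_net
    # sensitivity-analysis variant: concatenate the two directional scores
    merged: dict[str, float] = {}
    for p, z in sig.z_up.items():
        merged[f"{p}\x00up"] = z
    for p, z in sig.z_down.items():
        merged[f"{p}\x00down"] = -z
    return merged


def single_agent_score(
    compound_sig: PathwaySignature,
    dps: DiseasePathwaySet,
    directional: bool = False,
) -> tuple[float | None, str]:
    """Pearson r between a compound's and the disease's pathway z-scores.

    Restricted to the disease's selected pathways; more negative = stronger
    predicted reversal. With ``directional=True`` the correlation is computed
    on the concatenated per-direction scores instead of ``z_net``
    (sensitivity-analysis variant).
    """
    if not directional:
        return pearson_on_pathways(compound_sig.z_net, dps.z_disease, dps.selected)
    pathways = [f"{p}\x00up" for p in dps.selected] + [
        f"{p}\x00down" for p in dps.selected
    ]
    disease = _score_vector_from_dps(dps)
    return pearson_on_pathways(
        _score_vector(compound_sig, True), disease, pathways
    )


def _score_vector_from_dps(dps: DiseasePathwaySet) -> Mapping[str, float]:
    merged: dict[str, float] = {}
    for p in dps.selected:
        merged[f"{p}\x00up"] = dps.z_disease[p]
        merged[f"{p}\x00down"] = dps.z_disease[p]
    return merged


def rank_compounds(
    signatures: Iterable[PathwaySignature],
    dps: DiseasePathwaySet,
    directional: bool = False,
) -> RankedCompounds:
    """Rank compound instances ascending by single-agent score.

    Instances with undefined scores are omitted with a recorded reason; ties
    are broken by signature id for determinism.
    """
    scored: list[tuple[float, str, str]] = []
    skipped: dict[str, str] = {}
    for sig in signatures:
        score, reason = single_agent_score(sig, dps, directional=directional)
        if score is None:
            skipped[sig.owner] = reason
        else:
            scored.append((score, sig.owner, sig.cell_context))
    if not scored:
        raise ValueError("no compound signature could be scored against the disease")
    scored.sort(key=lambda t: (t[0], t[1]))
    rows = tuple(
        RankedRow(rank=i + 1, id=sid, cell_context=ctx, score=score)
        for i, (score, sid, ctx) in enumerate(scored)
    )
    return RankedCompounds(rows=rows, skipped=skipped)
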