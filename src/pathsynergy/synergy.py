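"""Synergy-partner scoring from the anchor drug's unreversed pathways.

Given an anchor drug (here: gemcitabine) that already ranks well as a single
agent, its effect on the disease's dysregulated pathways is partitioned into

* ACPs — anticorrelated pathways, where the anchor's pathway z-score has the
  opposite sign to the disease's (the anchor reverses them), and
* CPs — correlated pathways, where anchor and disease move in the same
  direction (the anchor fails to reverse them; hypothesised to carry
  residual resistance).

A synergistic partner should reverse the CPs. Candidate partners are scored
by the Pearson correlation of their pathway z-scores with the disease's,
restricted to the CP set of a given anchor instance (Score1 for instance 1,
Score2 for instance 2) or to the resistance subset — CPs that are
significantly dysregulated only in the focal (most resistant) cell line and
in none of the comparator lines (Res-score). More negative = more promising.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .enrichment import PathwaySignature
from .ranking import (
    DEFAULT_Z_THRESHOLD,
    DiseasePathwaySet,
    pearson_on_pathways,
)

__all__ = [
    "CPPartition",
    "ResistancePathwaySet",
    "partition_cp_acp",
    "combination_score",
    "resistance_pathways",
    "res_score",
]


@dataclass(frozen=True)
class CPPartition:
    """Exact partition of the disease's selected pathways for one anchor instance.

    ``acp`` — anchor reverses (opposite sign, anchor |z| above threshold);
    ``cp`` — anchor correlates (same sign, anchor |z| above threshold);
    ``undetermined`` — anchor is silent (below threshold or missing).
    """

    anchor_id: str
    acp: frozenset[str]
    cp: frozenset[str]
    undetermined: frozenset[str]

    def __post_init__(self) -> None:
        sets = (self.acp, self.cp, self.undetermined)
        total = sum(len(s) for s in sets)
        union = self.acp | self.cp | self.undetermined
        if total != len(union):
            raise ValueError("acp, cp and undetermined must be pairwise disjoint")


@dataclass(frozen=True)
class ResistancePathwaySet:
    """Anchor CPs significant only in the focal cell line ('resistance signature')."""

    focal_cell: str
    others: tuple[str, ...]
    pathways: frozenset[str]


def partition_cp_acp(
    anchor_sig: PathwaySignature,
    dps: DiseasePathwaySet,
    compound_threshold: float = DEFAULT_Z_THRESHOLD,
) -> CPPartition:
    """Split the disease's selected pathways by the anchor's sign and strength.

    A selected pathway is CP when the anchor's ``z_net`` has the same sign as
    the disease's and ``|z_anchor| >= compound_threshold``, ACP when the signs
    are opposite at the same strength, and undetermined otherwise. With
    ``compound_threshold=0`` every non-zero anchor score is classified by
    sign alone.
    """
    if not (set(dps.selected) & set(anchor_sig.z_net)):
        raise ValueError(
            f"anchor {anchor_sig.owner!r} carries none of the selected disease pathways"
        )
    acp: set[str] = set()
    cp: set[str] = set()
    undetermined: set[str] = set()
    for p in dps.selected:
        z_a = anchor_sig.z_net.get(p, 0.0)
        z_d = dps.z_disease[p]
        if abs(z_a) < compound_threshold or z_a == 0.0:
            undetermined.add(p)
        elif (z_a > 0) == (z_d > 0):
            cp.add(p)
        else:
            acp.add(p)
    return CPPartition(
        anchor_id=anchor_sig.owner,
        acp=frozenset(acp),
        cp=frozenset(cp),
        undetermined=frozenset(undetermined),
    )


def combination_score(
    candidate_sig: PathwaySignature,
    dps: DiseasePathwaySet,
    subset: Iterable[str],
) -> tuple[float | None, str]:
    """Pearson r of candidate vs disease z-scores on a pathway subset.

    ``subset`` is typically the CP set of an anchor instance (Score1/Score2),
    an explicit user-supplied pathway list ("selected score"), or the
    resistance set. Pathways missing from the candidate score as z = 0.
    Returns ``(score, reason)`` with ``score=None`` when fewer than three
    subset pathways are scorable or a restricted vector has zero variance.
    """
    subset = sorted(set(subset))
    return pearson_on_pathways(candidate_sig.z_net, dps.z_disease, subset)


def resistance_pathways(
    focal_dps: DiseasePathwaySet,
    other_sigs: Sequence[PathwaySignature],
    partitions: Sequence[CPPartition],
    threshold: float = DEFAULT_Z_THRESHOLD,
) -> ResistancePathwaySet:
    """CPs dysregulated in the focal cell line and in none of the others.

    Takes the union of the anchor instances' CP sets and keeps the pathways
    with ``|z_focal| >= threshold`` that stay below ``threshold`` in every
    comparator cell line's disease signature. An empty result is returned
    (not raised): the Res-score is then undefined.
    """
    if not other_sigs:
        raise ValueError("at least one other cell-line pathway signature is required")
    if not partitions:
        raise ValueError("at least one anchor CP partition is required")
    cp_union: set[str] = set()
    for part in partitions:
        cp_union |= part.cp
    result = set()
    for p in cp_union:
        z_focal = focal_dps.z_disease.get(p, 0.0)
        if abs(z_focal) < threshold:
            continue
        if all(abs(sig.z_net.get(p, 0.0)) < threshold for sig in other_sigs):
            result.add(p)
    return ResistancePathwaySet(
        focal_cell=focal_dps.disease_id,
        others=tuple(sig.owner for sig in other_sigs),
        pathways=frozenset(result),
    )


def res_score(
    candidate_sig: PathwaySignature,
    focal_dps: DiseasePathwaySet,
    rps: ResistancePathwaySet,
) -> tuple[float | None, str]:
    """Combination score restricted to the resistance pathway set."""
    if not rps.pathways:
        return None, "empty resistance pathway set"
    return combination_score(candidate_sig, focal_dps, rps.pathways)
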