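"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the shapes of the real inputs — a 978-gene landmark
universe, a few hundred pathway gene sets, 50-up/50-down compound
signatures, case-vs-normal contrasts, and 8x8 dose checkerboards — with
known planted structure:

* :func:`make_disease` shifts the log2 fold changes of all genes of chosen
  pathways by ±delta over standard-normal background noise, so those
  pathways become significantly dysregulated after enrichment;
* :func:`make_compound_library` builds compound signatures by role — full
  reversers, anchor-like partial reversers with declared ACP/CP subsets,
  CP-only reversers (partner-like), resistance-subset reversers, and random
  decoys — by placing genes of the targeted pathways into the opposing (or,
  for correlation, matching) signature direction;
* :func:`make_dose_matrix` simulates checkerboards under a Bliss-null,
  Loewe-null (sham self-combination) or uniformly boosted synergy model.

Everything is bit-reproducible given a seed, and the planted structure is
exposed as machine-readable truth objects / sidecar tables consumed by the
recovery tests. The noise model is deliberately minimal — standard-normal
log2fc background and uniform filler genes — a stand-in that exercises every
scoring path, not a model of real L1000 noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .combination import DoseMatrix, HillFit
from .enrichment import BackgroundModel, build_background, enrich
from .ranking import rank_compounds, select_disease_pathways
from .signatures import ExpressionContrast, GeneSignature, PathwayDB, disease_signature
from .synergy import combination_score, partition_cp_acp, res_score, resistance_pathways

__all__ = [
    "GeneratorConfig",
    "DiseaseTruth",
    "Role",
    "make_pathway_db",
    "make_disease",
    "make_compound_library",
    "make_dose_matrix",
    "library_truth_frame",
    "run_recovery_trial",
    "RecoveryOutcome",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic world.

    Defaults mirror the real data shapes: a 978-gene landmark universe,
    200 pathways of 15-25 genes, 50-gene signature halves, and a library of
    8 compound instances. ``effect_strength`` is the fraction of signature
    genes drawn from the targeted (planted) pathways; the remainder is
    uniform filler.
    """

    n_genes: int = 978
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (15, 25)
    signature_size: int = 50
    effect_strength: float = 0.9
    n_compounds: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ValueError("pathway sizes must be positive and fit in the universe")
        if not (0.0 < self.effect_strength <= 1.0):
            raise ValueError("effect_strength must be in (0, 1]")
        for name in ("n_genes", "n_pathways", "signature_size", "n_compounds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DiseaseTruth:
    """Ground-truth sidecar of a planted disease contrast."""

    cell_id: str
    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]
    delta: float

    def direction(self, pathway: str) -> int:
        if pathway in self.planted_up:
            return +1
        if pathway in self.planted_down:
            return -1
        return 0

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.cell_id, p, "up", self.delta) for p in self.planted_up]
        rows += [(self.cell_id, p, "down", self.delta) for p in self.planted_down]
        return pd.DataFrame(rows, columns=["cell_id", "pathway", "direction", "delta"])


@dataclass(frozen=True)
class Role:
    """Construction recipe for one synthetic compound instance.

    ``reverse`` — planted pathways whose disease direction the compound
    opposes; ``correlate`` — planted pathways where it mimics the disease.
    """

    kind: str
    reverse: frozenset[str] = frozenset()
    correlate: frozenset[str] = frozenset()

    @staticmethod
    def decoy() -> "Role":
        return Role("decoy")

    @staticmethod
    def full_reverser() -> "Role":
        return Role("full_reverser")  # targets resolved to all planted pathways

    @staticmethod
    def partial_reverser_acp(acp: Iterable[str], cp: Iterable[str]) -> "Role":
        return Role("partial_reverser_acp", frozenset(acp), frozenset(cp))

    @staticmethod
    def cp_reverser(cp: Iterable[str]) -> "Role":
        return Role("cp_reverser", frozenset(cp))

    @staticmethod
    def res_reverser(res: Iterable[str]) -> "Role":
        return Role("res_reverser", frozenset(res))


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def make_pathway_db(cfg: GeneratorConfig) -> PathwayDB:
    """Random pathway gene sets over the universe (overlaps allowed)."""
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(_gene_names(cfg.n_genes))
    lo, hi = cfg.pathway_size_range
    width = len(str(cfg.n_pathways))
    pathways: dict[str, frozenset[str]] = {}
    for i in range(1, cfg.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"PW{i:0{width}d}"] = frozenset(members.tolist())
    return PathwayDB(pathways, frozenset(genes.tolist()))


def make_disease(
    cfg: GeneratorConfig,
    db: PathwayDB,
    planted_up: Sequence[str],
    planted_down: Sequence[str],
    delta: float = 3.0,
    cell_id: str = "disease",
    seed: int | None = None,
) -> tuple[ExpressionContrast, DiseaseTruth]:
    """Case-vs-normal contrast with planted pathway effects.

    Every gene of a ``planted_up`` pathway receives a +``delta`` shift of its
    log2 fold change over N(0, 1) noise (``planted_down`` analogously with
    -``delta``); genes in both kinds of pathway cancel. Returns the contrast
    and its ground-truth record.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    genes = sorted(db.universe)
    log2fc = rng.standard_normal(len(genes))
    index = {g: i for i, g in enumerate(genes)}
    for name in planted_up:
        for g in db.effective_members(name):
            log2fc[index[g]] += delta
    for name in planted_down:
        for g in db.effective_members(name):
            log2fc[index[g]] -= delta
    contrast = ExpressionContrast(tuple(genes), log2fc, id=cell_id)
    truth = DiseaseTruth(cell_id, tuple(planted_up), tuple(planted_down), delta)
    return contrast, truth


def _draw_from_pathways(
    pathway_genes: list[list[str]],
    budget: int,
    used: set[str],
    rng: np.random.Generator,
) -> list[str]:
    """Round-robin sampling across pathways so coverage is spread evenly."""
    pools = [list(genes) for genes in pathway_genes]
    for pool in pools:
        rng.shuffle(pool)
    picked: list[str] = []
    while len(picked) < budget and any(pools):
        for pool in pools:
            while pool:
                gene = pool.pop()
                if gene not in used:
                    used.add(gene)
                    picked.append(gene)
                    break
            if len(picked) >= budget:
                break
        pools = [p for p in pools if p]
    return picked


def make_compound_library(
    cfg: GeneratorConfig,
    db: PathwayDB,
    truth: DiseaseTruth,
    roles: Mapping[str, Role],
    seed: int | None = None,
) -> list[GeneSignature]:
    """Compound signatures constructed according to their planted roles.

    For a targeted pathway with disease direction up, reversal places its
    genes in the compound's *down* list (and vice versa); correlation places
    them in the matching list. ``effect_strength`` of each 50-gene list comes
    from the targeted pathways (round-robin across pathways), the rest is
    uniform filler outside the planted gene territory; decoys are entirely
    uniform over the universe.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    all_planted = set(truth.planted_up) | set(truth.planted_down)
    planted_genes = set()
    for name in all_planted:
        planted_genes |= db.effective_members(name)
    universe = np.array(sorted(db.universe))
    neutral = np.array(sorted(db.universe - planted_genes))
    n = cfg.signature_size
    n_eff = int(round(cfg.effect_strength * n))

    signatures: list[GeneSignature] = []
    for comp_id in roles:
        role = roles[comp_id]
        if role.kind == "full_reverser":
            reverse, correlate = all_planted, set()
        else:
            reverse, correlate = set(role.reverse), set(role.correlate)
        unknown = (reverse | correlate) - all_planted
        if unknown:
            raise ValueError(f"{comp_id}: role targets unplanted pathways {sorted(unknown)[:3]}")

        used: set[str] = set()
        if role.kind == "decoy":
            draw = rng.choice(universe, size=2 * n, replace=False)
            up, down = list(draw[:n]), list(draw[n:])
        else:
            up_sources = [sorted(db.effective_members(p))
                          for p in sorted(reverse & set(truth.planted_down))]
            up_sources += [sorted(db.effective_members(p))
                           for p in sorted(correlate & set(truth.planted_up))]
            down_sources = [sorted(db.effective_members(p))
                            for p in sorted(reverse & set(truth.planted_up))]
            down_sources += [sorted(db.effective_members(p))
                             for p in sorted(correlate & set(truth.planted_down))]
            up = _draw_from_pathways(up_sources, n_eff, used, rng)
            down = _draw_from_pathways(down_sources, n_eff, used, rng)
            need_up, need_down = n - len(up), n - len(down)
            filler_pool = [g for g in neutral if g not in used]
            filler = rng.choice(np.array(filler_pool), size=need_up + need_down,
                                replace=False)
            up += list(filler[:need_up])
            down += list(filler[need_up:])
        signatures.append(
            GeneSignature(id=comp_id, up=tuple(up), down=tuple(down),
                          cell_context=f"synthetic:{role.kind}")
        )
    return signatures


def library_truth_frame(roles: Mapping[str, Role]) -> pd.DataFrame:
    """Flat ground-truth sidecar (one row per compound) for a role map."""
    rows = [
        (comp_id, role.kind,
         ",".join(sorted(role.reverse)), ",".join(sorted(role.correlate)))
        for comp_id, role in roles.items()
    ]
    return pd.DataFrame(rows, columns=["id", "role", "reverse", "correlate"])


DEFAULT_DOSES = np.array([0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0])


def make_dose_matrix(
    fit_a: HillFit,
    fit_b: HillFit,
    doses_a: np.ndarray | None = None,
    doses_b: np.ndarray | None = None,
    synergy_model: str = "bliss_null",
    boost: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
) -> DoseMatrix:
    """Simulated 8x8 checkerboard under a chosen combination null/planted model.

    ``bliss_null`` — multiplicative independence; ``loewe_null`` — sham
    self-combination (requires ``fit_a`` and ``fit_b`` to be the same curve;
    response evaluated at the summed dose); ``uniform_boost`` — Bliss null
    plus a flat ``boost`` percentage-point synergy on every combination cell.
    """
    da = DEFAULT_DOSES if doses_a is None else np.asarray(doses_a, dtype=float)
    db_ = DEFAULT_DOSES if doses_b is None else np.asarray(doses_b, dtype=float)
    ea = fit_a.effect_at(da)[:, None]
    eb = fit_b.effect_at(db_)[None, :]
    if synergy_model == "bliss_null":
        effect = ea + eb - ea * eb
    elif synergy_model == "loewe_null":
        params_a = (fit_a.e0, fit_a.emax, fit_a.ec50, fit_a.hill)
        params_b = (fit_b.e0, fit_b.emax, fit_b.ec50, fit_b.hill)
        if not np.allclose(params_a, params_b):
            raise ValueError("loewe_null is a sham self-combination: both fits must match")
        effect = fit_a.effect_at(da[:, None] + db_[None, :])
    elif synergy_model == "uniform_boost":
        effect = ea + eb - ea * eb
        effect[1:, 1:] += boost / 100.0
    else:
        raise ValueError(f"unknown synergy_model {synergy_model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        effect = effect + rng.normal(0.0, noise_sd, size=effect.shape)
        effect[0, 0] = 0.0
    effect = np.clip(effect, 0.0, 1.0)
    return DoseMatrix(drug_a=drug_a, drug_b=drug_b, doses_a=da, doses_b=db_,
                      effect=effect)


# ---------------------------------------------------------------------------
# Canonical planted-recovery experiment (used by the recovery tests)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryOutcome:
    """Per-seed outcomes of the planted-recovery experiment."""

    full_reverser_rank: int
    cp_reverser_score1: float
    decoy_score1: tuple[float, ...]
    res_scores: Mapping[str, float]
    res_reverser_is_unique_min: bool
    n_selected: int
    n_cp: int
    n_res: int


def run_recovery_trial(
    seed: int,
    cfg: GeneratorConfig | None = None,
    n_draws: int = 20_000,
    n_decoys: int = 3,
) -> RecoveryOutcome:
    """One full synthetic round trip: plant, enrich, rank, partition, score.

    Plants 6 up- and 6 down-dysregulated pathways in a focal disease line;
    the anchor reverses 4 of them (ACPs) and correlates on the other 8
    (CPs); a 6-pathway resistance subset of the CPs is planted only in the
    focal line and not in a comparator line. The library holds the anchor, a
    full reverser, a CP reverser, a resistance-subset reverser and
    ``n_decoys`` random decoys.
    """
    cfg = cfg or GeneratorConfig()
    cfg = GeneratorConfig(**{**cfg.__dict__, "seed": seed})
    db = make_pathway_db(cfg)
    rng = np.random.default_rng(seed + 10_000)
    names = sorted(db.pathways)
    chosen = list(rng.choice(np.array(names), size=12, replace=False))
    planted_up, planted_down = chosen[:6], chosen[6:]

    acp = set(planted_up[:2]) | set(planted_down[:2])
    cp = set(planted_up[2:]) | set(planted_down[2:])
    res = set(planted_up[2:5]) | set(planted_down[2:5])

    focal, truth = make_disease(cfg, db, planted_up, planted_down,
                                cell_id="FOCAL", seed=seed + 1)
    other, other_truth = make_disease(
        cfg, db,
        [p for p in planted_up if p not in res],
        [p for p in planted_down if p not in res],
        cell_id="OTHER-1", seed=seed + 2,
    )

    roles: dict[str, Role] = {
        "ANCHOR-1": Role.partial_reverser_acp(acp, cp),
        "FULLREV": Role.full_reverser(),
        "CPREV": Role.cp_reverser(cp),
        "RESREV": Role.res_reverser(res),
    }
    for i in range(1, n_decoys + 1):
        roles[f"DECOY-{i}"] = Role.decoy()
    library = make_compound_library(cfg, db, truth, roles, seed=seed + 3)

    background = build_background(db, cfg.signature_size, n_draws=n_draws, seed=seed + 4)
    focal_sig = enrich(disease_signature(focal, cfg.signature_size), db, background)
    other_sig = enrich(disease_signature(other, cfg.signature_size), db, background)
    compound_sigs = {s.id: enrich(s, db, background) for s in library}

    dps = select_disease_pathways(focal_sig)
    ranking = rank_compounds(compound_sigs.values(), dps)
    partition = partition_cp_acp(compound_sigs["ANCHOR-1"], dps)
    rps = resistance_pathways(dps, [other_sig], [partition])

    score1 = {
        cid: combination_score(sig, dps, partition.cp)[0]
        for cid, sig in compound_sigs.items()
    }
    res_scores = {
        cid: res_score(sig, dps, rps)[0] for cid, sig in compound_sigs.items()
    }
    # Competitive set for Res-score uniqueness: compounds whose construction
    # does not already revert a superset of the resistance pathways (the full
    # and CP reversers do by design, so they tie near -1 there trivially).
    competitors = ["ANCHOR-1"] + [f"DECOY-{i}" for i in range(1, n_decoys + 1)]
    defined_res = {c: s for c, s in res_scores.items() if s is not None}
    unique_min = (
        "RESREV" in defined_res
        and all(defined_res["RESREV"] < defined_res[c]
                for c in competitors if c in defined_res)
    )
    return RecoveryOutcome(
        full_reverser_rank=ranking.rank_of("FULLREV"),
        cp_reverser_score1=score1["CPREV"] if score1["CPREV"] is not None else np.nan,
        decoy_score1=tuple(score1[f"DECOY-{i}"] for i in range(1, n_decoys + 1)
                           if score1[f"DECOY-{i}"] is not None),
        res_scores={c: (np.nan if s is None else s) for c, s in res_scores.items()},
        res_reverser_is_unique_min=unique_min,
        n_selected=len(dps.selected),
        n_cp=len(partition.cp),
        n_res=len(rps.pathways),
    )
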