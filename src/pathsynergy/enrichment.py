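"""Monte-Carlo pathway enrichment z-scores for 50-up/50-down gene signatures.

For every pathway *p* the observed overlap count ``N`` between one direction
of a signature and the pathway's members (restricted to the gene universe)
is standardised against a background of random gene sets of the same length
drawn uniformly without replacement from the universe::

    z_p = (N - mu_p) / sigma_p

where ``mu_p`` and ``sigma_p`` are the sample mean and standard deviation of
the overlap counts over ``n_draws`` random sets (20,000 by default). The two
directional scores are combined into a single signed per-pathway value
``z_net = z_up - z_down``: positive when the signature's up-genes are
enriched in the pathway, negative when its down-genes are, which is the
orientation needed for reversal (connectivity-style) comparisons.

Pathways whose background overlap is constant (``sigma_p = 0``; degenerate or
tiny pathways) are excluded from signatures and recorded, never given
infinite scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature, PathwayDB

__all__ = [
    "BackgroundModel",
    "PathwaySignature",
    "build_background",
    "enrich",
    "read_pathway_signature",
    "write_pathway_signature",
]

DEFAULT_N_DRAWS = 20_000


@dataclass(frozen=True)
class BackgroundModel:
    """Per-pathway overlap statistics of random gene sets.

    ``mu[p]`` / ``sigma[p]`` are the sample mean and sd (ddof=1) of the
    overlap count between pathway ``p`` (within ``universe``) and ``n_draws``
    uniform without-replacement draws of ``set_size`` genes from ``universe``.
    """

    universe: frozenset[str]
    set_size: int
    n_draws: int
    seed: int
    mu: Mapping[str, float]
    sigma: Mapping[str, float]
    universe_hash: str = ""

    def degenerate_pathways(self) -> list[str]:
        """Pathways with zero background variance (excluded from signatures)."""
        return sorted(p for p, s in self.sigma.items() if s == 0.0)


@dataclass(frozen=True)
class PathwaySignature:
    """Per-pathway directional enrichment z-scores for one signature.

    ``z_up``, ``z_down`` and ``z_net = z_up - z_down`` share an identical
    pathway key set and contain finite values only; pathways dropped because
    of a zero-variance background are listed in ``excluded``.
    """

    owner: str
    z_up: Mapping[str, float]
    z_down: Mapping[str, float]
    z_net: Mapping[str, float]
    cell_context: str = ""
    excluded: tuple[str, ...] = ()
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = set(self.z_up)
        if set(self.z_down) != keys or set(self.z_net) != keys:
            raise ValueError("z_up/z_down/z_net must share the same pathway keys")
        for name, zmap in (("z_up", self.z_up), ("z_down", self.z_down), ("z_net", self.z_net)):
            values = np.fromiter(zmap.values(), dtype=float, count=len(zmap))
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def pathways(self) -> frozenset[str]:
        return frozenset(self.z_net)

    def to_frame(self) -> pd.DataFrame:
        names = sorted(self.z_net)
        return pd.DataFrame(
            {
                "pathway": names,
                "z_up": [self.z_up[p] for p in names],
                "z_down": [self.z_down[p] for p in names],
                "z_net": [self.z_net[p] for p in names],
            }
        )


def _membership_matrix(
    db: PathwayDB, gene_index: Mapping[str, int]
) -> tuple[list[str], np.ndarray]:
    """Boolean genes x pathways matrix over the universe (sorted pathway order)."""
    names = sorted(db.pathways)
    matrix = np.zeros((len(gene_index), len(names)), dtype=np.float32)
    for j, name in enumerate(names):
        for gene in db.effective_members(name):
            matrix[gene_index[gene], j] = 1.0
    return names, matrix


def build_background(
    db: PathwayDB,
    set_size: int,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    chunk: int = 4000,
) -> BackgroundModel:
    """Monte-Carlo background of random-set overlaps for every pathway.

    Draws ``n_draws`` gene sets of ``set_size`` genes uniformly without
    replacement from ``db.universe`` and accumulates per-pathway overlap
    means and standard deviations. Fully reproducible given ``seed``.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    genes = sorted(db.universe)
    n_genes = len(genes)
    if n_genes < set_size:
        raise ValueError(
            f"universe has {n_genes} genes, smaller than set_size={set_size}"
        )
    gene_index = {g: i for i, g in enumerate(genes)}
    names, membership = _membership_matrix(db, gene_index)

    rng = np.random.default_rng(seed)
    total = np.zeros(len(names))
    total_sq = np.zeros(len(names))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        # without-replacement draw per row: rank random keys, keep the smallest
        keys = rng.random((m, n_genes), dtype=np.float32)
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        indicator = np.zeros((m, n_genes), dtype=np.float32)
        np.put_along_axis(indicator, idx, 1.0, axis=1)
        counts = indicator @ membership  # m x n_pathways
        total += counts.sum(axis=0, dtype=np.float64)
        total_sq += np.square(counts, dtype=np.float64).sum(axis=0)
        done += m

    mean = total / n_draws
    var = (total_sq - n_draws * mean**2) / (n_draws - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    # counts are small integers; wipe numerically-zero variance to exact zero
    sd[sd < 1e-9] = 0.0
    return BackgroundModel(
        universe=frozenset(genes),
        set_size=set_size,
        n_draws=n_draws,
        seed=seed,
        mu=dict(zip(names, mean.tolist())),
        sigma=dict(zip(names, sd.tolist())),
        universe_hash=db.universe_hash(),
    )


def _overlap_counts(genes: Sequence[str], db: PathwayDB, names: Iterable[str]) -> dict[str, int]:
    gene_set = set(genes) & db.universe
    return {name: len(gene_set & db.effective_members(name)) for name in names}


def enrich(
    signature: GeneSignature,
    db: PathwayDB,
    background: BackgroundModel,
    background_down: BackgroundModel | None = None,
) -> PathwaySignature:
    """Convert a gene signature into a per-pathway z-score signature.

    ``background`` must have been built on ``db.universe`` with ``set_size``
    equal to the signature's up-list length; if the down list has a different
    length a second background of matching length is required via
    ``background_down``.
    """
    bg_up = background
    bg_down = background_down if background_down is not None else background
    if bg_up.universe != db.universe or bg_down.universe != db.universe:
        raise ValueError("background was not built on this pathway database's universe")
    if len(signature.up) != bg_up.set_size:
        raise ValueError(
            f"signature {signature.id!r}: up-list length {len(signature.up)} "
            f"does not match background set_size {bg_up.set_size}"
        )
    if len(signature.down) != bg_down.set_size:
        raise ValueError(
            f"signature {signature.id!r}: down-list length {len(signature.down)} "
            f"does not match background set_size {bg_down.set_size}"
        )
    if not (signature.genes & db.universe):
        raise ValueError(
            f"signature {signature.id!r}: no signature gene is in the universe"
        )

    names = sorted(db.pathways)
    n_up = _overlap_counts(signature.up, db, names)
    n_down = _overlap_counts(signature.down, db, names)

    z_up: dict[str, float] = {}
    z_down: dict[str, float] = {}
    z_net: dict[str, float] = {}
    excluded: list[str] = []
    for name in names:
        s_up, s_down = bg_up.sigma[name], bg_down.sigma[name]
        if s_up == 0.0 or s_down == 0.0:
            excluded.append(name)
            continue
        zu = (n_up[name] - bg_up.mu[name]) / s_up
        zd = (n_down[name] - bg_down.mu[name]) / s_down
        z_up[name] = zu
        z_down[name] = zd
        z_net[name] = zu - zd

    meta = {
        "seed": bg_up.seed,
        "n_draws": bg_up.n_draws,
        "set_size": bg_up.set_size,
        "universe_hash": bg_up.universe_hash,
    }
    return PathwaySignature(
        owner=signature.id,
        cell_context=signature.cell_context,
        z_up=z_up,
        z_down=z_down,
        z_net=z_net,
        excluded=tuple(excluded),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Serialization: TSV with a '#'-prefixed header block for provenance
# ---------------------------------------------------------------------------

def write_pathway_signature(sig: PathwaySignature, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# owner={sig.owner}\n")
        fh.write(f"# cell_context={sig.cell_context}\n")
        for key in ("seed", "n_draws", "set_size", "universe_hash"):
            if key in sig.meta:
                fh.write(f"# {key}={sig.meta[key]}\n")
        if sig.excluded:
            fh.write(f"# excluded={','.join(sig.excluded)}\n")
        sig.to_frame().to_csv(fh, sep="\t", index=False)


def read_pathway_signature(path: str | Path) -> PathwaySignature:
    path = Path(path)
    meta: dict[str, object] = {}
    header_lines = 0
    excluded: tuple[str, ...] = ()
    owner, context = path.stem, ""
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            key = key.strip()
            if key == "owner":
                owner = value
            elif key == "cell_context":
                context = value
            elif key == "excluded":
                excluded = tuple(v for v in value.split(",") if v)
            elif key in ("seed", "n_draws", "set_size"):
                meta[key] = int(value)
            else:
                meta[key] = value
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    return PathwaySignature(
        owner=owner,
        cell_context=context,
        z_up=dict(zip(df["pathway"], df["z_up"])),
        z_down=dict(zip(df["pathway"], df["z_down"])),
        z_net=dict(zip(df["pathway"], df["z_net"])),
        excluded=excluded,
        meta=meta,
    )
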