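"""Core domain types: gene signatures, pathway databases and expression contrasts.

The method works on three kinds of objects:

* a :class:`GeneSignature` — the 50 most up- and 50 most down-regulated genes
  of one compound treatment instance (LINCS-L1000 style) or of a disease
  contrast,
* a :class:`PathwayDB` — named gene sets (NCBI-BioSystems style, GMT format)
  together with the gene universe against which random backgrounds are drawn,
* an :class:`ExpressionContrast` — per-gene log2 fold changes of a case
  versus normal comparison, from which the disease signature is derived.

Gene identifiers are matched by exact string comparison after case-folding
and whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "PathwayDB",
    "ExpressionContrast",
    "GmtParseError",
    "normalize_gene",
    "read_gmt",
    "write_gmt",
    "read_signatures",
    "write_signatures",
    "read_contrast",
    "write_contrast",
    "disease_signature",
    "tanimoto",
    "format_percent",
]


def normalize_gene(gene: str) -> str:
    """Canonical form of a gene identifier: trimmed and case-folded."""
    return gene.strip().casefold()


class GmtParseError(ValueError):
    """Raised for malformed GMT input; carries the offending line number."""


@dataclass(frozen=True)
class GeneSignature:
    """Ordered up-/down-regulated gene lists for one compound instance or contrast.

    Parameters
    ----------
    id : str
        Compound-instance or contrast label.
    up, down : tuple of str
        Ordered gene identifiers, most dysregulated first. The two lists are
        disjoint and each identifier appears at most once per list.
    cell_context : str
        Free-text context (cell line, dose, duration).
    """

    id: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    cell_context: str = ""

    def __post_init__(self) -> None:
        up = tuple(normalize_gene(g) for g in self.up)
        down = tuple(normalize_gene(g) for g in self.down)
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        if len(set(up)) != len(up):
            raise ValueError(f"signature {self.id!r}: duplicate genes in 'up'")
        if len(set(down)) != len(down):
            raise ValueError(f"signature {self.id!r}: duplicate genes in 'down'")
        overlap = set(up) & set(down)
        if overlap:
            raise ValueError(
                f"signature {self.id!r}: up/down lists overlap on {sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.up) | frozenset(self.down)


@dataclass(frozen=True)
class PathwayDB:
    """Named gene sets plus the gene universe used for background draws.

    ``universe`` is the set of genes the profiling platform can observe;
    pathway members outside it are allowed in the definitions but are dropped
    before any counting (see :meth:`effective_members`) so observed and
    background overlaps see the same effective pathway sizes.
    """

    pathways: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        pathways = {
            str(name): frozenset(normalize_gene(g) for g in genes)
            for name, genes in self.pathways.items()
        }
        for name, genes in pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has no gene members")
        object.__setattr__(self, "pathways", pathways)
        object.__setattr__(
            self, "universe", frozenset(normalize_gene(g) for g in self.universe)
        )

    def __len__(self) -> int:
        return len(self.pathways)

    def effective_members(self, name: str) -> frozenset[str]:
        """Pathway gene set restricted to the declared universe."""
        return self.pathways[name] & self.universe

    def with_universe(self, universe: Iterable[str]) -> "PathwayDB":
        """Same pathway definitions against a different gene universe."""
        return PathwayDB(dict(self.pathways), frozenset(universe))

    def universe_hash(self) -> str:
        """Stable hex digest of the sorted universe (recorded in output metadata)."""
        import hashlib

        h = hashlib.md5()
        for g in sorted(self.universe):
            h.update(g.encode())
            h.update(b"\n")
        return h.hexdigest()


@dataclass(frozen=True)
class ExpressionContrast:
    """Per-gene log2 fold change of a case-vs-normal comparison."""

    genes: tuple[str, ...]
    log2fc: np.ndarray
    id: str = "contrast"

    def __post_init__(self) -> None:
        genes = tuple(normalize_gene(g) for g in self.genes)
        object.__setattr__(self, "genes", genes)
        values = np.asarray(self.log2fc, dtype=float)
        object.__setattr__(self, "log2fc", values)
        if values.ndim != 1 or len(values) != len(genes):
            raise ValueError("log2fc must be one value per gene")
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique in a contrast")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite log2 fold changes are not allowed")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayDB:
    """Read a GMT file (tab-separated: name, description, genes...).

    Duplicate gene mentions within a line are collapsed. ``universe`` defaults
    to the union of all pathway genes.
    """
    pathways: dict[str, frozenset[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0].strip()
            genes = frozenset(
                normalize_gene(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise GmtParseError(f"{path.name}:{lineno}: pathway {name!r} has no genes")
            if name in pathways:
                raise GmtParseError(f"{path.name}:{lineno}: duplicate pathway name {name!r}")
            pathways[name] = genes
    if universe is None:
        universe = frozenset().union(*pathways.values()) if pathways else frozenset()
    return PathwayDB(pathways, frozenset(universe))


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(db.pathways):
            genes = "\t".join(sorted(db.pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def write_signatures(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    """Write signatures as long-format TSV (id, cell_context, direction, gene)."""
    rows = []
    for sig in signatures:
        for direction, genes in (("up", sig.up), ("down", sig.down)):
            for gene in genes:
                rows.append((sig.id, sig.cell_context, direction, gene))
    pd.DataFrame(rows, columns=["id", "cell_context", "direction", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_signatures(path: str | Path) -> list[GeneSignature]:
    """Read signatures from long-format TSV; preserves within-file gene order."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "direction", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"signature table missing columns: {sorted(missing)}")
    out: list[GeneSignature] = []
    for sig_id, grp in df.groupby("id", sort=False):
        context = str(grp["cell_context"].iloc[0]) if "cell_context" in grp else ""
        up = tuple(grp.loc[grp["direction"] == "up", "gene"])
        down = tuple(grp.loc[grp["direction"] == "down", "gene"])
        out.append(GeneSignature(id=str(sig_id), up=up, down=down, cell_context=context))
    return out


def read_contrast(path: str | Path, id: str = "contrast") -> ExpressionContrast:
    """Read a (gene, log2fc) TSV into an :class:`ExpressionContrast`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if not {"gene", "log2fc"} <= set(df.columns):
        raise ValueError("contrast table needs columns 'gene' and 'log2fc'")
    df = df.dropna(subset=["log2fc"])
    return ExpressionContrast(tuple(df["gene"]), df["log2fc"].to_numpy(float), id=id)


def write_contrast(contrast: ExpressionContrast, path: str | Path) -> None:
    pd.DataFrame({"gene": contrast.genes, "log2fc": contrast.log2fc}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Derivation and similarity
# ---------------------------------------------------------------------------

def disease_signature(contrast: ExpressionContrast, n: int = 50) -> GeneSignature:
    """Top-``n`` over- and underexpressed genes of a case-vs-normal contrast.

    The ``up`` list holds the ``n`` genes with the largest log2 fold change
    (sorted by decreasing value, ties broken by gene identifier); ``down``
    then holds the ``n`` smallest among the *remaining* genes (increasing
    value, same tie rule). Selecting ``down`` from the remainder makes the
    two lists disjoint by construction and keeps the procedure deterministic
    even on heavily tied inputs.
    """
    if n < 1:
        raise ValueError("n must be positive")
    genes = np.asarray(contrast.genes)
    values = contrast.log2fc
    if len(genes) < 2 * n:
        raise ValueError(
            f"need at least {2 * n} genes with finite log2fc, got {len(genes)}"
        )
    order_up = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    up_idx = order_up[:n]
    up_set = set(up_idx)
    order_down = sorted(
        (i for i in range(len(genes)) if i not in up_set),
        key=lambda i: (values[i], genes[i]),
    )
    down_idx = order_down[:n]
    return GeneSignature(
        id=contrast.id,
        up=tuple(genes[i] for i in up_idx),
        down=tuple(genes[i] for i in down_idx),
    )


def tanimoto(a: Iterable[str], b: Iterable[str]) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| of two gene sets."""
    sa = {normalize_gene(g) for g in a}
    sb = {normalize_gene(g) for g in b}
    union = sa | sb
    if not union:
        raise ValueError("tanimoto is undefined for two empty sets")
    return len(sa & sb) / len(union)


def format_percent(fraction: float, digits: int = 1) -> str:
    """Render a fraction as the percentage string used in reports (0.0638 -> '6.4%')."""
    return f"{100.0 * fraction:.{digits}f}%"
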