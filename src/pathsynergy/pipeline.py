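"""Run-configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` (YAML) names the inputs and parameters of one analysis:
pathway GMT, disease contrasts (focal plus comparator cell lines), compound
signature table, anchor instance ids, z thresholds, background size and
seed. :func:`run_pipeline` executes enrichment → disease-pathway selection →
single-agent ranking → CP/ACP partition → Score1/Score2/Res-score and writes
TSV outputs plus a JSON manifest (seed, thresholds, universe hash, package
version) so a run is reproducible byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import DEFAULT_N_DRAWS, build_background, enrich, write_pathway_signature
from .ranking import DEFAULT_Z_THRESHOLD, rank_compounds, select_disease_pathways
from .signatures import disease_signature, read_contrast, read_gmt, read_signatures
from .synergy import combination_score, partition_cp_acp, res_score, resistance_pathways

__all__ = ["RunConfig", "ConfigError", "PipelineError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage (CLI exit code 1)."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters of one full prediction run."""

    gmt: Path
    focal_contrast: Path
    compounds: Path
    focal_cell: str = "FOCAL"
    other_contrasts: dict[str, Path] = field(default_factory=dict)
    assay_universe: Path | None = None
    anchor_instance1: str | None = None
    anchor_instance2: str | None = None
    threshold_disease: float = DEFAULT_Z_THRESHOLD
    threshold_compound: float = DEFAULT_Z_THRESHOLD
    n_draws: int = DEFAULT_N_DRAWS
    set_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_disease <= 0 or self.threshold_compound <= 0:
            raise ConfigError("z thresholds must be positive")
        if self.anchor_instance1 is None:
            raise ConfigError("anchor_instance1 is required for synergy scoring")
        for label, path in self.iter_paths():
            if not Path(path).exists():
                raise ConfigError(f"{label}: file not found: {path}")

    def iter_paths(self):
        yield "gmt", self.gmt
        yield "focal_contrast", self.focal_contrast
        yield "compounds", self.compounds
        for cell, path in self.other_contrasts.items():
            yield f"other_contrasts[{cell}]", path
        if self.assay_universe is not None:
            yield "assay_universe", self.assay_universe

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as err:
            raise ConfigError(f"cannot parse {path}: {err}") from err
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        base = path.parent

        def resolve(p):
            return (base / p).resolve() if p is not None else None

        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("gmt", "focal_contrast", "compounds", "assay_universe"):
            if key in kwargs:
                kwargs[key] = resolve(kwargs[key])
        if "other_contrasts" in kwargs:
            kwargs["other_contrasts"] = {
                cell: resolve(p) for cell, p in kwargs["other_contrasts"].items()
            }
        try:
            return cls(**kwargs)
        except TypeError as err:
            raise ConfigError(f"{path}: {err}") from err


def _stage(name: str):
    """Decorator-free helper: re-raise any stage failure with its stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, (ConfigError, PipelineError)):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full prediction pipeline and write the report bundle.

    Outputs in ``out_dir``: per-signature pathway z-score TSVs, the
    single-agent ``ranking.tsv``, the partner ``scores.tsv`` (Score1, Score2,
    Res-score with the number of pathways behind each), and ``manifest.json``.
    Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load-inputs"):
        db = read_gmt(cfg.gmt)
        focal = read_contrast(cfg.focal_contrast, id=cfg.focal_cell)
        others = {
            cell: read_contrast(path, id=cell)
            for cell, path in cfg.other_contrasts.items()
        }
        compounds = read_signatures(cfg.compounds)
        if not compounds:
            raise PipelineError("[load-inputs] compound signature table is empty")
        ids = {s.id for s in compounds}
        for label, anchor in (("anchor_instance1", cfg.anchor_instance1),
                              ("anchor_instance2", cfg.anchor_instance2)):
            if anchor is not None and anchor not in ids:
                raise ConfigError(f"{label}={anchor!r} not found among compound signatures")

    with _stage("background"):
        compound_bg = build_background(db, cfg.set_size, cfg.n_draws, cfg.seed)
        if cfg.assay_universe is not None:
            assay_genes = [
                line.strip() for line in Path(cfg.assay_universe).read_text().splitlines()
                if line.strip()
            ]
            assay_db = db.with_universe(assay_genes)
            disease_bg = build_background(assay_db, cfg.set_size, cfg.n_draws, cfg.seed)
        else:
            assay_db, disease_bg = db, compound_bg

    with _stage("enrichment"):
        focal_sig = enrich(disease_signature(focal, cfg.set_size), assay_db, disease_bg)
        other_sigs = [
            enrich(disease_signature(c, cfg.set_size), assay_db, disease_bg)
            for c in others.values()
        ]
        compound_sigs = {s.id: enrich(s, db, compound_bg) for s in compounds}
        sig_dir = out / "pathway_signatures"
        sig_dir.mkdir(exist_ok=True)
        write_pathway_signature(focal_sig, sig_dir / f"{focal_sig.owner}.tsv")
        for sig in list(compound_sigs.values()) + other_sigs:
            write_pathway_signature(sig, sig_dir / f"{sig.owner}.tsv")

    with _stage("disease-selection"):
        dps = select_disease_pathways(focal_sig, cfg.threshold_disease)

    with _stage("single-agent-ranking"):
        ranking = rank_compounds(compound_sigs.values(), dps)
        ranking.to_frame().to_csv(out / "ranking.tsv", sep="\t", index=False)

    with _stage("cp-acp-partition"):
        partitions = {}
        for anchor in filter(None, (cfg.anchor_instance1, cfg.anchor_instance2)):
            partitions[anchor] = partition_cp_acp(
                compound_sigs[anchor], dps, cfg.threshold_compound
            )

    with _stage("partner-scoring"):
        rps = None
        if other_sigs:
            rps = resistance_pathways(
                dps, other_sigs, list(partitions.values()), cfg.threshold_disease
            )
        rows = []
        cp1 = partitions.get(cfg.anchor_instance1)
        cp2 = partitions.get(cfg.anchor_instance2)
        for cid, sig in sorted(compound_sigs.items()):
            row: dict[str, object] = {"id": cid, "cell_context": sig.cell_context}
            for label, part in (("score1", cp1), ("score2", cp2)):
                if part is None:
                    row[label], row[f"n_{label}"] = None, 0
                    continue
                score, _ = combination_score(sig, dps, part.cp)
                row[label] = score
                row[f"n_{label}"] = len(part.cp)
            if rps is not None:
                score, _ = res_score(sig, dps, rps)
                row["res_score"] = score
                row["n_res_score"] = len(rps.pathways)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "scores.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_draws": cfg.n_draws,
        "set_size": cfg.set_size,
        "threshold_disease": cfg.threshold_disease,
        "threshold_compound": cfg.threshold_compound,
        "universe_hash": db.universe_hash(),
        "assay_universe_hash": assay_db.universe_hash(),
        "n_pathways": len(db),
        "n_compounds": len(compound_sigs),
        "n_selected_pathways": len(dps.selected),
        "selected_pathways": list(dps.selected),
        "anchors": {
            name: {"acp": sorted(part.acp), "cp": sorted(part.cp),
                   "undetermined": sorted(part.undetermined)}
            for name, part in partitions.items()
        },
        "resistance_pathways": sorted(rps.pathways) if rps is not None else None,
        "skipped_compounds": dict(ranking.skipped),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
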