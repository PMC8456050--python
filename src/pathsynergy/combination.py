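"""Checkerboard combination analysis: dose-response fits and synergy surfaces.

Experimental combination screens are 8x8 dose grids (including dose 0 on
both axes) of growth-inhibition fractions. Monotherapy rows/columns are
fitted with a four-parameter logistic (4PL) curve

    E(d) = e0 + (emax - e0) * d^h / (ec50^h + d^h)

from which GI50/GI90 (doses at 50%/90% inhibition) are solved analytically.
Synergy surfaces are observed-minus-expected inhibition (in percentage
points) under three null models:

* Bliss independence:   expected = Ea + Eb - Ea*Eb,
* Loewe additivity:     expected E solves  da/Da(E) + db/Db(E) = 1  on the
  fitted inverse dose-response curves (dose equivalence),
* HSA (highest single agent): expected = max(Ea, Eb).

A summary score is a weighted sum over surface cells (plain sum by default,
matching a SUM_SYN_WEIGHTED-style aggregate up to the weighting scheme). The
scoring-category comparison (AVG / one-tailed t-test vs single agents / DIV
ratio) operates on a table of per-compound synergy scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseMatrix",
    "HillFit",
    "HillFitError",
    "SynergyResult",
    "fit_hill",
    "hill_curve",
    "bliss_surface",
    "loewe_surface",
    "hsa_surface",
    "summarize_synergy",
    "category_comparison",
    "assign_categories",
    "load_table1",
    "read_dose_matrix",
    "write_dose_matrix",
    "SINGLE_AGENT_CATEGORY",
]

SINGLE_AGENT_CATEGORY = "Single agents"


class HillFitError(RuntimeError):
    """4PL fit failure; carries the residuals of the best attempt."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class DoseMatrix:
    """Checkerboard of growth-inhibition fractions on two ascending dose grids.

    ``effect[i, j]`` is the inhibition fraction at ``doses_a[i]`` of drug A
    and ``doses_b[j]`` of drug B; both grids start at 0 so row 0 / column 0
    are the monotherapy responses and ``effect[0, 0]`` is the untreated
    control (~0 after normalization).
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    effect: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        eff = np.asarray(self.effect, dtype=float)
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "effect", eff)
        for name, grid in (("doses_a", da), ("doses_b", db)):
            if grid[0] != 0.0:
                raise ValueError(f"{name} must include dose 0 first")
            if not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} must be strictly ascending")
        if eff.shape != (len(da), len(db)):
            raise ValueError(
                f"effect shape {eff.shape} does not match dose grids "
                f"({len(da)}, {len(db)})"
            )

    @property
    def mono_a(self) -> np.ndarray:
        """Monotherapy inhibition of drug A (column at dose_b = 0)."""
        return self.effect[:, 0]

    @property
    def mono_b(self) -> np.ndarray:
        """Monotherapy inhibition of drug B (row at dose_a = 0)."""
        return self.effect[0, :]


@dataclass(frozen=True)
class HillFit:
    """Fitted 4PL dose-response curve with analytic GI50/GI90.

    ``gi50``/``gi90`` are ``None`` ("not reached") when the target inhibition
    lies outside the fitted asymptotes or the solved dose exceeds the tested
    range.
    """

    e0: float
    emax: float
    ec50: float
    hill: float
    gi50: float | None
    gi90: float | None
    max_dose: float
    residual_ss: float = 0.0
    degenerate: bool = False

    def effect_at(self, dose) -> np.ndarray:
        return hill_curve(np.asarray(dose, dtype=float), self.e0, self.emax, self.ec50, self.hill)

    def dose_at(self, effect: float) -> float:
        """Inverse curve D(E); raises for effects outside (e0, emax)."""
        if self.emax <= self.e0:
            raise ValueError("degenerate fit has no inverse")
        if not (self.e0 < effect < self.emax):
            raise ValueError(f"effect {effect} outside fitted range ({self.e0}, {self.emax})")
        frac = (effect - self.e0) / (self.emax - effect)
        return self.ec50 * frac ** (1.0 / self.hill)

    def gi_label(self, which: str = "gi50") -> str:
        value = getattr(self, which)
        if value is None:
            return f"> {self.max_dose:g}"
        return f"{value:g}"


def hill_curve(dose: np.ndarray, e0: float, emax: float, ec50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ec50) ** hill, 0.0)
    return e0 + (emax - e0) * ratio / (1.0 + ratio)


def _solve_gi(e0: float, emax: float, ec50: float, hill: float, target: float,
              max_dose: float) -> float | None:
    if not (e0 < target < emax):
        return None
    dose = ec50 * ((target - e0) / (emax - target)) ** (1.0 / hill)
    return dose if dose <= max_dose else None


def fit_hill(doses: Sequence[float], effects: Sequence[float]) -> HillFit:
    """Least-squares 4PL fit of a monotherapy dose-response vector.

    Requires >= 4 dose levels with effects in [0, 1] (inhibition fractions
    after normalization). A flat response degenerates gracefully (constant
    fit, GI50 not reached) instead of erroring; genuine non-convergence
    raises :class:`HillFitError` carrying the residuals.
    """
    d = np.asarray(doses, dtype=float)
    e = np.asarray(effects, dtype=float)
    if len(d) < 4:
        raise ValueError("at least 4 dose levels are required for a 4PL fit")
    if np.any((e < -0.05) | (e > 1.05)):
        raise ValueError("effects must be inhibition fractions in [0, 1]")
    e = np.clip(e, 0.0, 1.0)
    max_dose = float(d.max())

    if np.ptp(e) < 1e-9:
        level = float(e.mean())
        return HillFit(
            e0=level, emax=level, ec50=max_dose if max_dose > 0 else 1.0, hill=1.0,
            gi50=None, gi90=None, max_dose=max_dose, residual_ss=0.0, degenerate=True,
        )

    positive = d[d > 0]
    ec50_guess = float(np.median(positive)) if len(positive) else 1.0
    p0 = [max(float(e.min()), 0.0), np.ptp(e), ec50_guess, 1.0]
    lower = [0.0, 0.0, 1e-9, 0.05]
    upper = [1.0, 1.0, max(max_dose * 1e3, 1.0), 20.0]
    p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, lower, upper)]

    def model(dose, e0, de, ec50, hill):
        return hill_curve(dose, e0, min(e0 + de, 1.0), ec50, hill)

    try:
        popt, _ = optimize.curve_fit(
            model, d, e, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as err:
        residuals = e - model(d, *p0)
        raise HillFitError(f"4PL fit did not converge: {err}", residuals) from err

    e0, de, ec50, hill = popt
    emax = min(e0 + de, 1.0)
    fitted = hill_curve(d, e0, emax, ec50, hill)
    rss = float(np.sum((e - fitted) ** 2))
    return HillFit(
        e0=float(e0), emax=float(emax), ec50=float(ec50), hill=float(hill),
        gi50=_solve_gi(e0, emax, ec50, hill, 0.5, max_dose),
        gi90=_solve_gi(e0, emax, ec50, hill, 0.9, max_dose),
        max_dose=max_dose, residual_ss=rss,
    )


@dataclass(frozen=True)
class SynergyResult:
    """Observed-minus-expected synergy surface and its summary score.

    ``surface`` is in percentage points on the combination grid (the zero-dose
    row/column removed); undefined cells are NaN. ``summary`` is the weighted
    sum of the defined cells.
    """

    model: str
    surface: np.ndarray
    summary: float
    meta: Mapping[str, object] = field(default_factory=dict)


def _check_monotherapy(m: DoseMatrix) -> None:
    if m.effect.shape[0] < 2 or m.effect.shape[1] < 2:
        raise ValueError("dose matrix needs at least one non-zero dose per drug")


def bliss_surface(m: DoseMatrix) -> SynergyResult:
    """Bliss-independence synergy surface: observed - (Ea + Eb - Ea*Eb)."""
    _check_monotherapy(m)
    ea = m.mono_a[1:, None]
    eb = m.mono_b[None, 1:]
    expected = ea + eb - ea * eb
    surface = 100.0 * (m.effect[1:, 1:] - expected)
    return SynergyResult("bliss", surface, _weighted_sum(surface, "sum"),
                         meta={"weighting": "sum"})


def hsa_surface(m: DoseMatrix) -> SynergyResult:
    """Highest-single-agent synergy surface: observed - max(Ea, Eb)."""
    _check_monotherapy(m)
    expected = np.maximum(m.mono_a[1:, None], m.mono_b[None, 1:])
    surface = 100.0 * (m.effect[1:, 1:] - expected)
    return SynergyResult("hsa", surface, _weighted_sum(surface, "sum"),
                         meta={"weighting": "sum"})


def _loewe_expected(da: float, db: float, fit_a: HillFit, fit_b: HillFit,
                    tol: float = 1e-12) -> float:
    """Solve da/Da(E) + db/Db(E) = 1 for the dose-equivalent expected effect."""
    lo = max(fit_a.e0, fit_b.e0)
    hi = min(fit_a.emax, fit_b.emax)
    if hi <= lo:
        return math.nan
    eps = 1e-9 * max(1.0, hi - lo)

    def f(effect: float) -> float:
        return (da / fit_a.dose_at(effect)) + (db / fit_b.dose_at(effect)) - 1.0

    a, b = lo + eps, hi - eps
    fa, fb = f(a), f(b)
    if fa < 0:       # even the weakest joint effect overshoots: expected at floor
        return a
    if fb > 0:       # no root in range: combination exceeds both curves' reach
        return b
    return float(optimize.brentq(f, a, b, xtol=tol, maxiter=200))


def loewe_surface(m: DoseMatrix, fit_a: HillFit, fit_b: HillFit) -> SynergyResult:
    """Loewe-additivity synergy surface from the two monotherapy 4PL fits.

    For each dose pair the expected effect is found by bracketed root-finding
    of the dose-equivalence equation on [max(e0), min(emax)]; cells whose
    expected effect would sit at the bracket edge are clamped there and
    counted in ``meta['clamped']``.
    """
    _check_monotherapy(m)
    if fit_a.degenerate or fit_b.degenerate or fit_a.emax <= fit_a.e0 or fit_b.emax <= fit_b.e0:
        raise ValueError("Loewe expectation requires two invertible monotherapy fits")
    rows, cols = len(m.doses_a) - 1, len(m.doses_b) - 1
    expected = np.full((rows, cols), np.nan)
    clamped = 0
    for i in range(rows):
        for j in range(cols):
            e = _loewe_expected(m.doses_a[i + 1], m.doses_b[j + 1], fit_a, fit_b)
            if math.isnan(e):
                continue
            lo = max(fit_a.e0, fit_b.e0)
            hi = min(fit_a.emax, fit_b.emax)
            if e <= lo + 2e-9 or e >= hi - 2e-9:
                clamped += 1
            expected[i, j] = e
    surface = 100.0 * (m.effect[1:, 1:] - expected)
    return SynergyResult(
        "loewe", surface, _weighted_sum(surface, "sum"),
        meta={"weighting": "sum", "clamped": clamped},
    )


def _weighted_sum(surface: np.ndarray, scheme: str | np.ndarray) -> float:
    cells = surface[np.isfinite(surface)]
    if isinstance(scheme, str):
        if scheme == "sum":
            weights = np.ones_like(cells)
        elif scheme == "mean":
            weights = np.full_like(cells, 1.0 / max(len(cells), 1))
        else:
            raise ValueError(f"unknown weighting scheme {scheme!r}")
    else:
        weights = np.asarray(scheme, dtype=float)[np.isfinite(surface)]
    return float(np.sum(cells * weights))


def summarize_synergy(result: SynergyResult, weights: str | np.ndarray = "sum") -> SynergyResult:
    """Re-summarize a surface under a weighting scheme ('sum', 'mean', or a matrix)."""
    meta = dict(result.meta)
    meta["weighting"] = weights if isinstance(weights, str) else "custom"
    return SynergyResult(result.model, result.surface,
                         _weighted_sum(result.surface, weights), meta)


# ---------------------------------------------------------------------------
# Scoring-category comparison (per-compound synergy score table)
# ---------------------------------------------------------------------------

_CATEGORY_MAP = {
    "res": "Res-score",
    "res-score": "Res-score",
    "score1": "Score1",
    "score2": "Score2",
}


def assign_categories(row: Mapping[str, object]) -> list[str]:
    """Scoring categories for one table row.

    ``score_type`` may list several hypotheses separated by '/', e.g.
    "Res/Score1" counts in both Res-score and Score1; any "Selected ..."
    variant maps to the Selected category; positive controls ("PC") are
    excluded; rows marked single-agent only ('S') with no score type form
    the single-agent reference category.
    """
    score_type = str(row.get("score_type", "") or "").strip()
    single_comb = str(row.get("single_or_comb", "") or "").strip()
    if score_type.upper() == "PC":
        return []
    if not score_type or score_type.upper() in ("NA", "NAN"):
        return [SINGLE_AGENT_CATEGORY] if single_comb == "S" else []
    cats: list[str] = []
    for part in score_type.split("/"):
        part = part.strip()
        if not part:
            continue
        if part.lower().startswith("selected"):
            cats.append("Selected")
        else:
            cats.append(_CATEGORY_MAP.get(part.lower(), part))
    return cats


def category_comparison(
    table: pd.DataFrame,
    score_columns: Sequence[str] = ("loewe_combenefit", "bliss_combenefit"),
    ttest: str = "welch",
) -> pd.DataFrame:
    """Per-category AVG / TTEST / DIV of synergy scores vs the single-agent group.

    For each score column: AVG is the category mean, TTEST the one-tailed
    (category > single agents) two-sample t-test p-value (Welch by default,
    ``ttest='student'`` for the pooled-variance flavor), and DIV the ratio
    AVG_category / AVG_single. Empty categories are omitted with a warning.
    """
    if ttest not in ("welch", "student"):
        raise ValueError("ttest must be 'welch' or 'student'")
    groups: dict[str, dict[str, list[float]]] = {}
    for _, row in table.iterrows():
        for cat in assign_categories(row):
            bucket = groups.setdefault(cat, {c: [] for c in score_columns})
            for col in score_columns:
                value = row.get(col)
                if value is not None and np.isfinite(pd.to_numeric(value, errors="coerce")):
                    bucket[col].append(float(value))
    if SINGLE_AGENT_CATEGORY not in groups:
        raise ValueError("no single-agent reference category in the table")

    single = groups[SINGLE_AGENT_CATEGORY]
    ordered = [c for c in ("Res-score", "Score1", "Score2", "Selected") if c in groups]
    ordered += sorted(set(groups) - set(ordered) - {SINGLE_AGENT_CATEGORY})
    ordered.append(SINGLE_AGENT_CATEGORY)

    records = []
    for cat in ordered:
        rec: dict[str, object] = {"category": cat}
        for col in score_columns:
            values = groups[cat][col]
            if not values:
                import warnings

                warnings.warn(f"category {cat!r} has no values for {col}; omitted")
                rec[f"avg_{col}"] = np.nan
                continue
            avg = float(np.mean(values))
            rec[f"avg_{col}"] = avg
            rec[f"n_{col}"] = len(values)
            if cat != SINGLE_AGENT_CATEGORY:
                ref = single[col]
                res = stats.ttest_ind(
                    values, ref, equal_var=(ttest == "student"), alternative="greater"
                )
                rec[f"ttest_{col}"] = float(res.pvalue)
                rec[f"div_{col}"] = avg / float(np.mean(ref))
        records.append(rec)
    return pd.DataFrame(records).set_index("category")


def load_table1() -> pd.DataFrame:
    """Packaged per-compound synergy score table (prediction scores, GI50/GI90,
    Combenefit Loewe/Bliss summaries) used by the category comparison."""
    path = Path(__file__).parent / "data" / "table1.tsv"
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# Dose-matrix CSV I/O: first row/column are the dose grids in nM
# ---------------------------------------------------------------------------

def write_dose_matrix(m: DoseMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#drug_a={m.drug_a}\n#drug_b={m.drug_b}\n#control=normalized\n")
        fh.write("," + ",".join(f"{d:g}" for d in m.doses_b) + "\n")
        for dose_a, row in zip(m.doses_a, m.effect):
            fh.write(f"{dose_a:g}," + ",".join(f"{v:.6g}" for v in row) + "\n")


def read_dose_matrix(path: str | Path) -> DoseMatrix:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            elif line.strip():
                rows.append(line)
    header = rows[0].split(",")
    doses_b = np.array([float(v) for v in header[1:]])
    doses_a = []
    effect = []
    for line in rows[1:]:
        parts = line.split(",")
        doses_a.append(float(parts[0]))
        effect.append([float(v) for v in parts[1:]])
    return DoseMatrix(
        drug_a=meta.get("drug_a", "drug_a"),
        drug_b=meta.get("drug_b", "drug_b"),
        doses_a=np.array(doses_a),
        doses_b=doses_b,
        effect=np.array(effect),
    )
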