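"""Building and scoring the Molecular Index of Soil Health (MISH).

An index definition is a portable list of (EC, weight, sign) entries per
soil-health indicator (or "overall").  Enzymes are taken from the ensemble
summary: only those with positive gain in at least ``presence_min`` of the
runs survive (stability selection), ranked by average gain, and the top k
are kept.  An enzyme whose scaled abundance correlates negatively
(Spearman) with the indicator is inverted (its scaled value x becomes
1 - x) before averaging, so higher always means healthier.  The score of a
sample is then

    score = 100 * sum_e w_e * x'_e / sum_e w_e,  x'_e = x_e or 1 - x_e,

a gain-weighted mean of scaled, sign-corrected abundances on a 0-100 scale.

The enzyme count k is chosen by sweeping a grid (default 10-100), scoring
samples at each k, regressing the index rating on the indicator rating,
and taking the smallest k whose adjusted R² is within a parsimony
tolerance of the grid maximum; the AIC curve is reported alongside.
Per-indicator definitions merge into an overall index by union, a shared
enzyme keeping the maximum gain (and that indicator's sign) among its
contributors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import EnsembleSummary
from .errors import DataError
from .evaluate import fit_rating_regression
from .profile import FeatureTable

DEFAULT_K_GRID = tuple(range(10, 101, 10))


@dataclass
class IndexEntry:
    ec: str
    weight: float
    sign: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DataError(f"non-positive weight for {self.ec}")
        if self.sign not in (+1, -1):
            raise DataError(f"sign must be +1 or -1, got {self.sign}")


@dataclass
class MishDefinition:
    """A portable index: (EC, weight, sign) entries plus scoring scale."""

    indicator_id: str
    entries: list[IndexEntry]
    scaling_params: dict[str, tuple[float, float]] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ecs = [e.ec for e in self.entries]
        if len(set(ecs)) != len(ecs):
            raise DataError("duplicate ECs in index definition")

    @property
    def k(self) -> int:
        return len(self.entries)

    def to_json(self, path: str | Path) -> None:
        doc = {"indicator_id": self.indicator_id,
               "entries": [asdict(e) for e in self.entries],
               "scaling_params": ({k: list(v) for k, v in
                                   self.scaling_params.items()}
                                  if self.scaling_params else None),
               "provenance": self.provenance}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "MishDefinition":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            indicator_id=doc["indicator_id"],
            entries=[IndexEntry(**e) for e in doc["entries"]],
            scaling_params=({k: (float(v[0]), float(v[1])) for k, v in
                             doc["scaling_params"].items()}
                            if doc.get("scaling_params") else None),
            provenance=doc.get("provenance", {}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])


@dataclass
class SweepResult:
    """Adjusted R² / AIC of index-vs-indicator regression per enzyme count."""

    grid: list[int]
    adj_r2: list[float]
    aic: list[float]
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.grid, "adj_r2": self.adj_r2,
                             "aic": self.aic})


def select_top_enzymes(summary: EnsembleSummary, presence_min: int = 13,
                       k: int = 50) -> pd.DataFrame:
    """Stability-filter and rank enzymes; return the top k with weights.

    Enzymes with positive gain in at least ``presence_min`` runs are ranked
    by average gain (descending); ties break by higher presence count, then
    EC string.  Fewer than k survivors returns them all with a warning.
    """
    if presence_min > summary.n_runs:
        raise DataError(
            f"presence_min {presence_min} exceeds n_runs {summary.n_runs}")
    if k < 1:
        raise DataError("k must be >= 1")
    t = summary.table
    stable = t[t["presence_count"] >= presence_min].copy()
    if stable.empty:
        raise DataError(f"no enzyme present in >= {presence_min} runs")
    stable["_ec"] = stable.index
    stable = stable.sort_values(
        ["average_gain", "presence_count", "_ec"],
        ascending=[False, False, True]).drop(columns="_ec")
    if len(stable) < k:
        warnings.warn(f"only {len(stable)} enzymes pass the stability filter; "
                      f"requested k={k}")
    return stable.head(k)


def assign_signs(features: FeatureTable, rating: pd.Series,
                 ecs: list[str]) -> dict[str, int]:
    """Sign per EC: -1 for negative Spearman correlation with the rating, else +1.

    An undefined correlation (constant feature) defaults to +1 with a warning.
    """
    signs: dict[str, int] = {}
    y = rating.loc[features.data.index].to_numpy(dtype=float)
    for ec in ecs:
        if ec not in features.data.columns:
            raise DataError(f"EC {ec} absent from feature table")
        x = features.data[ec].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"correlation undefined for {ec}; sign set to +1")
            signs[ec] = +1
            continue
        rho = stats.spearmanr(x, y).statistic
        signs[ec] = -1 if rho < 0 else +1
    return signs


def score(definition: MishDefinition, features: FeatureTable) -> pd.Series:
    """Score samples 0-100: gain-weighted mean of sign-corrected scaled values.

    The feature table must already be on the definition's [0, 1] scale.
    ECs missing from the table are imputed as scaled 0 (inversion then
    applies) with a warning listing them.
    """
    if not features.scaled:
        raise DataError("score expects a scaled feature table")
    if not definition.entries:
        raise DataError("empty index definition")
    missing = [e.ec for e in definition.entries
               if e.ec not in features.data.columns]
    if missing:
        warnings.warn(f"ECs missing from feature table imputed as scaled 0: "
                      f"{missing}")
    n = len(features.data)
    num = np.zeros(n)
    wsum = 0.0
    for e in definition.entries:
        x = (features.data[e.ec].to_numpy(dtype=float)
             if e.ec in features.data.columns else np.zeros(n))
        xprime = x if e.sign == +1 else 1.0 - x
        num += e.weight * xprime
        wsum += e.weight
    return pd.Series(100.0 * num / wsum, index=features.data.index,
                     name=f"mish_{definition.indicator_id}")


def build_indicator_index(summary: EnsembleSummary, features: FeatureTable,
                          rating: pd.Series, presence_min: int = 13,
                          k: int = 50, seed: int | None = None
                          ) -> MishDefinition:
    """Compose stability selection and sign assignment into an index definition."""
    top = select_top_enzymes(summary, presence_min=presence_min, k=k)
    signs = assign_signs(features, rating, list(top.index))
    entries = [IndexEntry(ec=ec, weight=float(top.loc[ec, "average_gain"]),
                          sign=signs[ec]) for ec in top.index]
    return MishDefinition(
        indicator_id=str(rating.name) if rating.name else "indicator",
        entries=entries,
        scaling_params=features.scaling_params,
        provenance={"n_runs": summary.n_runs, "presence_min": presence_min,
                    "k": len(entries), "seed": seed})


def sweep_k(summary: EnsembleSummary, features: FeatureTable,
            rating: pd.Series, k_grid: tuple[int, ...] = DEFAULT_K_GRID,
            presence_min: int = 13, tolerance: float = 0.005) -> SweepResult:
    """Sweep the enzyme count, regress index rating on indicator rating per k.

    Chosen k = smallest grid value whose adjusted R² lies within
    ``tolerance`` of the grid maximum (parsimony rule); the AIC curve is
    recorded for inspection.
    """
    if not k_grid:
        raise DataError("k_grid must be non-empty")
    grid = sorted(set(int(k) for k in k_grid))
    adj_r2s, aics = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in grid:
            definition = build_indicator_index(
                summary, features, rating, presence_min=presence_min, k=k)
            s = score(definition, features)
            reg = fit_rating_regression(s.to_numpy(),
                                        rating.loc[s.index].to_numpy())
            adj_r2s.append(reg.adj_r2)
            aics.append(reg.aic)
    best = max(adj_r2s)
    chosen = next(k for k, r in zip(grid, adj_r2s) if r >= best - tolerance)
    return SweepResult(grid=grid, adj_r2=adj_r2s, aic=aics, chosen_k=chosen)


def build_overall_index(definitions: list[MishDefinition],
                        k_per_indicator: int = 50) -> MishDefinition:
    """Merge per-indicator definitions into one overall index.

    Takes the union of each definition's top ``k_per_indicator`` enzymes;
    an enzyme shared between indicators keeps the maximum gain among them,
    and the sign of the indicator contributing that maximum.  Sign
    conflicts are resolved by the same max-gain rule and logged.
    """
    if not definitions:
        raise DataError("no definitions to merge")
    best: dict[str, IndexEntry] = {}
    origin: dict[str, str] = {}
    conflicts: set[str] = set()
    for d in definitions:
        for e in d.entries[:k_per_indicator]:
            if e.ec in best and best[e.ec].sign != e.sign:
                conflicts.add(e.ec)
            if e.ec not in best or e.weight > best[e.ec].weight:
                best[e.ec] = IndexEntry(ec=e.ec, weight=e.weight, sign=e.sign)
                origin[e.ec] = d.indicator_id
    if conflicts:
        warnings.warn(f"{len(conflicts)} shared EC(s) had conflicting signs; "
                      f"max-gain sign used: {sorted(conflicts)[:5]}")
    entries = sorted(best.values(), key=lambda e: (-e.weight, e.ec))
    scaling: dict[str, tuple[float, float]] | None = None
    if any(d.scaling_params for d in definitions):
        scaling = {}
        for d in definitions:
            scaling.update(d.scaling_params or {})
    return MishDefinition(
        indicator_id="overall", entries=entries, scaling_params=scaling,
        provenance={"merged_from": [d.indicator_id for d in definitions],
                    "k_per_indicator": k_per_indicator,
                    "sign_conflicts": sorted(conflicts)})
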