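"""Empirical-distribution-function ratings and soil-health bins.

Indicator values (or residuals from an upstream climate/texture model) are
converted to a 0-100 rating by the right-continuous empirical distribution
function: rating(v) = 100 * (# values <= v) / n.  The maximum therefore
rates 100 and the minimum 100/n, never 0 — the convention of R's ecdf().
Ratings are then grouped into five equidistant bins (very low: 0-20,
low: 20-40, med: 40-60, high: 60-80, very high: 80-100); intervals are
half-open on the right except the top bin, which includes 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

#: Canonical indicator identifiers of the six soil-health regression targets.
STANDARD_INDICATORS = ["ACE", "ActiveC", "AggStab", "Resp", "SOM", "WaterCap"]

BIN_LABELS = ["very low", "low", "med", "high", "very high"]


@dataclass(frozen=True)
class BinScheme:
    """Equidistant rating bins spanning [0, 100]."""

    edges: tuple[float, ...] = (0, 20, 40, 60, 80, 100)
    labels: tuple[str, ...] = tuple(BIN_LABELS)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if not (np.all(np.diff(e) > 0) and e[0] == 0 and e[-1] == 100):
            raise DataError("bin edges must strictly increase from 0 to 100")
        if len(self.labels) != len(self.edges) - 1:
            raise DataError("need exactly one label per bin")


DEFAULT_BINS = BinScheme()


@dataclass
class IndicatorRatings:
    """Samples x indicators matrix of 0-100 ratings with bin labels."""

    ratings: pd.DataFrame
    bins: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    scheme: BinScheme = DEFAULT_BINS

    def __post_init__(self) -> None:
        vals = self.ratings.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise DataError("ratings must lie in [0, 100]")
        if self.bins is None:
            self.bins = self.ratings.apply(
                lambda col: [bin_rating(v, self.scheme) if np.isfinite(v)
                             else None for v in col])
            self.bins.index = self.ratings.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratings.index)

    @property
    def indicator_ids(self) -> list[str]:
        return list(self.ratings.columns)

    def write(self, path: str | Path) -> None:
        self.ratings.to_csv(path, sep="\t", index_label="sample_id",
                            float_format="%.12g")


def ecdf_rating(values: np.ndarray | pd.Series) -> np.ndarray:
    """0-100 ECDF rating of each value: 100 * (# values <= v) / n.

    Ties receive identical ratings; missing values propagate as NaN and are
    excluded from the denominator.  For n distinct values the sorted
    ratings are exactly 100*(1/n, 2/n, ..., n/n).
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = np.isfinite(arr)
    obs = arr[mask]
    n = obs.size
    if n < 2:
        raise DataError("ECDF rating needs at least 2 observed values")
    if np.all(obs == obs[0]):
        warnings.warn("all values identical; every rating is 100")
        out[mask] = 100.0
        return out
    # right-continuous ECDF == 'max' rank / n
    ranks = stats.rankdata(obs, method="max")
    out[mask] = 100.0 * ranks / n
    return out


def bin_rating(rating: float, scheme: BinScheme = DEFAULT_BINS) -> str:
    """Assign a rating to its bin; [lo, hi) intervals, 100 in the top bin."""
    if not 0 <= rating <= 100:
        raise DataError(f"rating {rating} outside [0, 100]")
    edges = np.asarray(scheme.edges)
    idx = int(np.searchsorted(edges[1:-1], rating, side="right"))
    return scheme.labels[idx]


def rate_indicators(values: pd.DataFrame, scheme: BinScheme = DEFAULT_BINS
                    ) -> IndicatorRatings:
    """ECDF-rate each indicator column of a samples x indicators table."""
    rated = values.apply(lambda col: ecdf_rating(col.to_numpy()))
    return IndicatorRatings(ratings=rated, scheme=scheme)


def load_ratings(path: str | Path, transform: bool = False,
                 scheme: BinScheme = DEFAULT_BINS) -> IndicatorRatings:
    """Load a samples x indicators TSV of ratings or raw values.

    With ``transform=True`` the columns are raw indicator values (or model
    residuals) and are ECDF-rated; otherwise they must already be 0-100
    ratings.  Bins are (re)computed either way.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(f"non-numeric cell at sample {df.index[r]!r}, "
                        f"indicator {df.columns[c]!r}")
    df = numeric.astype(float)
    if transform:
        return rate_indicators(df, scheme=scheme)
    vals = df.to_numpy()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise DataError("pre-rated table contains ratings outside [0, 100]")
    return IndicatorRatings(ratings=df, scheme=scheme)
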