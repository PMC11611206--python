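"""Corrected enzyme feature tables from stratified metagenome predictions.

PICRUSt2-style stratified output assigns, to every (sample, taxon, EC
function) triple, the taxon's relative abundance in the sample and the
number of gene copies per genome.  Because taxa differ in 16S rRNA copy
number, raw 16S-derived relative abundances over-represent taxa with many
rRNA operons; the predicted per-taxon 16S copy number is used to correct
for this.  The corrected per-sample relative abundance of an enzyme is

    sum over taxa of  taxon_rel_abund / 100 * genome_function_count / genome_16S_count

This module parses the two PICRUSt2 output dialects (stratified
contributions and marker/NSTI predictions), applies the correction,
min-max scales features, filters by prevalence, and computes the
occurrence analytics (collector's curves, prevalence histograms) used to
judge whether sampling saturated functional richness.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Default header spellings of current PICRUSt2 stratified output.
DEFAULT_CONTRIB_COLUMNS = {
    "sample": "sample",
    "taxon": "taxon",
    "function": "function",
    "taxon_rel_abun": "taxon_rel_abun",
    "genome_function_count": "genome_function_count",
}

#: Default header spellings of marker_predicted_and_nsti.tsv.gz.
DEFAULT_MARKER_COLUMNS = {
    "taxon": "sequence",
    "copy_number": "16S_rRNA_Count",
    "nsti": "metadata_NSTI",
}

_CANONICAL_CONTRIB = ["sample_id", "taxon_id", "function_id",
                      "taxon_rel_abund", "genome_function_count"]


@dataclass
class ContributionTable:
    """Long-format per-(sample, taxon, EC) predicted gene contributions.

    ``data`` has columns sample_id, taxon_id, function_id (EC string,
    possibly with dash placeholders), taxon_rel_abund (percent, [0, 100])
    and genome_function_count (gene copies per genome, >= 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CANONICAL_CONTRIB if c not in self.data.columns]
        if missing:
            raise ConfigurationError(f"contribution table missing columns: {missing}")
        neg = self.data[(self.data["taxon_rel_abund"] < 0)
                        | (self.data["genome_function_count"] < 0)]
        if len(neg):
            raise DataError(
                f"negative abundance or gene count at rows {list(neg.index[:5])}")
        dups = self.data.duplicated(["sample_id", "taxon_id", "function_id"])
        if dups.any():
            raise DataError(
                "duplicated (sample, taxon, function) triplets at rows "
                f"{list(self.data.index[dups][:5])}")
        partial = self.data["function_id"].astype(str).str.contains("-")
        if partial.any():
            logger.warning("%d rows carry partial EC numbers (dash placeholders)",
                           int(partial.sum()))

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def write(self, path: str | Path, column_map: dict | None = None) -> None:
        """Write back out in PICRUSt2 dialect (gzip if path ends in .gz)."""
        cmap = dict(DEFAULT_CONTRIB_COLUMNS)
        if column_map:
            cmap.update(column_map)
        out = self.data.rename(columns={
            "sample_id": cmap["sample"], "taxon_id": cmap["taxon"],
            "function_id": cmap["function"],
            "taxon_rel_abund": cmap["taxon_rel_abun"],
            "genome_function_count": cmap["genome_function_count"]})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class MarkerTable:
    """Per-taxon predicted 16S copy number and NSTI.

    ``nsti_known`` is False when the input lacked an NSTI column; NSTI
    filtering is then disabled and nsti is NaN throughout.
    """

    data: pd.DataFrame  # index taxon_id; columns genome_16S_count, nsti
    nsti_known: bool = True

    def __post_init__(self) -> None:
        bad = self.data[self.data["genome_16S_count"] <= 0]
        if len(bad):
            raise DataError(f"non-positive 16S copy number for taxa {list(bad.index[:5])}")
        if self.nsti_known and (self.data["nsti"] < 0).any():
            raise DataError("negative NSTI values present")


@dataclass
class FeatureTable:
    """Samples x EC-features matrix of non-negative relative abundances.

    Absence is encoded as 0, never NaN.  After min-max scaling the
    per-feature (min, max) pair is persisted in ``scaling_params`` so a
    saved index definition can score new samples on the training scale.
    """

    data: pd.DataFrame  # index sample_id, columns feature ids
    scaled: bool = False
    scaling_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise DataError("feature table contains missing cells")
        if self.scaled:
            if self.scaling_params is None:
                raise DataError("scaled table must carry scaling_params")
            vals = self.data.to_numpy()
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise DataError("scaled values outside [0, 1]")
        elif (self.data.to_numpy() < 0).any():
            raise DataError("negative feature values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def presence_fraction(self) -> pd.Series:
        """Fraction of samples in which each feature is present (> 0)."""
        return (self.data > 0).mean(axis=0)

    def write(self, path: str | Path, params_path: str | Path | None = None) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id",
                         float_format="%.12g")
        if params_path is not None and self.scaling_params is not None:
            with open(params_path, "w") as fh:
                json.dump({k: list(v) for k, v in self.scaling_params.items()},
                          fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path, params_path: str | Path | None = None
             ) -> "FeatureTable":
        data = pd.read_csv(path, sep="\t", index_col="sample_id")
        data.index = data.index.astype(str)
        params = None
        if params_path is not None:
            with open(params_path) as fh:
                params = {k: (float(v[0]), float(v[1]))
                          for k, v in json.load(fh).items()}
        return cls(data=data, scaled=params is not None, scaling_params=params)


@dataclass
class AccumulationCurve:
    """Mean/sd cumulative feature richness over permuted sample orders."""

    n_samples: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_samples": self.n_samples,
                             "mean_richness": self.mean_richness,
                             "sd_richness": self.sd_richness})


@dataclass
class PrevalenceFilterReport:
    retained: list[str] = field(default_factory=list)
    removed: list[str] = field(default_factory=list)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV, transparently handling gzip by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        with gzip.open(path, "rt") as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def parse_stratified_contributions(path: str | Path,
                                   column_map: dict | None = None
                                   ) -> ContributionTable:
    """Parse a PICRUSt2-dialect stratified contribution TSV (optionally gzip).

    ``column_map`` overrides default header names, keyed by the canonical
    roles ``sample, taxon, function, taxon_rel_abun, genome_function_count``.
    """
    cmap = dict(DEFAULT_CONTRIB_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = _read_tsv(path)
    for role, col in cmap.items():
        if col not in raw.columns:
            raise ConfigurationError(
                f"required column '{col}' (role: {role}) not in header "
                f"{list(raw.columns)}")
    data = pd.DataFrame({
        "sample_id": raw[cmap["sample"]].astype(str),
        "taxon_id": raw[cmap["taxon"]].astype(str),
        "function_id": raw[cmap["function"]].astype(str),
        "taxon_rel_abund": pd.to_numeric(raw[cmap["taxon_rel_abun"]]),
        "genome_function_count": pd.to_numeric(raw[cmap["genome_function_count"]]),
    })
    return ContributionTable(data=data)


def parse_marker_predictions(path: str | Path,
                             column_map: dict | None = None) -> MarkerTable:
    """Parse a marker/NSTI prediction TSV (taxon, 16S copy number, NSTI).

    A missing NSTI column is tolerated: a warning is issued and NSTI
    filtering is disabled downstream.
    """
    cmap = dict(DEFAULT_MARKER_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = _read_tsv(path)
    if cmap["taxon"] not in raw.columns:
        # fall back to the first column as the taxon identifier
        cmap["taxon"] = raw.columns[0]
    # accept this package's canonical spellings alongside the PICRUSt2 ones
    if cmap["copy_number"] not in raw.columns and \
            "genome_16S_count" in raw.columns:
        cmap["copy_number"] = "genome_16S_count"
    if cmap["nsti"] not in raw.columns and "nsti" in raw.columns:
        cmap["nsti"] = "nsti"
    if cmap["copy_number"] not in raw.columns:
        raise ConfigurationError(
            f"required column '{cmap['copy_number']}' (16S copy number) "
            f"not in header {list(raw.columns)}")
    nsti_known = cmap["nsti"] in raw.columns
    data = pd.DataFrame({
        "genome_16S_count": pd.to_numeric(raw[cmap["copy_number"]]).to_numpy(),
        "nsti": (pd.to_numeric(raw[cmap["nsti"]]).to_numpy()
                 if nsti_known else np.nan),
    }, index=pd.Index(raw[cmap["taxon"]].astype(str), name="taxon_id"))
    if not nsti_known:
        warnings.warn("marker table has no NSTI column; NSTI filtering disabled")
    return MarkerTable(data=data, nsti_known=nsti_known)


def compute_ec_relative_abundance(contribs: ContributionTable,
                                  markers: MarkerTable,
                                  nsti_max: float = 2.0) -> FeatureTable:
    """Copy-number-corrected EC relative abundances per sample.

    For each (sample, EC) the value is the sum over retained taxa of
    ``taxon_rel_abund / 100 * genome_function_count / genome_16S_count``.
    Taxa with NSTI above ``nsti_max`` are removed first (PICRUSt2's
    conventional quality cutoff is 2.0; override as needed).  Taxa absent
    from the marker table are dropped with a warning.
    """
    if nsti_max <= 0:
        raise ConfigurationError("nsti_max must be > 0")
    df = contribs.data
    known = df["taxon_id"].isin(markers.data.index)
    if not known.all():
        dropped = sorted(df.loc[~known, "taxon_id"].unique())
        warnings.warn(f"{len(dropped)} taxa absent from marker table dropped: "
                      f"{dropped[:5]}...")
        df = df[known]
    if markers.nsti_known:
        ok_taxa = markers.data.index[markers.data["nsti"] <= nsti_max]
        df = df[df["taxon_id"].isin(ok_taxa)]
    if df.empty:
        raise DataError("no contributions remain after NSTI/marker filtering")
    copies = markers.data["genome_16S_count"]
    contrib = (df["taxon_rel_abund"].to_numpy() / 100.0
               * df["genome_function_count"].to_numpy()
               / copies.loc[df["taxon_id"]].to_numpy())
    long = pd.DataFrame({"sample_id": df["sample_id"].to_numpy(),
                         "function_id": df["function_id"].to_numpy(),
                         "value": contrib})
    wide = (long.pivot_table(index="sample_id", columns="function_id",
                             values="value", aggfunc="sum", fill_value=0.0)
            .sort_index(axis=0).sort_index(axis=1))
    wide.columns.name = None
    return FeatureTable(data=wide, scaled=False)


def minmax_scale(table: FeatureTable) -> FeatureTable:
    """Scale each feature to [0, 1]; constant features map to 0 with a warning.

    The per-feature (min, max) pair is persisted so new cohorts can be
    projected onto the training scale with :func:`apply_scaling`.
    """
    if table.scaled:
        raise DataError("table already scaled; refusing double scaling")
    mins = table.data.min(axis=0)
    maxs = table.data.max(axis=0)
    span = maxs - mins
    constant = span == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) scaled to 0")
    safe_span = span.where(~constant, 1.0)
    scaled = (table.data - mins) / safe_span
    scaled.loc[:, constant[constant].index] = 0.0
    params = {f: (float(mins[f]), float(maxs[f])) for f in table.data.columns}
    return FeatureTable(data=scaled, scaled=True, scaling_params=params)


def apply_scaling(table: FeatureTable,
                  params: dict[str, tuple[float, float]]) -> FeatureTable:
    """Project a raw table onto stored (min, max) scaling; clip into [0, 1].

    Features in ``params`` but absent from ``table`` are imputed as scaled
    0 with a warning, so a saved index definition can always be applied.
    """
    if table.scaled:
        raise DataError("table already scaled")
    missing = [f for f in params if f not in table.data.columns]
    if missing:
        warnings.warn(f"{len(missing)} feature(s) absent from new table "
                      f"imputed as scaled 0: {missing[:5]}...")
    cols = {}
    for feat, (lo, hi) in params.items():
        if feat in table.data.columns:
            span = hi - lo
            col = ((table.data[feat] - lo) / span if span > 0
                   else table.data[feat] * 0.0)
            cols[feat] = col.clip(0.0, 1.0)
        else:
            cols[feat] = pd.Series(0.0, index=table.data.index)
    scaled = pd.DataFrame(cols, index=table.data.index)
    return FeatureTable(data=scaled, scaled=True, scaling_params=dict(params))


def prevalence_filter(table: FeatureTable, min_fraction: float = 1 / 3
                      ) -> tuple[FeatureTable, PrevalenceFilterReport]:
    """Retain features present (value > 0) in MORE than ``min_fraction`` of samples.

    The inequality is strict: a feature present in exactly one third of the
    samples is removed at the default threshold.
    """
    if not 0 < min_fraction < 1:
        raise ConfigurationError("min_fraction must lie in (0, 1)")
    frac = table.presence_fraction()
    keep = frac > min_fraction
    report = PrevalenceFilterReport(retained=list(frac.index[keep]),
                                    removed=list(frac.index[~keep]))
    if not keep.any():
        raise DataError(f"prevalence filter at {min_fraction} removed every feature")
    out = FeatureTable(
        data=table.data.loc[:, keep],
        scaled=table.scaled,
        scaling_params=({f: table.scaling_params[f] for f in frac.index[keep]}
                        if table.scaling_params else None))
    return out, report


def collectors_curve(table: FeatureTable, n_permutations: int = 100,
                     seed: int = 0) -> AccumulationCurve:
    """Collector's (accumulation) curve of feature richness.

    For each k, the mean and sd over random sample orderings of the number
    of features observed (> 0) in at least one of the first k samples.
    """
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    presence = (table.data.to_numpy() > 0)
    n = presence.shape[0]
    rng = np.random.default_rng(seed)
    richness = np.empty((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.logical_or.accumulate(presence[order], axis=0)
        richness[p] = seen.sum(axis=1)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean_richness=richness.mean(axis=0),
        sd_richness=richness.std(axis=0, ddof=0),
        n_permutations=n_permutations,
        seed=seed)


def prevalence_histogram(table: FeatureTable, n_bins: int = 5) -> pd.DataFrame:
    """Count features per prevalence bin (presence fraction in [0, 1]).

    Bins are half-open [lo, hi) with the last bin closed at 1.  Features
    never present fall in the first bin and are flagged.
    """
    if n_bins < 1:
        raise ConfigurationError("n_bins must be >= 1")
    frac = table.presence_fraction()
    edges = np.linspace(0, 1, n_bins + 1)
    idx = np.minimum(np.digitize(frac.to_numpy(), edges[1:], right=False),
                     n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    out = pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "n_features": counts})
    out["n_never_present"] = 0
    out.loc[0, "n_never_present"] = int((frac == 0).sum())
    return out
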