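"""Synthetic soil-microbiome datasets with known ground truth.

The generator emulates the statistical shape of a survey-scale predicted
functional profile: per sample, one latent soil-health value per indicator
(standard Gaussian with small climate-zone offsets), a minority of
"signal" enzymes whose scaled abundances track their indicator
monotonically with a target |Spearman| correlation (half of them with a
negative sign by default), and a majority of background enzymes drawn from
a zero-inflated log-normal so that prevalence varies widely across
features, as it does in real occurrence data.  Indicator ratings are the
0-100 ECDF of the latent values plus a little observation noise.

For a target Spearman correlation s between a signal enzyme and its
Gaussian latent, the required Gaussian noise scale uses the bivariate
normal identity rho_spearman = (6/pi) * asin(rho_pearson / 2): invert to
get the Pearson target, then sd = sqrt(1/rho^2 - 1).

A second generator builds taxa-level stratified contribution tables with
known 16S copy numbers, together with the brute-force expected feature
table, so the profile stage can be checked end to end.

Everything is reproducible from a single master seed; sub-generators are
derived with numpy SeedSequence spawning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .profile import ContributionTable, FeatureTable, MarkerTable
from .ratings import IndicatorRatings, ecdf_rating, STANDARD_INDICATORS


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic survey.

    ``signal_strength`` is the target |Spearman| between each signal enzyme
    and its indicator's latent value; ``negative_fraction`` the share of
    signal enzymes correlated negatively.  Background enzymes are
    zero-inflated log-normal with per-enzyme presence probability uniform
    on (bg_presence_lo, bg_presence_hi).
    """

    n_samples: int = 400
    n_ecs: int = 600
    n_signal_ecs: int = 30
    n_indicators: int = 1
    signal_strength: float = 0.5
    negative_fraction: float = 0.5
    noise_sd: float | None = None   # override the calibrated signal noise
    rating_noise_sd: float = 0.05
    n_zones: int = 4
    zone_sd: float = 0.3
    bg_presence_lo: float = 0.05
    bg_presence_hi: float = 0.95
    bg_log_mu: float = -3.0
    bg_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_ecs > self.n_ecs:
            raise ConfigurationError("n_signal_ecs exceeds n_ecs")
        if not 0 <= self.negative_fraction <= 1:
            raise ConfigurationError("negative_fraction must lie in [0, 1]")
        if not 0 < self.signal_strength < 1:
            raise ConfigurationError("signal_strength must lie in (0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted: latents, signal ECs with signs, zones."""

    latent: pd.DataFrame            # samples x indicators
    signal_ecs: dict[str, dict[str, int]]  # indicator -> {ec: true sign}
    zones: pd.Series                # sample -> zone label
    realized_spearman: pd.DataFrame = field(default=None)  # type: ignore

    def all_signal_ecs(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.signal_ecs.values():
            out.update(d)
        return out


def _noise_sd_for_spearman(target: float) -> float:
    """Gaussian noise sd giving |Spearman| ~= target against a N(0,1) latent."""
    rho_pearson = 2 * np.sin(np.pi * target / 6)
    return float(np.sqrt(1.0 / rho_pearson**2 - 1.0))


def _ec_names(n: int) -> list[str]:
    # synthetic EC-like identifiers, zero-padded for stable lexicographic order
    return [f"EC:{1 + i % 6}.{1 + (i // 6) % 9}.{1 + (i // 54) % 9}.{i + 1:04d}"
            for i in range(n)]


def simulate_features(config: SimulationConfig
                      ) -> tuple[FeatureTable, IndicatorRatings, GroundTruth]:
    """Generate a raw feature table, indicator ratings, and ground truth.

    Signal enzymes are assigned to indicators round-robin; each enzyme's
    raw value is a logistic transform of (sign * latent + noise), so its
    Spearman correlation with the latent is unaffected by the transform and
    the feature is present in every sample (signal enzymes model the
    near-ubiquitous core functions an index would be built from).
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rng_latent, rng_sig, rng_bg, rng_rate = (
        np.random.default_rng(s) for s in root.spawn(4))

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    indicators = (STANDARD_INDICATORS[:cfg.n_indicators]
                  if cfg.n_indicators <= len(STANDARD_INDICATORS)
                  else [f"IND{i + 1}" for i in range(cfg.n_indicators)])
    zones = pd.Series([f"zone{1 + i % cfg.n_zones}" for i in range(cfg.n_samples)],
                      index=samples, name="zone")

    zone_offsets = {ind: {f"zone{z + 1}": rng_latent.normal(0, cfg.zone_sd)
                          for z in range(cfg.n_zones)} for ind in indicators}
    latent = pd.DataFrame(index=samples, columns=indicators, dtype=float)
    for ind in indicators:
        base = rng_latent.normal(size=cfg.n_samples)
        latent[ind] = base + zones.map(zone_offsets[ind]).to_numpy()

    ecs = _ec_names(cfg.n_ecs)
    signal_pool = ecs[:cfg.n_signal_ecs]
    noise_pool = ecs[cfg.n_signal_ecs:]
    sd = (cfg.noise_sd if cfg.noise_sd is not None
          else _noise_sd_for_spearman(cfg.signal_strength))

    data = pd.DataFrame(0.0, index=samples, columns=ecs)
    signal_ecs: dict[str, dict[str, int]] = {ind: {} for ind in indicators}
    n_neg = int(round(cfg.n_signal_ecs * cfg.negative_fraction))
    signs = np.array([-1] * n_neg + [+1] * (cfg.n_signal_ecs - n_neg))
    rng_sig.shuffle(signs)
    for j, ec in enumerate(signal_pool):
        ind = indicators[j % len(indicators)]
        sign = int(signs[j])
        raw = sign * latent[ind].to_numpy() + rng_sig.normal(
            scale=sd, size=cfg.n_samples)
        # logistic squash: monotone, keeps Spearman, yields abundance-like values
        data[ec] = 1.0 / (1.0 + np.exp(-raw))
        signal_ecs[ind][ec] = sign

    for ec in noise_pool:
        p = rng_bg.uniform(cfg.bg_presence_lo, cfg.bg_presence_hi)
        present = rng_bg.random(cfg.n_samples) < p
        vals = np.zeros(cfg.n_samples)
        vals[present] = rng_bg.lognormal(cfg.bg_log_mu, cfg.bg_log_sigma,
                                         size=int(present.sum()))
        data[ec] = vals

    ratings = pd.DataFrame(index=samples, columns=indicators, dtype=float)
    for ind in indicators:
        noisy = latent[ind].to_numpy() + rng_rate.normal(
            scale=cfg.rating_noise_sd, size=cfg.n_samples)
        ratings[ind] = ecdf_rating(noisy)

    realized = _realized_spearman(data, latent, signal_ecs)
    low = (realized[realized["spearman"].abs() < 0.5 * cfg.signal_strength]
           if len(realized) else realized)
    if len(low):
        warnings.warn(
            f"{len(low)} signal EC(s) realized |Spearman| below half the "
            f"target {cfg.signal_strength}; check noise settings")

    truth = GroundTruth(latent=latent, signal_ecs=signal_ecs, zones=zones,
                        realized_spearman=realized)
    return FeatureTable(data=data, scaled=False), \
        IndicatorRatings(ratings=ratings), truth


def _realized_spearman(data: pd.DataFrame, latent: pd.DataFrame,
                       signal_ecs: dict[str, dict[str, int]]) -> pd.DataFrame:
    from scipy import stats
    rows = []
    for ind, d in signal_ecs.items():
        for ec, sign in d.items():
            rho = stats.spearmanr(data[ec], latent[ind]).statistic
            rows.append({"indicator": ind, "ec": ec, "true_sign": sign,
                         "spearman": float(rho)})
    return pd.DataFrame(rows, columns=["indicator", "ec", "true_sign",
                                       "spearman"])


def simulate_contributions(n_samples: int = 20, n_taxa: int = 10,
                           n_ecs: int = 15,
                           copy_number_range: tuple[float, float] = (1.0, 8.0),
                           gene_count_mean: float = 2.0,
                           nsti_max_value: float = 0.3,
                           seed: int = 0
                           ) -> tuple[ContributionTable, MarkerTable,
                                      FeatureTable]:
    """Taxa-level stratified contributions with the brute-force expected table.

    Per-sample taxon relative abundances are Dirichlet draws rescaled to
    sum to exactly 100; per-taxon 16S copy numbers are uniform in
    ``copy_number_range``; per-(taxon, EC) gene counts are Poisson.  The
    expected samples x EC feature table is computed by an explicit triple
    loop over (sample, taxon, EC) — an independent oracle for the
    vectorized profile stage.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    taxa = [f"taxon{j + 1:03d}" for j in range(n_taxa)]
    ecs = _ec_names(n_ecs)

    copies = rng.uniform(*copy_number_range, size=n_taxa)
    nsti = rng.uniform(0, nsti_max_value, size=n_taxa)
    genes = rng.poisson(gene_count_mean, size=(n_taxa, n_ecs))
    # every genome carries at least one gene: bump an EC for all-zero taxa
    for j in np.flatnonzero(genes.sum(axis=1) == 0):
        genes[j, rng.integers(n_ecs)] = 1
    rel = rng.dirichlet(np.ones(n_taxa), size=n_samples) * 100.0
    rel = rel / rel.sum(axis=1, keepdims=True) * 100.0  # exact 100 per sample

    rows = []
    for i, s in enumerate(samples):
        for j, t in enumerate(taxa):
            for k, ec in enumerate(ecs):
                if genes[j, k] > 0:
                    rows.append((s, t, ec, rel[i, j], genes[j, k]))
    contrib = ContributionTable(data=pd.DataFrame(
        rows, columns=["sample_id", "taxon_id", "function_id",
                       "taxon_rel_abund", "genome_function_count"]))
    marker = MarkerTable(data=pd.DataFrame(
        {"genome_16S_count": copies, "nsti": nsti},
        index=pd.Index(taxa, name="taxon_id")))

    # brute-force oracle: plain triple loop over the printed equation
    expected = np.zeros((n_samples, n_ecs))
    for i in range(n_samples):
        for j in range(n_taxa):
            for k in range(n_ecs):
                expected[i, k] += rel[i, j] / 100.0 * genes[j, k] / copies[j]
    exp_table = FeatureTable(
        data=pd.DataFrame(expected, index=samples, columns=ecs),
        scaled=False)
    return contrib, marker, exp_table
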