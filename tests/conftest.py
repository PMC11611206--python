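"""Shared fixtures: small synthetic datasets generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mish import ensemble, profile, simulate


@pytest.fixture()
def tiny_contrib_tsv(tmp_path):
    """3-row stratified contribution fixture: 1 sample, 2 taxa, 2 ECs."""
    path = tmp_path / "contrib.tsv"
    path.write_text(
        "sample\ttaxon\tfunction\ttaxon_rel_abun\tgenome_function_count\n"
        "S1\ttaxA\tEC:1.1.1.1\t60.0\t2\n"
        "S1\ttaxA\tEC:2.2.2.2\t60.0\t1\n"
        "S1\ttaxB\tEC:1.1.1.1\t40.0\t3\n")
    return path


@pytest.fixture()
def tiny_marker_tsv(tmp_path):
    path = tmp_path / "marker.tsv"
    path.write_text("sequence\t16S_rRNA_Count\tmetadata_NSTI\n"
                    "taxA\t1.0\t0.05\n"
                    "taxB\t4.0\t0.30\n")
    return path


@pytest.fixture()
def small_dataset():
    """Quick synthetic survey for unit tests (not the acceptance conditions)."""
    cfg = simulate.SimulationConfig(n_samples=80, n_ecs=50, n_signal_ecs=8,
                                    signal_strength=0.6, n_zones=2, seed=42)
    feats, rated, truth = simulate.simulate_features(cfg)
    return feats, rated, truth


@pytest.fixture()
def small_filtered(small_dataset):
    feats, rated, truth = small_dataset
    scaled = profile.minmax_scale(feats)
    filt, _ = profile.prevalence_filter(scaled)
    return filt, rated, truth


@pytest.fixture(scope="session")
def planted_ensemble():
    """Session-scoped planted-signal ensemble at the documented study scale.

    400 samples x 600 ECs with 30 signal enzymes at target |Spearman| 0.5
    across 4 climate zones; 10 independent splits with tuning budget 15.
    Shared by the recovery, sign and held-out-score checks.
    """
    cfg = simulate.SimulationConfig(n_samples=400, n_ecs=600, n_signal_ecs=30,
                                    signal_strength=0.5, n_zones=4, seed=2024)
    feats, rated, truth = simulate.simulate_features(cfg)
    scaled = profile.minmax_scale(feats)
    filt, _ = profile.prevalence_filter(scaled)
    rating = rated.ratings.iloc[:, 0]
    # hold out a stratified 20% for scoring validation
    plans_holdout = ensemble.make_splits(filt.sample_ids, truth.zones,
                                         n_runs=1, test_fraction=0.2,
                                         seed=7)
    train_ids = list(plans_holdout[0].train_ids)
    test_ids = list(plans_holdout[0].test_ids)
    train = profile.FeatureTable(data=filt.data.loc[train_ids],
                                 scaled=True,
                                 scaling_params=filt.scaling_params)
    plans = ensemble.make_splits(train_ids, truth.zones, n_runs=10,
                                 test_fraction=0.2, seed=2024)
    econf = ensemble.EnsembleConfig(n_runs=10, tuning_budget=15, seed=2024)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, summary = ensemble.run_ensemble(train, rating.loc[train_ids],
                                                 plans, econf)
    return {
        "features": filt, "train": train, "test_ids": test_ids,
        "rating": rating, "truth": truth, "results": results,
        "summary": summary,
    }
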