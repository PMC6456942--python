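"""Shared fixtures.

The expensive end-to-end fixture (synthetic epigenome -> encoded dataset ->
cross-validated training of the standard model and both ablations) is
session-scoped so the planted-motif, motif-recovery, and variant tests all
reuse one training run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from histmark.dataset import (
    OpennessTrack,
    build_batch,
    build_site_table,
    call_sites,
)
from histmark.network import NetworkSpec
from histmark.synthetic import (
    SyntheticConfig,
    generate_dnase,
    generate_genome,
    generate_variant_pairs,
    plant_sites,
)
from histmark.training import TrainConfig, run_cv_encoded

# Study conditions for the end-to-end synthetic benchmark: 220 sites per
# marker and a reduced network (16 initial kernels, dense growth 2) that one
# CPU can cross-validate in a few minutes.
PIPELINE_SEED = 2019
SITES_PER_MARKER = 220


def reduced_spec(mode: str = "standard") -> NetworkSpec:
    return NetworkSpec(init_kernels=16, growth=2, head_hidden_sizes=(64,), mode=mode)


def train_config(seed: int, folds: int = 5, max_epochs: int = 12) -> TrainConfig:
    return TrainConfig(
        learning_rate=1e-3,
        batch_size=16,
        max_epochs=max_epochs,
        patience=2,
        folds=folds,
        seed=seed,
        holdout_fraction=0.1,
    )


def build_synthetic_world(seed: int, sites_per_marker: int = SITES_PER_MARKER):
    """Genome + planted sites + DNase track + encoded dataset."""
    config = SyntheticConfig(seed=seed, sites_per_marker=sites_per_marker)
    genome = generate_genome(config)
    genome, peaks, truth = plant_sites(config, genome)
    dnase = generate_dnase(config, truth)
    sizes = {c: len(s) for c, s in genome.items()}
    per_marker = {m: call_sites(pk, sizes) for m, pk in peaks.items()}
    table = build_site_table(per_marker, config.markers, "SYN1")
    track = OpennessTrack(dnase)
    batch = build_batch(genome, track, table)
    return {
        "config": config,
        "genome": genome,
        "peaks": peaks,
        "truth": truth,
        "track": track,
        "table": table,
        "batch": batch,
    }


@pytest.fixture(scope="session")
def trained_pipeline():
    """Simulate, encode, and cross-validate the standard model plus both
    single-branch ablations on one synthetic epigenome."""
    world = build_synthetic_world(PIPELINE_SEED)
    batch = world["batch"]
    cv = run_cv_encoded(batch, reduced_spec("standard"), train_config(PIPELINE_SEED))
    cv_dna = run_cv_encoded(
        batch, reduced_spec("dna_only"), train_config(PIPELINE_SEED + 1, folds=2, max_epochs=5)
    )
    cv_dnase = run_cv_encoded(
        batch, reduced_spec("dnase_only"), train_config(PIPELINE_SEED + 2, folds=2, max_epochs=5)
    )
    variant_marker = world["config"].markers[-1]  # H3K27ac, the haQTL mark
    pos, neg = generate_variant_pairs(
        world["config"], world["genome"], world["truth"], n_pos=50, n_neg=50,
        distance_bp=500, marker=variant_marker,
    )
    return {
        **world,
        "cv": cv,
        "cv_dna": cv_dna,
        "cv_dnase": cv_dnase,
        "variant_marker": variant_marker,
        "variants_pos": pos,
        "variants_neg": neg,
    }


@pytest.fixture
def tiny_spec() -> NetworkSpec:
    """A network small enough for per-test construction."""
    return NetworkSpec(
        seq_len=64, init_kernels=4, growth=2, head_hidden_sizes=(8,), n_markers=7
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
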