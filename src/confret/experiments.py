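"""Repeatable calibration/test experiments on the synthetic generators.

These drive the stochastic validation suite: resample an exchangeable
instance, calibrate a threshold on the calibration split, and measure the
realized loss on the held-out split, over many seeded trials.  Used both by
the acceptance tests and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .conformal_calibration import (
    build_loss_curves,
    crc_threshold,
    ltt_threshold,
)
from .losses import CostVector, MatchSpec
from .synthetic_data import FlatSpec, HierarchySpec, gen_flat_instance, gen_hierarchy_instance

__all__ = [
    "split_calibration_test",
    "rate_control_trials",
    "hierarchical_fnr_trials",
    "hierarchical_certificate_trials",
    "risk_curves",
]


def split_calibration_test(n_total: int, n_cal: int, rng: np.random.Generator):
    """Random exchangeable split of query indices."""
    perm = rng.permutation(n_total)
    return perm[:n_cal], perm[n_cal:]


def _test_loss_at(result, matrix, annotations, spec, loss):
    """Mean held-out loss at the calibrated threshold (single-point grid)."""
    curves = build_loss_curves(
        matrix, annotations, spec, grid=[result.lambda_hat], loss=loss
    )
    return curves.losses[:, 0]


def rate_control_trials(
    n_trials: int = 100,
    seed: int = 0,
    loss: str = "fdr",
    method: str = "ltt",
    alpha: float = 0.1,
    delta: float = 0.1,
    n_cal: int = 300,
    n_test: int = 100,
    n_lookup: int = 2000,
    vocab_size: int = 50,
    grid: int = 200,
    spec_overrides: Optional[dict] = None,
) -> np.ndarray:
    """Mean held-out FDR/FNR per trial for a calibrated threshold.

    Each trial draws a fresh flat instance with ``n_cal + n_test`` queries,
    splits it at random, calibrates with CRC or LTT on the calibration
    split, and evaluates the mean loss on the test split.
    """
    master = np.random.SeedSequence(seed)
    match_spec = MatchSpec(mode="pfam_exact")
    out = np.empty(n_trials)
    for t, child in enumerate(master.spawn(n_trials)):
        rng = np.random.default_rng(child)
        flat = FlatSpec(
            seed=int(rng.integers(2**31)),
            n_query=n_cal + n_test,
            n_lookup=n_lookup,
            vocab_size=vocab_size,
            **(spec_overrides or {}),
        )
        matrix, annotations, _ = gen_flat_instance(flat)
        cal_idx, test_idx = split_calibration_test(flat.n_query, n_cal, rng)
        cal = matrix.subset_queries(cal_idx)
        test = matrix.subset_queries(test_idx)
        curves = build_loss_curves(cal, annotations, match_spec, grid=grid, loss=loss)
        if method == "crc":
            result = crc_threshold(curves, alpha)
        elif method == "ltt":
            result = ltt_threshold(curves, alpha, delta)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[t] = _test_loss_at(result, test, annotations, match_spec, loss).mean()
    return out


def hierarchical_fnr_trials(
    n_trials: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
    n_cal: int = 300,
    n_test: int = 100,
    branching: tuple = (5, 4, 4, 4),
    max_depth: int = 0,
    grid: int = 200,
    spec_overrides: Optional[dict] = None,
) -> np.ndarray:
    """Mean held-out family-level FNR per trial under CRC calibration."""
    master = np.random.SeedSequence(seed)
    match_spec = MatchSpec(mode="hierarchical", max_depth=max_depth)
    out = np.empty(n_trials)
    for t, child in enumerate(master.spawn(n_trials)):
        rng = np.random.default_rng(child)
        hspec = HierarchySpec(
            seed=int(rng.integers(2**31)),
            n_query=n_cal + n_test,
            branching=branching,
            **(spec_overrides or {}),
        )
        matrix, annotations, _ = gen_hierarchy_instance(hspec)
        cal_idx, test_idx = split_calibration_test(hspec.n_query, n_cal, rng)
        cal = matrix.subset_queries(cal_idx)
        test = matrix.subset_queries(test_idx)
        curves = build_loss_curves(cal, annotations, match_spec, grid=grid, loss="fnr")
        result = crc_threshold(curves, alpha)
        out[t] = _test_loss_at(result, test, annotations, match_spec, "fnr").mean()
    return out


def hierarchical_certificate_trials(
    n_trials: int = 100,
    seed: int = 0,
    alpha: float = 1.0,
    n_cal: int = 300,
    n_test: int = 100,
    branching: tuple = (4, 3, 3, 3),
    noise_scale: float = 0.15,
    level_increment: float = 0.25,
    grid: int = 200,
) -> np.ndarray:
    """Pooled held-out hierarchical losses at the CRC threshold over trials.

    The hierarchical max-mismatch loss grows with the retrieval set, so CRC
    runs in the mirrored orientation.  Returns the concatenated test losses
    across all trials (input to the per-level certificate check).
    """
    master = np.random.SeedSequence(seed)
    cost = CostVector.unit()
    match_spec = MatchSpec(mode="hierarchical", cost_vector=cost)
    pooled = []
    for child in master.spawn(n_trials):
        rng = np.random.default_rng(child)
        hspec = HierarchySpec(
            seed=int(rng.integers(2**31)),
            n_query=n_cal + n_test,
            branching=branching,
            noise_scale=noise_scale,
            level_increment=level_increment,
        )
        matrix, annotations, _ = gen_hierarchy_instance(hspec)
        cal_idx, test_idx = split_calibration_test(hspec.n_query, n_cal, rng)
        cal = matrix.subset_queries(cal_idx)
        test = matrix.subset_queries(test_idx)
        curves = build_loss_curves(
            cal, annotations, match_spec, grid=grid, loss="hierarchical"
        )
        result = crc_threshold(curves, alpha)
        pooled.append(
            _test_loss_at(result, test, annotations, match_spec, "hierarchical")
        )
    return np.concatenate(pooled)


def risk_curves(
    seed: int = 0,
    n_query: int = 300,
    n_lookup: int = 1000,
    vocab_size: int = 50,
    grid: int = 100,
):
    """Mean FDR and FNR as a function of the (user-orientation) threshold.

    Returns ``(lambdas ascending, mean_fdr, mean_fnr)`` on one flat
    instance; FDR should fall and FNR rise as the threshold approaches the
    top of the score range.
    """
    # single-label annotations: every query has true matches, so the FNR
    # curve reaches 1 at the restrictive end instead of being diluted by
    # flagged no-match queries
    flat = FlatSpec(
        seed=seed,
        n_query=n_query,
        n_lookup=n_lookup,
        vocab_size=vocab_size,
        labels_per_protein=(1.0,),
    )
    matrix, annotations, _ = gen_flat_instance(flat)
    match_spec = MatchSpec(mode="pfam_exact")
    fdr = build_loss_curves(matrix, annotations, match_spec, grid=grid, loss="fdr")
    fnr = build_loss_curves(matrix, annotations, match_spec, grid=grid, loss="fnr")
    lam = fdr.user_grid()
    order = np.argsort(lam)
    return (
        lam[order],
        fdr.empirical_risk()[order],
        fnr.empirical_risk()[order],
    )
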