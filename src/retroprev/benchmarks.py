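"""Calibration and validation studies over the synthetic generators.

These routines measure how well the pipeline recovers known ground truth:
interval-operation agreement with a brute-force scan, classification fidelity
on synthetic landscapes, Pagel's-lambda and slope recovery, type-I error of
the slope test, lambda-model AIC ordering, and end-to-end power of the full
pipeline. They are used by the analysis drivers and the acceptance script;
the brute-force interval oracles here are deliberately independent of the
sorted-search implementation in :mod:`retroprev.proximity`.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import pgls, pipeline, simulate
from .proximity import GeneRecord, closest_distances, genic_insertion_count
from .repeats import RepeatRecord, count_active

__all__ = [
    "brute_force_closest",
    "brute_force_genic_count",
    "random_interval_instance",
    "interval_oracle_agreement",
    "classification_fidelity",
    "RecoveryResult",
    "lambda_recovery",
    "type_one_error_rate",
    "aic_ordering_rate",
    "end_to_end_power",
]


def brute_force_closest(query, targets) -> int | None:
    """O(m) all-pairs nearest distance; None if no target shares the chromosome."""
    best = None
    for t in targets:
        if t.chrom != query.chrom:
            continue
        if t.start < query.end and t.end > query.start:
            return 0
        gap = max(t.start - query.end, query.start - t.end)
        best = gap if best is None else min(best, gap)
    return best


def brute_force_genic_count(queries, targets) -> int:
    n = 0
    for q in queries:
        if any(t.chrom == q.chrom and t.start < q.end and t.end > q.start for t in targets):
            n += 1
    return n


def random_interval_instance(rng, max_n: int = 200, max_m: int = 200):
    """A random (queries, targets) instance over a few short chromosomes."""
    chroms = ["c1", "c2", "c3"]
    n = int(rng.integers(1, max_n + 1))
    m = int(rng.integers(1, max_m + 1))

    def coords():
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, 10_000))
        return c, s, s + int(rng.integers(1, 500))

    queries = [RepeatRecord(*coords(), "+", "L1", 1.0) for _ in range(n)]
    targets = [GeneRecord(*coords(), f"g{i}") for i in range(m)]
    return queries, targets


def interval_oracle_agreement(n_instances: int = 1000, seed: int = 0,
                              max_n: int = 200, max_m: int = 200) -> float:
    """Fraction of random instances where closest_distances and
    genic_insertion_count both match the brute-force oracles exactly."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        queries, targets = random_interval_instance(rng, max_n, max_m)
        fast, n_skipped = closest_distances(queries, targets)
        expected = [brute_force_closest(q, targets) for q in queries]
        exp_dists = [d for d in expected if d is not None]
        exp_skipped = sum(1 for d in expected if d is None)
        ok = (
            list(fast) == exp_dists
            and n_skipped == exp_skipped
            and genic_insertion_count(queries, targets)
            == brute_force_genic_count(queries, targets)
        )
        agree += ok
    return agree / n_instances


def classification_fidelity(n_landscapes: int = 100, seed: int = 0) -> float:
    """Fraction of synthetic landscapes whose active L1/SINE counts equal the
    generator's ground truth exactly."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_landscapes):
        sub_seed = int(rng.integers(2**31 - 1))
        frac_l1 = float(rng.uniform(0.0, 1.0))
        frac_sine = float(rng.uniform(0.0, 1.0))
        repeats, _, truth = simulate.simulate_repeat_landscape(
            genome_length=600_000, n_genes=20, n_l1=40, n_sine=80,
            active_frac_l1=frac_l1, active_frac_sine=frac_sine, seed=sub_seed,
        )
        counts = count_active(repeats, "sp")
        exact += (
            counts.n_active_l1 == truth.n_active_l1
            and counts.n_active_sine == truth.n_active_sine
            and counts.n_combined == truth.n_active_l1 + truth.n_active_sine
        )
    return exact / n_landscapes


@dataclass
class RecoveryResult:
    lambda_true: float
    mean_lambda_hat: float
    mean_slope_hat: float
    slope_true: float

    @property
    def lambda_bias(self) -> float:
        return self.mean_lambda_hat - self.lambda_true

    @property
    def slope_relative_bias(self) -> float:
        return (self.mean_slope_hat - self.slope_true) / self.slope_true


def _sim_tree_cov(n_tips: int, seed: int):
    tree = simulate.simulate_tree(n_tips, seed=seed)
    return pgls.vcv_from_tree(tree)


def lambda_recovery(lambda_true: float, n_tips: int = 200, n_reps: int = 300,
                    seed: int = 0, slope_true: float = 1.0) -> RecoveryResult:
    """Mean lambda_hat and slope over replicate fits at a known lambda."""
    cov = _sim_tree_cov(n_tips, seed)
    rng = np.random.default_rng(seed + 1)
    X = np.column_stack([np.ones(n_tips), rng.standard_normal(n_tips)])
    beta_true = np.array([0.0, slope_true])
    lam_hats = np.empty(n_reps)
    slopes = np.empty(n_reps)
    for r in range(n_reps):
        y = simulate.simulate_traits(cov.C, lambda_true, 1.0, beta_true, X, None,
                                     seed=int(rng.integers(2**31 - 1)))
        fit = pgls.fit_pgls(y, X, cov.C, lambda_mode="estimate",
                            compute_diagnostics=False)
        lam_hats[r] = fit.lambda_hat
        slopes[r] = fit.beta[1]
    return RecoveryResult(
        lambda_true=lambda_true,
        mean_lambda_hat=float(lam_hats.mean()),
        mean_slope_hat=float(slopes.mean()),
        slope_true=slope_true,
    )


def type_one_error_rate(n_tips: int = 100, n_reps: int = 1000, alpha: float = 0.05,
                        seed: int = 0, lambda_true: float = 0.5) -> float:
    """Rejection rate of the slope t-test under a true null slope."""
    cov = _sim_tree_cov(n_tips, seed)
    rng = np.random.default_rng(seed + 1)
    X = np.column_stack([np.ones(n_tips), rng.standard_normal(n_tips)])
    beta_true = np.array([0.0, 0.0])
    rejections = 0
    for _ in range(n_reps):
        y = simulate.simulate_traits(cov.C, lambda_true, 1.0, beta_true, X, None,
                                     seed=int(rng.integers(2**31 - 1)))
        fit = pgls.fit_pgls(y, X, cov.C, lambda_mode="estimate",
                            compute_diagnostics=False)
        rejections += fit.p_values[1] < alpha
    return rejections / n_reps


def aic_ordering_rate(n_reps: int = 200, n_tips: int = 100, seed: int = 0) -> float:
    """On lambda_true = 0 data, fraction of replicates where the lambda = 1
    model has the worst AIC of the {0, hat, 1} comparison."""
    cov = _sim_tree_cov(n_tips, seed)
    rng = np.random.default_rng(seed + 1)
    X = np.column_stack([np.ones(n_tips), rng.standard_normal(n_tips)])
    worst = 0
    for _ in range(n_reps):
        y = simulate.simulate_traits(cov.C, 0.0, 1.0, np.array([0.0, 0.5]), X, None,
                                     seed=int(rng.integers(2**31 - 1)))
        tab = pgls.compare_lambda_models(y, X, cov.C)
        aics = dict(zip(tab["model"], tab["aic"]))
        worst += aics["lambda_1"] >= max(aics.values())
    return worst / n_reps


def end_to_end_power(n_reps: int = 100, seed: int = 0, n_species: int = 55) -> float:
    """Fraction of full-pipeline replicates recovering a positive,
    FDR-significant effect of combined L1+SINE burden on neoplasia prevalence.

    Each replicate writes a fresh synthetic dataset, runs the configured model
    batch, and checks the abundance-family neoplasia ~ n_combined model.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        with tempfile.TemporaryDirectory() as tmp:
            simulate.simulate_study(
                tmp, seed=rep_seed, n_species=n_species,
                landscape_kwargs={"genome_length": 400_000, "n_genes": 15},
            )
            config = pipeline.load_config(Path(tmp) / "config.yaml")
            config["models"]["families"] = ["abundance"]
            config["models"]["responses"] = ["neoplasia"]
            report = pipeline.run_models(config)
        target = [
            m for m in report["models"]
            if m["predictor"] == "n_combined" and m["response"] == "neoplasia"
            and not m["with_longevity"]
        ]
        m = target[0]
        hits += (
            m.get("status") == "ok"
            and m["slope"] > 0
            and bool(m.get("fdr_significant"))
        )
    return hits / n_reps
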