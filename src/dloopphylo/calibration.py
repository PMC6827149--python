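"""Calibration and power studies for the neutrality tests.

These routines run the package's own simulators and statistics end to
end: the neutral constant-size coalescent as the null (checking the
size of Tajima's D test and the near-zero mean of D and Fs, and the
recovery of theta by Watterson's estimator), and the star-expansion
generator as the alternative (checking that D and Fs go negative and
that the Fs test has power against recent expansion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .popgen import (
    fs_statistic,
    fus_fs,
    tajima_coefficients,
    tajima_d_from_summaries,
    tajima_d_null,
    tajima_d_pvalue,
    tajimas_d,
)
from .simulate import (
    coalescent_mutation_sets,
    simulate_star_sample,
    summarize_mutation_sets,
)


@dataclass
class NullCalibration:
    n: int
    theta: float
    reps: int
    mean_d: float
    mean_fs: float
    watterson_mean: float  # mean of S / a1 across reps
    watterson_se: float


def null_calibration(n: int = 20, theta: float = 5.0, reps: int = 2000,
                     seed: int = 0) -> NullCalibration:
    """Summaries of D, Fs and theta_W over neutral coalescent replicates.

    Under neutrality the means of D and Fs sit near zero (D carries a
    known mild negative bias from its normalization) and S/a1 is an
    unbiased estimator of theta.
    """
    rng = np.random.default_rng(seed)
    a1 = tajima_coefficients(n).a1
    ds, fss, thetas = [], [], []
    for _ in range(reps):
        muts = coalescent_mutation_sets(n, rng, theta=theta)
        k, s, n_hap = summarize_mutation_sets(muts, n)
        if s > 0:
            ds.append(tajima_d_from_summaries(k, s, n))
        fs = fs_statistic(k, n_hap, n)
        if not math.isnan(fs):
            fss.append(fs)
        thetas.append(s / a1)
    thetas = np.asarray(thetas)
    return NullCalibration(
        n, theta, reps, float(np.mean(ds)), float(np.mean(fss)),
        float(np.mean(thetas)),
        float(np.std(thetas, ddof=1) / math.sqrt(reps)))


def d_test_type1_error(n: int = 20, theta: float = 5.0, reps: int = 1000,
                       null_reps: int = 1000, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Empirical size of the two-sided D test under the neutral null.

    p-values come from the fixed-S conditional null; the null
    distribution is cached per observed S, since it depends only on
    (n, S).
    """
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rejections = 0
    tested = 0
    for _ in range(reps):
        muts = coalescent_mutation_sets(n, rng, theta=theta)
        k, s, _ = summarize_mutation_sets(muts, n)
        if s == 0:
            continue
        d = tajima_d_from_summaries(k, s, n)
        if s not in null_cache:
            null_cache[s] = tajima_d_null(n, s, null_reps, rng)
        p = tajima_d_pvalue(d, n, s, null=null_cache[s])
        tested += 1
        if p < alpha:
            rejections += 1
    return rejections / tested if tested else math.nan


@dataclass
class ExpansionPower:
    reps: int
    mean_d: float
    mean_fs: float
    fs_rejection_rate: float
    d_negative_fraction: float


def star_expansion_power(founder_length: int = 431, star_lambda: float = 2.0,
                         n: int = 50, reps: int = 500,
                         null_reps: int = 200, alpha: float = 0.05,
                         transition_bias: float = 0.9,
                         seed: int = 0) -> ExpansionPower:
    """Behaviour of D and Fs on star-expanded samples.

    Each replicate draws a fresh founder and a star sample of ``n``
    lineages with Poisson(star_lambda) private mutations, then computes
    D (no p-value) and Fs with its coalescent p-value.  The expansion
    signature is negative D and Fs, with the Fs test rejecting at rate
    well above ``alpha``.
    """
    rng = np.random.default_rng(seed)
    ds, fss = [], []
    fs_reject = 0
    fs_tested = 0
    for _ in range(reps):
        founder = "".join(rng.choice(list("ACGT"), size=founder_length))
        seqs = simulate_star_sample(founder, n, star_lambda,
                                    transition_bias, rng)
        d_res = tajimas_d(seqs, compute_p=False)
        if not math.isnan(d_res.statistic):
            ds.append(d_res.statistic)
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        pairs = n * (n - 1) / 2
        k = sum(sum(a != b for a, b in zip(seqs[i], seqs[j]))
                for i in range(n) for j in range(i + 1, n)) / pairs
        res = fus_fs(k, len(counts), n, reps=null_reps, seed=rng)
        if not math.isnan(res.statistic):
            fss.append(res.statistic)
            fs_tested += 1
            if res.p_value < alpha and res.statistic < 0:
                fs_reject += 1
    ds = np.asarray(ds)
    return ExpansionPower(
        reps, float(np.mean(ds)), float(np.mean(fss)),
        fs_reject / fs_tested if fs_tested else math.nan,
        float(np.mean(ds < 0)))
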