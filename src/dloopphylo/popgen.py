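"""Diversity and neutrality statistics per population.

Implements the classical summary statistics on an aligned sample of
sequences:

* S, the number of segregating sites (complete deletion: columns with
  any gap or N are excluded);
* K, the mean number of pairwise nucleotide differences, and
  Pi = K / L_effective, the per-site nucleotide diversity (pairwise
  deletion: each pair is compared over its mutually unambiguous
  columns; L_effective is the mean number of such columns per pair, so
  Pi = K / L_effective holds exactly by construction);
* Hd, Nei's haplotype (gene) diversity n(1 - sum p_i^2)/(n - 1) with
  its sampling variance;
* Tajima's D = (theta_pi - theta_W) / sqrt(e1 S + e2 S(S-1)), with a
  two-sided p-value from the neutral coalescent conditioned on the
  observed number of segregating sites (fixed-S mutation placement);
* Fu's Fs = ln(S'/(1 - S')) where S' is the Ewens-sampling probability
  of observing at least the observed number of distinct haplotypes
  given theta_pi, with a one-sided (lower-tail) p-value from the
  neutral coalescent at theta = theta_pi.

Negative D and strongly negative Fs indicate an excess of rare
variants, the signature of recent population expansion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .seqio import AnchoredAlignment
from .simulate import coalescent_mutation_sets, summarize_mutation_sets

logger = logging.getLogger(__name__)

_GOOD = frozenset("ACGT")

DEFAULT_PVALUE_REPS = 10_000


def _as_seqs(alignment: AnchoredAlignment | Sequence[str]) -> list[str]:
    if isinstance(alignment, AnchoredAlignment):
        return alignment.sequences()
    return list(alignment)


def complete_deletion_columns(seqs: Sequence[str]) -> list[int]:
    """Column indices where every sequence has an unambiguous base."""
    L = len(seqs[0])
    return [c for c in range(L) if all(s[c] in _GOOD for s in seqs)]


def segregating_sites(alignment: AnchoredAlignment | Sequence[str]) -> int:
    """Number of polymorphic columns under complete deletion."""
    seqs = _as_seqs(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    cols = complete_deletion_columns(seqs)
    return sum(1 for c in cols if len({s[c] for s in seqs}) > 1)


class DiversityResult(NamedTuple):
    pi: float
    k: float
    l_effective: float


def nucleotide_diversity(alignment: AnchoredAlignment | Sequence[str]
                         ) -> DiversityResult:
    """Mean pairwise differences K and per-site diversity Pi.

    Pairwise deletion: each pair (i, j) is compared over the columns
    where both carry A/C/G/T; d_ij counts substitution differences.
    K is the mean of d_ij over all C(n,2) pairs, L_effective the mean
    number of compared columns, and Pi = K / L_effective.
    """
    seqs = _as_seqs(alignment)
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    # per-column allele counting: sum over columns of (comparable pairs)
    # and (differing pairs) equals the pair-by-pair tallies exactly
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
    total_d = 0
    total_l = 0
    counts = {b: (mat == b.encode()).sum(axis=0) for b in "ACGT"}
    good = sum(counts.values())
    total_l = int((good * (good - 1) // 2).sum())
    same = sum(c * (c - 1) // 2 for c in counts.values())
    total_d = total_l - int(same.sum())
    pairs = n * (n - 1) // 2
    k = total_d / pairs
    l_eff = total_l / pairs
    pi = k / l_eff if l_eff > 0 else 0.0
    return DiversityResult(pi, k, l_eff)


def haplotype_diversity(counts: Sequence[int],
                        n: int | None = None) -> tuple[float, float]:
    """Nei's haplotype diversity and its standard deviation.

    Hd = n (1 - sum p_i^2) / (n - 1); the variance is Nei's
    small-sample formula
    Var = 2/(n(n-1)) { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                       + sum p_i^2 - (sum p_i^2)^2 }.
    """
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"counts sum to {total}, not n={n}")
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2")
    p = np.asarray(counts, dtype=float) / n
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    hd = n * (1.0 - s2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return hd, math.sqrt(max(var, 0.0))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator theta_W = S / a1, a1 = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return S / tajima_coefficients(n).a1 if S else 0.0


@dataclass(frozen=True)
class NeutralityCoefficients:
    """The constants of Tajima's variance normalization."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=None)
def tajima_coefficients(n: int) -> NeutralityCoefficients:
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return NeutralityCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d_from_summaries(k: float, S: int, n: int) -> float:
    """Tajima's D from K, S and n (D = 0 when S = 0, by convention)."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return 0.0
    co = tajima_coefficients(n)
    var = co.e1 * S + co.e2 * S * (S - 1)
    return (k - S / co.a1) / math.sqrt(var)


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    note: str = ""


def tajima_d_null(n: int, S: int, reps: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Null distribution of D: coalescent genealogies with exactly S
    mutations placed proportionally to branch length."""
    out = np.empty(reps)
    for r in range(reps):
        muts = coalescent_mutation_sets(n, rng, n_mutations=S)
        k_sim, s_sim, _ = summarize_mutation_sets(muts, n)
        out[r] = tajima_d_from_summaries(k_sim, s_sim, n)
    return out


def tajima_d_pvalue(d_obs: float, n: int, S: int,
                    reps: int = DEFAULT_PVALUE_REPS,
                    rng: np.random.Generator | None = None,
                    null: np.ndarray | None = None) -> float:
    """Two-sided Monte-Carlo p-value for Tajima's D.

    Doubles the smaller tail of the conditional (fixed-S) null
    distribution; a precomputed ``null`` sample may be supplied to
    amortize simulations across tests sharing (n, S).
    """
    if null is None:
        if rng is None:
            rng = np.random.default_rng()
        null = tajima_d_null(n, S, reps, rng)
    lo = float(np.mean(null <= d_obs))
    hi = float(np.mean(null >= d_obs))
    return min(1.0, 2.0 * min(lo, hi))


def tajimas_d(alignment: AnchoredAlignment | Sequence[str],
              reps: int = DEFAULT_PVALUE_REPS,
              seed: int | np.random.Generator | None = None,
              compute_p: bool = True) -> TestResult:
    """Tajima's D with a simulation-based two-sided p-value.

    Both K and S are computed over complete-deletion columns so the
    statistic is internally consistent.  Conventions: D = 0 with p = NA
    when S = 0; NA for n < 4 (the variance terms vanish).
    """
    seqs = _as_seqs(alignment)
    n = len(seqs)
    if n < 4:
        return TestResult(math.nan, math.nan,
                          f"n={n} < 4: Tajima's D undefined")
    cols = complete_deletion_columns(seqs)
    sub = ["".join(s[c] for c in cols) for s in seqs]
    S = sum(1 for c in range(len(cols))
            if len({s[c] for s in sub}) > 1)
    if S == 0:
        return TestResult(0.0, math.nan, "S=0: monomorphic sample")
    pairs = n * (n - 1) // 2
    mat = np.frombuffer("".join(sub).encode(), dtype="S1").reshape(n, -1)
    same = sum(((mat == b.encode()).sum(axis=0) *
                ((mat == b.encode()).sum(axis=0) - 1) // 2).sum()
               for b in "ACGT")
    k = (pairs * len(cols) - int(same)) / pairs
    d = tajima_d_from_summaries(k, S, n)
    if not compute_p:
        return TestResult(d, math.nan)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return TestResult(d, tajima_d_pvalue(d, n, S, reps, rng))


# ---------------------------------------------------------------------------
# Fu's Fs


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |S1(n, k)| for k = 0..n (unsigned Stirling, first kind),
    by the recurrence |S1(n,k)| = |S1(n-1,k-1)| + (n-1)|S1(n-1,k)|
    evaluated in log space."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |S1(0,0)| = 1
    for m in range(1, n + 1):
        shifted = np.concatenate(([-np.inf], row[:-1]))  # |S1(m-1, k-1)|
        if m > 1:
            row = np.logaddexp(shifted, math.log(m - 1) + row)
        else:
            row = shifted
    return row


def ewens_prob_at_least(k_obs: int, theta: float, n: int) -> float:
    """S' = P(number of alleles >= k_obs | theta, n) under the Ewens
    sampling formula: sum_k |S1(n,k)| theta^k / theta^(n) (rising)."""
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must lie in [1, n]")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    logs = _log_stirling_row(n)
    lt = math.log(theta)
    terms = logs[1:n + 1] + lt * np.arange(1, n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_upper = _logsumexp(terms[k_obs - 1:])
    return math.exp(log_upper - log_rising)


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    if not math.isfinite(m):
        return m
    return m + math.log(float(np.sum(np.exp(x - m))))


def fs_statistic(k_mean: float, k_obs: int, n: int) -> float:
    """Fu's Fs = ln(S'/(1 - S')), theta estimated by theta_pi = K.

    Undefined (NaN) when k_obs = 1 or K = 0 (S' = 1 degenerates the
    log-odds); the tails are evaluated in log space to avoid underflow.
    """
    if k_obs <= 1 or k_mean <= 0:
        return math.nan
    logs = _log_stirling_row(n)
    lt = math.log(k_mean)
    terms = logs[1:n + 1] + lt * np.arange(1, n + 1)
    log_rising = sum(math.log(k_mean + i) for i in range(n))
    log_upper = _logsumexp(terms[k_obs - 1:]) - log_rising
    log_lower = _logsumexp(terms[:k_obs - 1]) - log_rising
    return log_upper - log_lower


def fus_fs(k_mean: float, k_obs: int, n: int,
           reps: int = DEFAULT_PVALUE_REPS,
           seed: int | np.random.Generator | None = None,
           compute_p: bool = True) -> TestResult:
    """Fu's Fs with a coalescent p-value conditioned on n and theta_pi.

    The p-value is the fraction of neutral constant-size coalescent
    replicates (theta = K) whose Fs is <= the observed Fs; replicates
    with undefined Fs (monomorphic) cannot be more extreme and count
    against rejection.  By Fu's convention Fs is judged significant at
    p < 0.02 for a nominal 5% test; both thresholds are reported by
    :func:`population_summary`.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    fs = fs_statistic(k_mean, k_obs, n)
    if math.isnan(fs):
        return TestResult(math.nan, math.nan,
                          "k_obs=1 or K=0: Fs undefined")
    if not compute_p:
        return TestResult(fs, math.nan)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    hits = 0
    for _ in range(reps):
        muts = coalescent_mutation_sets(n, rng, theta=k_mean)
        k_sim, _, hap_sim = summarize_mutation_sets(muts, n)
        fs_sim = fs_statistic(k_sim, hap_sim, n)
        if not math.isnan(fs_sim) and fs_sim <= fs:
            hits += 1
    return TestResult(fs, hits / reps)


# ---------------------------------------------------------------------------
# Per-population report


def population_summary(alignment: AnchoredAlignment | Sequence[str],
                       metadata: pd.DataFrame,
                       sample_ids: Sequence[str] | None = None,
                       reps: int = DEFAULT_PVALUE_REPS,
                       seed: int | None = 0,
                       alpha: float = 0.05,
                       fs_alpha: float = 0.02) -> pd.DataFrame:
    """One row of diversity + neutrality statistics per population.

    Columns mirror the classical per-population table: n, S, number of
    haplotypes, Hd with SD, Pi, K, Tajima's D with p, Fu's Fs with p,
    and significance stars at ``alpha`` (a second star column applies
    Fu's stricter 0.02 convention for Fs).  Populations with fewer than
    2 samples are skipped with a log line.
    """
    if isinstance(alignment, AnchoredAlignment):
        seqs = alignment.sequences()
        ids = list(alignment.samples)
    else:
        seqs = list(alignment)
        ids = list(sample_ids) if sample_ids is not None else None
    if ids is None:
        raise ValueError("sample_ids required for a plain sequence list")
    label = dict(zip(metadata["sample_id"], metadata["population"]))
    rng = np.random.default_rng(seed)
    rows = []
    for pop in sorted({label[i] for i in ids if i in label}):
        members = [s for s, i in zip(seqs, ids) if label.get(i) == pop]
        n = len(members)
        if n < 2:
            logger.info("population %s skipped (n=%d < 2)", pop, n)
            continue
        S = segregating_sites(members)
        div = nucleotide_diversity(members)
        hap_counts: dict[str, int] = {}
        for s in members:
            hap_counts[s] = hap_counts.get(s, 0) + 1
        k_obs = len(hap_counts)
        hd, sd = haplotype_diversity(list(hap_counts.values()), n)
        d_res = (tajimas_d(members, reps=reps, seed=rng)
                 if n >= 4 else TestResult(math.nan, math.nan, "n<4"))
        fs_res = fus_fs(div.k, k_obs, n, reps=reps, seed=rng)
        rows.append({
            "population": pop, "n": n, "S": S, "n_haplotypes": k_obs,
            "Hd": hd, "SD": sd, "Pi": div.pi, "K": div.k,
            "L_effective": div.l_effective,
            "TajimaD": d_res.statistic, "p_D": d_res.p_value,
            "sig_D": _star(d_res.p_value, alpha),
            "FuFs": fs_res.statistic, "p_Fs": fs_res.p_value,
            "sig_Fs": _star(fs_res.p_value, alpha),
            "sig_Fs_strict": _star(fs_res.p_value, fs_alpha),
        })
    return pd.DataFrame(rows)


def _star(p: float, alpha: float) -> str:
    return "*" if (not math.isnan(p)) and p < alpha else ""
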