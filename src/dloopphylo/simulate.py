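"""Seeded synthetic D-loop datasets and neutral coalescent samples.

Two generative models live here:

* a *star-expansion* model for clade-structured fragment data — four
  founder haplotypes defined by two diagnostic transitions, with each
  sampled lineage descending independently from its founder and carrying
  a Poisson number of private substitutions.  This is the simplest
  generator that produces the star-shaped radiation and the excess of
  rare variants (negative Tajima's D / Fu's Fs) characteristic of
  recently expanded populations.

* a standard neutral constant-size *coalescent* under infinite sites,
  used as the null model for calibrating the neutrality tests and for
  simulation-based p-values.

Both are fully reproducible from an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .seqio import SequenceRecord, write_fasta

POPULATIONS = ("NC", "LY", "CC", "SC", "SW", "PT")
CLADES = ("A", "B", "C", "D")

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

# Provinces associated with each geographic type; used only to give
# synthetic metadata a realistic shape.
_PROVINCES = {
    "NC": ("Shandong", "Hebei", "Henan"),
    "LY": ("Zhejiang", "Jiangsu"),
    "CC": ("Hubei", "Hunan"),
    "SC": ("Guangdong", "Guangxi"),
    "SW": ("Yunnan", "Sichuan"),
    "PT": ("Tibet", "Gansu", "Qinghai"),
}


def _default_clade_sizes() -> dict[str, int]:
    # Clade membership counts of the study cohort (2466 native pigs).
    return {"A": 1107, "B": 339, "C": 591, "D": 429}


def _default_population_mix() -> dict[str, dict[str, float]]:
    # Clade A composition follows the reported shares (PT 62.15%,
    # SW 27.1%, remainder spread over the other four types).  The other
    # clades follow the qualitative pattern: SW concentrated in clade B,
    # NC in clade C, PT also in clade D.
    rest_a = (1.0 - 0.6215 - 0.271) / 4.0
    return {
        "A": {"PT": 0.6215, "SW": 0.271, "NC": rest_a, "LY": rest_a,
              "CC": rest_a, "SC": rest_a},
        "B": {"SW": 0.55, "LY": 0.20, "SC": 0.10, "CC": 0.08, "NC": 0.05,
              "PT": 0.02},
        "C": {"NC": 0.50, "LY": 0.20, "CC": 0.15, "SC": 0.08, "SW": 0.05,
              "PT": 0.02},
        "D": {"PT": 0.60, "SW": 0.20, "NC": 0.08, "CC": 0.06, "LY": 0.04,
              "SC": 0.02},
    }


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    Parameters
    ----------
    sequence_length
        Fragment length in sites (default 431, the amplified D-loop
        fragment length).
    anchor_offset
        Reference mitogenome coordinate (1-based) of the first fragment
        site; default 15,459.
    diagnostic_sites
        Reference coordinates of the two clade-diagnostic transitions
        (default 15,610 and 15,648).
    clade_sizes
        Number of sampled individuals per clade.
    population_mix
        Per-clade categorical distribution over the six geographic
        population labels.
    star_lambda
        Expected number of private substitutions per sampled lineage in
        the star-expansion model.  The default 0.9 yields a mean
        pairwise difference of about 2*lambda = 1.8 within a clade,
        matching the observed per-population K of roughly 1.5-2.4.
    transition_bias
        Probability that a simulated substitution is a transition
        (default 0.9; the catalogued D-loop differences are almost all
        transitions).
    theta
        Scaled mutation rate for the coalescent mode.
    seed
        Integer seed; identical seeds give byte-identical outputs.
    """

    sequence_length: int = 431
    anchor_offset: int = 15459
    diagnostic_sites: tuple[int, int] = (15610, 15648)
    clade_sizes: dict[str, int] = field(default_factory=_default_clade_sizes)
    population_mix: dict[str, dict[str, float]] = field(
        default_factory=_default_population_mix)
    star_lambda: float = 0.9
    transition_bias: float = 0.9
    theta: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sequence_length < 1:
            raise ConfigError("sequence_length must be >= 1")
        if self.star_lambda < 0:
            raise ConfigError("star_lambda must be >= 0")
        if not 0.0 <= self.transition_bias <= 1.0:
            raise ConfigError("transition_bias must lie in [0, 1]")
        lo = self.anchor_offset
        hi = self.anchor_offset + self.sequence_length - 1
        for site in self.diagnostic_sites:
            if not lo <= site <= hi:
                raise ConfigError(
                    f"diagnostic site {site} outside fragment "
                    f"[{lo}, {hi}]")
        for clade, n in self.clade_sizes.items():
            if clade not in CLADES:
                raise ConfigError(f"unknown clade {clade!r}")
            if n < 0:
                raise ConfigError(f"clade_sizes[{clade!r}] must be >= 0")
        for clade, mix in self.population_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"population_mix[{clade!r}] sums to {total}, not 1")
            for pop in mix:
                if pop not in POPULATIONS:
                    raise ConfigError(f"unknown population label {pop!r}")

    @property
    def diagnostic_local_indices(self) -> tuple[int, int]:
        """0-based fragment indices of the diagnostic sites."""
        return tuple(s - self.anchor_offset for s in self.diagnostic_sites)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["diagnostic_sites"] = list(self.diagnostic_sites)
        return d


@dataclass
class SyntheticDataset:
    """A generated cohort: sequences, metadata and ground truth."""

    sequences: list[tuple[str, str]]
    metadata: pd.DataFrame  # sample_id, breed, province, population
    truth: pd.DataFrame  # sample_id, clade, founder
    reference: SequenceRecord
    config: SimulationConfig


def make_reference(config: SimulationConfig,
                   ref_id: str = "SYN_REF") -> SequenceRecord:
    """Build a seeded random reference fragment.

    The reference carries the ancestral base T at both diagnostic sites,
    so that the four clade founders can be derived from it by the
    diagnostic T->C transitions.
    """
    rng = np.random.default_rng(config.seed)
    bases = rng.choice(list("ACGT"), size=config.sequence_length)
    seq = list("".join(bases))
    for idx in config.diagnostic_local_indices:
        seq[idx] = "T"
    return SequenceRecord(ref_id, "".join(seq))


def make_clade_founders(reference: SequenceRecord,
                        config: SimulationConfig) -> dict[str, str]:
    """Derive the four clade founder sequences from the reference.

    Clade D is the reference itself (no diagnostic mutation); clade C
    carries T->C at the first diagnostic site only, clade B at the
    second only, and clade A at both.
    """
    i, j = config.diagnostic_local_indices
    seq = reference.seq
    for idx in (i, j):
        if seq[idx] != "T":
            raise ValueError(
                f"reference lacks ancestral T at diagnostic index {idx} "
                f"(found {seq[idx]!r})")

    def mutate(s: str, positions: Sequence[int]) -> str:
        out = list(s)
        for p in positions:
            out[p] = "C"
        return "".join(out)

    return {
        "A": mutate(seq, (i, j)),
        "B": mutate(seq, (j,)),
        "C": mutate(seq, (i,)),
        "D": seq,
    }


def simulate_star_sample(founder: str, n: int, star_lambda: float,
                         transition_bias: float,
                         rng: np.random.Generator,
                         protected: Sequence[int] = ()) -> list[str]:
    """Draw ``n`` lineages radiating independently from a founder.

    Each lineage carries Poisson(star_lambda) substitutions at uniformly
    chosen non-protected sites (finite sites: a site may mutate more
    than once, in which case the later substitution acts on the current
    base).  Each substitution is a transition with probability
    ``transition_bias``, otherwise a uniformly chosen transversion.
    Protected (diagnostic) sites never mutate, so the clade label of
    every descendant is preserved.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if star_lambda < 0:
        raise ValueError("star_lambda must be >= 0")
    protected_set = frozenset(protected)
    free_sites = [i for i in range(len(founder)) if i not in protected_set]
    out = []
    for _ in range(n):
        seq = list(founder)
        k = rng.poisson(star_lambda)
        for _ in range(k):
            pos = free_sites[rng.integers(len(free_sites))]
            base = seq[pos]
            if rng.random() < transition_bias:
                seq[pos] = _TRANSITION[base]
            else:
                tv = _TRANSVERSIONS[base]
                seq[pos] = tv[rng.integers(2)]
        out.append("".join(seq))
    return out


# ---------------------------------------------------------------------------
# Neutral coalescent


class TooManySegregatingSites(ValueError):
    """More mutations than alignment columns under infinite sites."""


def coalescent_branches(n: int, rng: np.random.Generator
                        ) -> list[tuple[tuple[int, ...], float]]:
    """Simulate one constant-size coalescent genealogy for ``n`` samples.

    Returns a list of (leaf set, branch length) pairs, one per branch of
    the tree, with time in units of 2N generations: with k active
    lineages the waiting time to the next coalescence is exponential
    with rate k(k-1)/2, and the merging pair is uniform.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    active: list[tuple[tuple[int, ...], float]] = [
        ((i,), 0.0) for i in range(n)]
    branches: list[tuple[tuple[int, ...], float]] = []
    t = 0.0
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        if i > j:
            i, j = j, i
        (leaves_j, birth_j) = active.pop(j)
        (leaves_i, birth_i) = active.pop(i)
        branches.append((leaves_i, t - birth_i))
        branches.append((leaves_j, t - birth_j))
        merged = tuple(sorted(leaves_i + leaves_j))
        active.append((merged, t))
        k -= 1
    return branches


def _drop_mutations(branches, n_mut: int,
                    rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Place ``n_mut`` mutations on branches proportionally to length."""
    lengths = np.array([b[1] for b in branches])
    total = lengths.sum()
    if total <= 0 or n_mut == 0:
        return []
    counts = rng.multinomial(n_mut, lengths / total)
    muts: list[tuple[int, ...]] = []
    for (leaves, _), c in zip(branches, counts):
        muts.extend([leaves] * c)
    return muts


def coalescent_mutation_sets(n: int, rng: np.random.Generator, *,
                             theta: float | None = None,
                             n_mutations: int | None = None
                             ) -> list[tuple[int, ...]]:
    """Simulate the derived-allele carrier sets of one coalescent sample.

    Either ``theta`` (mutations Poisson with mean theta/2 x total tree
    length) or a fixed ``n_mutations`` must be given.  Each returned
    tuple is the set of sample indices carrying one derived mutation;
    under infinite sites every mutation is its own segregating site.
    """
    if (theta is None) == (n_mutations is None):
        raise ValueError("give exactly one of theta or n_mutations")
    branches = coalescent_branches(n, rng)
    if n_mutations is None:
        total = sum(b[1] for b in branches)
        n_mutations = rng.poisson(theta / 2.0 * total)
    return _drop_mutations(branches, n_mutations, rng)


def summarize_mutation_sets(mut_sets, n: int) -> tuple[float, int, int]:
    """Return (K, S, number of distinct haplotypes) for one sample.

    K is the mean pairwise difference: a mutation carried by c samples
    separates c(n-c) of the n(n-1)/2 pairs.
    """
    pairs = n * (n - 1) / 2.0
    k = sum(len(m) * (n - len(m)) for m in mut_sets) / pairs
    sigs: dict[int, list[int]] = {i: [] for i in range(n)}
    for m_idx, leaves in enumerate(mut_sets):
        for leaf in leaves:
            sigs[leaf].append(m_idx)
    n_hap = len({tuple(v) for v in sigs.values()})
    return k, len(mut_sets), n_hap


def simulate_coalescent_sample(n: int, theta: float, L: int,
                               seed: int | np.random.Generator
                               ) -> list[str]:
    """Simulate a neutral coalescent alignment of ``n`` sequences.

    Mutations are dropped on the genealogy at rate theta/2 per unit
    branch length and mapped, infinite-sites style, onto distinct
    columns of an L-site nucleotide alignment (derived state = the
    transition of the ancestral base).

    Raises
    ------
    TooManySegregatingSites
        if the realized number of mutations exceeds L; rerun with a
        larger L.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mut_sets = coalescent_mutation_sets(n, rng, theta=theta)
    if len(mut_sets) > L:
        raise TooManySegregatingSites(
            f"{len(mut_sets)} segregating sites exceed alignment "
            f"length {L}")
    ancestral = rng.choice(list("ACGT"), size=L)
    columns = rng.choice(L, size=len(mut_sets), replace=False)
    rows = [list("".join(ancestral)) for _ in range(n)]
    for col, leaves in zip(columns, mut_sets):
        derived = _TRANSITION[ancestral[col]]
        for leaf in leaves:
            rows[leaf][col] = derived
    return ["".join(r) for r in rows]


# ---------------------------------------------------------------------------
# Full-dataset generation


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a clade-structured cohort with metadata and truth table.

    Per-clade star samples are concatenated; each sample's population
    label is drawn from the clade's population mix; breed and province
    are synthesized deterministically from the label.  Reproducible from
    ``config.seed``.
    """
    config.validate()
    if sum(config.clade_sizes.values()) == 0:
        raise ConfigError("empty dataset: all clade sizes are zero")
    rng = np.random.default_rng(config.seed + 1)
    reference = make_reference(config)
    founders = make_clade_founders(reference, config)
    protected = config.diagnostic_local_indices

    sequences: list[tuple[str, str]] = []
    meta_rows = []
    truth_rows = []
    for clade in CLADES:
        n = config.clade_sizes.get(clade, 0)
        if n == 0:
            continue
        seqs = simulate_star_sample(
            founders[clade], n, config.star_lambda,
            config.transition_bias, rng, protected=protected)
        mix = config.population_mix.get(clade, {"PT": 1.0})
        pops = sorted(mix)
        probs = np.array([mix[p] for p in pops])
        labels = rng.choice(pops, size=n, p=probs / probs.sum())
        for i, (seq, pop) in enumerate(zip(seqs, labels), start=1):
            sid = f"{clade}{i:04d}"
            provinces = _PROVINCES[pop]
            province = provinces[rng.integers(len(provinces))]
            breed = f"{province}_{pop}_local{rng.integers(3) + 1}"
            sequences.append((sid, seq))
            meta_rows.append((sid, breed, province, pop))
            truth_rows.append((sid, clade, founders[clade]))

    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "breed", "province", "population"])
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "clade", "founder"])
    return SyntheticDataset(sequences, metadata, truth, reference, config)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path,
                  config_format: str = "yaml") -> dict[str, Path]:
    """Write FASTA, metadata, truth table, reference and config to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "samples.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "reference": outdir / "reference.fasta",
        "config": outdir / ("config.yaml" if config_format == "yaml"
                            else "config.json"),
    }
    write_fasta([SequenceRecord(sid, seq)
                 for sid, seq in dataset.sequences], paths["fasta"])
    write_fasta([dataset.reference], paths["reference"])
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = dataset.config.to_dict()
    with open(paths["config"], "w") as fh:
        if config_format == "yaml":
            yaml.safe_dump(cfg, fh, sort_keys=True)
        else:
            json.dump(cfg, fh, indent=2, sort_keys=True)
    return paths
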