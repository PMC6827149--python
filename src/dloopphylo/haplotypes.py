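"""Haplotype collapsing, diagnostic-site clade classification, naming.

The clade rule operates on the two diagnostic control-region sites
(reference coordinates 15,610 and 15,648 in the default configuration),
whose ancestral state is T.  Derived (non-T, unambiguous) states at
neither site give clade D, at the first site only clade C, at the
second only clade B, and at both clade A.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .seqio import AnchoredAlignment

logger = logging.getLogger(__name__)

CLADE_RULE: Mapping[tuple[bool, bool], str] = {
    # (derived at site 1, derived at site 2) -> clade
    (False, False): "D",
    (True, False): "C",
    (False, True): "B",
    (True, True): "A",
}

_AMBIGUOUS = frozenset("N-")


@dataclass
class Haplotype:
    """An equivalence class of identical aligned sequences."""

    haplotype_id: str
    sequence: str
    members: list[str]
    ambiguous: bool = False  # formed by an N-carrier that fit no group

    @property
    def frequency(self) -> int:
        return len(self.members)

    def population_counts(self, labels: Mapping[str, str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            pop = labels[m]
            counts[pop] = counts.get(pop, 0) + 1
        return counts


@dataclass
class CladeAssignment:
    haplotype_id: str
    state_site1: str
    state_site2: str
    clade: str | None  # None when unclassifiable
    reason: str = ""


def _compatible(seq_n: str, seq: str) -> bool:
    """Does an N-carrying sequence match ``seq`` at every called site?"""
    return all(a == b or a == "N" for a, b in zip(seq_n, seq))


def collapse_haplotypes(alignment: AnchoredAlignment | Sequence[str],
                        sample_ids: Sequence[str] | None = None
                        ) -> list[Haplotype]:
    """Group identical aligned sequences into haplotypes.

    Sequences without N are grouped by exact match.  An N-carrying
    sequence joins an existing group only when compatible (equal at
    every non-N site) with exactly one of them; otherwise it founds its
    own haplotype and is flagged ambiguous.  Output order is descending
    frequency, then lexicographic representative — deterministic and
    idempotent.
    """
    if isinstance(alignment, AnchoredAlignment):
        seqs = alignment.sequences()
        ids = list(alignment.samples)
    else:
        seqs = list(alignment)
        ids = (list(sample_ids) if sample_ids is not None
               else [f"s{i + 1}" for i in range(len(seqs))])
    if not seqs:
        raise ValueError("no sequences to collapse")
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences have unequal aligned lengths")

    groups: dict[str, list[str]] = {}
    deferred: list[tuple[str, str]] = []
    for sid, seq in zip(ids, seqs):
        if "N" in seq:
            deferred.append((sid, seq))
        else:
            groups.setdefault(seq, []).append(sid)
    flagged: dict[str, bool] = {}
    for sid, seq in deferred:
        hits = [g for g in groups if "N" not in g and _compatible(seq, g)]
        if len(hits) == 1:
            groups[hits[0]].append(sid)
        else:
            groups.setdefault(seq, []).append(sid)
            flagged[seq] = True
            logger.info(
                "sample %s: ambiguous bases match %d haplotype groups; "
                "kept as its own flagged haplotype", sid, len(hits))

    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Haplotype(f"H{i + 1:03d}", seq, members,
                  ambiguous=flagged.get(seq, False))
        for i, (seq, members) in enumerate(ordered)
    ]


def classify_clade(haplotype: Haplotype | str,
                   diagnostic_columns: tuple[int, int],
                   ancestral: str = "T") -> CladeAssignment:
    """Apply the two-site clade rule to one haplotype.

    ``diagnostic_columns`` are 0-based column indices of the two
    diagnostic sites in the aligned representative.  A site is derived
    when its state differs from the ancestral base and is unambiguous;
    the expected derived state is C (a transition), so any other
    non-ancestral base is logged but still counts as derived.  A gap or
    N at either site makes the haplotype unclassifiable.
    """
    if isinstance(haplotype, Haplotype):
        hid, seq = haplotype.haplotype_id, haplotype.sequence
    else:
        hid, seq = "?", haplotype
    i, j = diagnostic_columns
    s1, s2 = seq[i], seq[j]
    if s1 in _AMBIGUOUS or s2 in _AMBIGUOUS:
        return CladeAssignment(hid, s1, s2, None,
                               "gap/ambiguous base at a diagnostic site")
    for site, state in ((i, s1), (j, s2)):
        if state not in (ancestral, "C"):
            logger.warning(
                "haplotype %s: unexpected derived state %r at diagnostic "
                "column %d (expected C)", hid, state, site)
    clade = CLADE_RULE[(s1 != ancestral, s2 != ancestral)]
    return CladeAssignment(hid, s1, s2, clade)


def classify_all(haplotypes: Iterable[Haplotype],
                 diagnostic_columns: tuple[int, int],
                 ancestral: str = "T") -> list[CladeAssignment]:
    return [classify_clade(h, diagnostic_columns, ancestral)
            for h in haplotypes]


def name_haplotypes(haplotypes: Sequence[Haplotype],
                    assignments: Sequence[CladeAssignment],
                    network: nx.Graph | None = None) -> dict[str, str]:
    """Assign stable display names (A01, A02, ..., A01a, ...).

    Within each clade, haplotypes are ranked by descending frequency
    (ties by representative sequence) and named clade letter +
    zero-padded rank.  When a haplotype network is supplied, a
    haplotype one mutation step from an already-named haplotype of the
    same clade instead inherits that parent's name plus the next free
    lowercase suffix; assignment order is deterministic, so reruns give
    identical names.  Unclassifiable haplotypes are named U01, U02, ...
    """
    clade_of = {a.haplotype_id: (a.clade or "U") for a in assignments}
    by_id = {h.haplotype_id: h for h in haplotypes}
    names: dict[str, str] = {}
    counters: dict[str, int] = {}
    child_counters: dict[str, int] = {}
    order = sorted(
        haplotypes,
        key=lambda h: (clade_of.get(h.haplotype_id, "U"), -h.frequency,
                       h.sequence))
    for h in order:
        clade = clade_of.get(h.haplotype_id, "U")
        parent_name = None
        if network is not None and h.haplotype_id in network:
            candidates = []
            for nb, attrs in network[h.haplotype_id].items():
                if (attrs.get("weight", 0) == 1 and nb in names
                        and clade_of.get(nb) == clade):
                    candidates.append(names[nb])
            if candidates:
                parent_name = min(candidates)
        if parent_name is not None:
            k = child_counters.get(parent_name, 0)
            child_counters[parent_name] = k + 1
            names[h.haplotype_id] = parent_name + string.ascii_lowercase[k]
        else:
            counters[clade] = counters.get(clade, 0) + 1
            names[h.haplotype_id] = f"{clade}{counters[clade]:02d}"
    return names


def shared_unique_counts(haplotypes: Sequence[Haplotype],
                         metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-population haplotype accounting.

    A haplotype is *unique* to a population when all its members carry
    that label, and *shared* when its members span at least two
    populations.  Returns one row per population with columns
    n_haplotypes (= n_unique + n_shared), n_unique, n_shared.
    """
    labels = dict(zip(metadata["sample_id"], metadata["population"]))
    missing = sorted({m for h in haplotypes for m in h.members
                      if m not in labels})
    if missing:
        raise ValueError(f"samples without a population label: {missing}")
    per_pop: dict[str, list[int]] = {}
    for h in haplotypes:
        pops = {labels[m] for m in h.members}
        for pop in pops:
            row = per_pop.setdefault(pop, [0, 0, 0])
            row[0] += 1
            if len(pops) == 1:
                row[1] += 1
            else:
                row[2] += 1
    out = pd.DataFrame(
        [(pop, *per_pop[pop]) for pop in sorted(per_pop)],
        columns=["population", "n_haplotypes", "n_unique", "n_shared"])
    return out


def haplotype_table(haplotypes: Sequence[Haplotype],
                    assignments: Sequence[CladeAssignment],
                    metadata: pd.DataFrame | None = None,
                    names: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Tabulate haplotypes for export (TSV-friendly)."""
    clade_of = {a.haplotype_id: (a.clade or "unclassifiable")
                for a in assignments}
    labels = (dict(zip(metadata["sample_id"], metadata["population"]))
              if metadata is not None else {})
    rows = []
    for h in haplotypes:
        pops = sorted({labels[m] for m in h.members if m in labels})
        rows.append({
            "haplotype_id": h.haplotype_id,
            "name": names.get(h.haplotype_id, "") if names else "",
            "clade": clade_of.get(h.haplotype_id, ""),
            "frequency": h.frequency,
            "members": ",".join(h.members),
            "populations": ",".join(pops),
        })
    return pd.DataFrame(rows)


def write_haplotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
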