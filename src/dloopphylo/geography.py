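"""Clade-by-region composition tables and map-style count binning.

The composition table answers questions of the form "which geographic
type dominates clade A?" with explicit denominators: percent_of_clade
uses the clade's total as denominator, percent_of_group the group's.
Percentages are computed with exact rational arithmetic before
formatting, so each clade's shares sum to exactly 100.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path
from typing import Mapping

import pandas as pd

GROUP_COLUMNS = ("population", "province", "breed")

# Count-to-circle-size bins used for map display: upper bound of each
# bin (inclusive); counts above the last bound fall in bin 8.
_BIN_BOUNDS = (1, 5, 10, 30, 50, 100, 150)


def circle_bin(count: int) -> int:
    """Map an individual count to its display circle size (1..8).

    1 -> 1; 2-5 -> 2; 6-10 -> 3; 11-30 -> 4; 31-50 -> 5; 51-100 -> 6;
    101-150 -> 7; >150 -> 8.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    for b, bound in enumerate(_BIN_BOUNDS, start=1):
        if count <= bound:
            return b
    return 8


def clade_composition(sample_clades: Mapping[str, str],
                      metadata: pd.DataFrame,
                      group_by: str = "population") -> pd.DataFrame:
    """Cross-tabulate clade membership against a metadata grouping.

    ``sample_clades`` maps sample_id -> clade letter (unclassifiable
    samples simply absent).  Rows are ordered by clade, then descending
    count, then group value; counts sum to the number of classified
    samples and per-clade percentages to exactly 100.
    """
    if group_by not in metadata.columns:
        raise ValueError(f"metadata has no column {group_by!r}")
    group_of = dict(zip(metadata["sample_id"], metadata[group_by]))
    counts: dict[tuple[str, str], int] = {}
    clade_totals: dict[str, int] = {}
    group_totals: dict[str, int] = {}
    for sid, clade in sample_clades.items():
        if sid not in group_of:
            raise ValueError(f"sample {sid!r} missing from metadata")
        g = group_of[sid]
        counts[(clade, g)] = counts.get((clade, g), 0) + 1
        clade_totals[clade] = clade_totals.get(clade, 0) + 1
        group_totals[g] = group_totals.get(g, 0) + 1
    rows = []
    for (clade, g), c in sorted(counts.items(),
                                key=lambda kv: (kv[0][0], -kv[1], kv[0][1])):
        pc = Fraction(100 * c, clade_totals[clade])
        pg = Fraction(100 * c, group_totals[g])
        rows.append({
            "group": g, "clade": clade, "count": c,
            "percent_of_clade": float(pc), "percent_of_group": float(pg),
        })
    return pd.DataFrame(rows)


def distribution_report(composition: pd.DataFrame,
                        out_tsv: str | Path,
                        coordinates: pd.DataFrame | None = None,
                        out_plot: str | Path | None = None) -> list[str]:
    """Write the long-format composition TSV and an optional scatter.

    ``coordinates`` needs columns group, longitude, latitude; rows whose
    group value never occurs in the composition are returned as
    warnings.  The scatter encodes the count's circle bin as marker
    size and the clade as color; it is emitted only when coordinates
    are supplied.
    """
    df = composition.copy()
    df["circle_bin"] = df["count"].map(circle_bin)
    df["percent_of_clade"] = df["percent_of_clade"].map(
        lambda x: round(x, 2))
    df["percent_of_group"] = df["percent_of_group"].map(
        lambda x: round(x, 2))
    df.to_csv(out_tsv, sep="\t", index=False)
    warnings: list[str] = []
    if coordinates is not None and out_plot is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        known = set(df["group"])
        for g in coordinates["group"]:
            if g not in known:
                warnings.append(
                    f"coordinate row {g!r} matches no composition group")
        coords = coordinates.set_index("group")
        fig, ax = plt.subplots(figsize=(7, 6))
        clades = sorted(df["clade"].unique())
        cmap = dict(zip(clades, ("C0", "C1", "C2", "C3", "C4", "C5")))
        for _, row in df.iterrows():
            if row["group"] not in coords.index:
                continue
            x = coords.loc[row["group"], "longitude"]
            y = coords.loc[row["group"], "latitude"]
            ax.scatter(x, y, s=30 * row["circle_bin"] ** 1.5,
                       c=cmap.get(row["clade"], "k"), alpha=0.6,
                       label=row["clade"])
        handles, labels = ax.get_legend_handles_labels()
        uniq = dict(zip(labels, handles))
        ax.legend(uniq.values(), uniq.keys(), title="clade")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        fig.tight_layout()
        fig.savefig(out_plot, dpi=150)
        plt.close(fig)
    return warnings
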