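#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Writes two seeded datasets under results/data/:

* ``full`` — the study-scale cohort (2466 samples; clade sizes 1107 /
  339 / 591 / 429) used for haplotype accounting, geography and the
  per-population statistics;
* ``scaled`` — a 1/20-scale cohort (123 samples) used for the network
  and phylogeny stages, whose cost grows quadratically or worse in the
  number of distinct haplotypes.
"""

from pathlib import Path

from dloopphylo import simulate

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 1


def main() -> None:
    full = simulate.SimulationConfig(seed=SEED)
    scaled = simulate.SimulationConfig(
        clade_sizes={"A": 55, "B": 17, "C": 30, "D": 21}, seed=SEED)
    for name, cfg in (("full", full), ("scaled", scaled)):
        ds = simulate.generate_dataset(cfg)
        paths = simulate.write_dataset(ds, OUT / name)
        by_clade = ds.truth["clade"].value_counts().sort_index()
        print(f"[{name}] {len(ds.sequences)} samples -> {OUT / name}")
        print(f"[{name}] clade sizes: "
              + ", ".join(f"{c}={n}" for c, n in by_clade.items()))
        print(f"[{name}] files: "
              + ", ".join(p.name for p in paths.values()))


if __name__ == "__main__":
    main()
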