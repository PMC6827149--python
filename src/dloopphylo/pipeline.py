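"""End-to-end orchestration: config, staged runs, reproducible bundles.

``run_all`` chains the analysis — anchor fragments, collapse
haplotypes, classify clades, per-population statistics, median-joining
network, K2P/NJ tree, geographic composition — and writes every
artifact plus a JSON manifest (seed, parameters, input checksums) that
suffices to reproduce the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, geography, haplotypes, network, phylo, popgen, seqio

logger = logging.getLogger(__name__)

ARTIFACTS = ("haplotypes.tsv", "clades.tsv", "popstats.tsv",
             "network.graphml", "tree.nwk", "composition.tsv")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    fasta: str
    reference: str
    metadata: str
    outdir: str = "results"
    reference_offset: int = 15459
    diagnostic_sites: tuple[int, int] = (15610, 15648)
    pvalue_reps: int = 1000
    seed: int = 0
    epsilon: int = 0
    bootstrap_reps: int = 100
    outgroup: str | None = None
    deletion_mode: str = "dnasp"  # complete for S/D, pairwise for K/Pi

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("fasta", "reference", "metadata"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {key} path missing: {p}")
        if len(self.diagnostic_sites) != 2:
            raise ValueError("diagnostic_sites must have two coordinates")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis, returning the artifact paths.

    Any stage failure aborts with the stage name and removes the
    partial outputs written during this run.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    t0 = time.time()

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        stage = "read_inputs"
        reference = seqio.read_fasta(config.reference)[0]
        fragments = seqio.read_fasta(config.fasta)
        metadata = seqio.read_metadata(
            config.metadata, fasta_ids=[f.id for f in fragments])

        stage = "anchor"
        rows = [seqio.anchor_fragment(reference, frag,
                                      reference_offset=config.reference_offset)
                for frag in fragments]
        aln = seqio.build_alignment(reference, rows,
                                    reference_offset=config.reference_offset)
        logger.info("[%s] %d fragments anchored (%.1fs)", stage,
                    len(rows), time.time() - t0)

        stage = "haplotype"
        haps = haplotypes.collapse_haplotypes(aln)
        cols = tuple(aln.column_of(s) for s in config.diagnostic_sites)
        assignments = haplotypes.classify_all(haps, cols)
        sample_clades = {}
        clade_by_hid = {a.haplotype_id: a.clade for a in assignments}
        for h in haps:
            clade = clade_by_hid[h.haplotype_id]
            if clade is not None:
                for m in h.members:
                    sample_clades[m] = clade

        stage = "network"
        net = network.median_joining(
            network.HaplotypeInput([h.haplotype_id for h in haps],
                                   [h.sequence for h in haps],
                                   [h.frequency for h in haps]),
            epsilon=config.epsilon)
        names = haplotypes.name_haplotypes(haps, assignments, net)
        hap_table = haplotypes.haplotype_table(haps, assignments, metadata,
                                               names)
        hap_table.to_csv(emit("haplotypes.tsv"), sep="\t", index=False)
        for h in haps:
            if h.haplotype_id in net:
                net.nodes[h.haplotype_id]["clade"] = (
                    clade_by_hid[h.haplotype_id] or "unclassifiable")
                pops = h.population_counts(dict(zip(
                    metadata["sample_id"], metadata["population"])))
                net.nodes[h.haplotype_id]["populations"] = ";".join(
                    f"{k}:{v}" for k, v in sorted(pops.items()))
        network.write_graphml(net, emit("network.graphml"))
        pd.DataFrame(
            [{"haplotype_id": a.haplotype_id, "name": names[a.haplotype_id],
              "state_site1": a.state_site1, "state_site2": a.state_site2,
              "clade": a.clade or "unclassifiable", "note": a.reason}
             for a in assignments]
        ).to_csv(emit("clades.tsv"), sep="\t", index=False)

        stage = "stats"
        stats = popgen.population_summary(
            aln, metadata, reps=config.pvalue_reps, seed=config.seed)
        stats.to_csv(emit("popstats.tsv"), sep="\t", index=False,
                     float_format="%.6g")
        logger.info("[%s] %d populations (%.1fs)", stage, len(stats),
                    time.time() - t0)

        stage = "tree"
        tree_ids = [names[h.haplotype_id] for h in haps]
        tree_seqs = [h.sequence for h in haps]
        outgroup_leaf = None
        if config.outgroup:
            # the outgroup is a sample id; its (distant) haplotype is the
            # leaf the root goes on
            hit = next((h for h in haps if config.outgroup in h.members),
                       None)
            if hit is None:
                raise ValueError(
                    f"outgroup {config.outgroup!r} not among samples")
            outgroup_leaf = names[hit.haplotype_id]
        if len(tree_seqs) >= 3:
            boot = phylo.bootstrap_supports(
                tree_seqs, tree_ids, n_replicates=config.bootstrap_reps,
                seed=config.seed)
            tree = boot.tree
            if outgroup_leaf is not None:
                tree = phylo.root_with_outgroup(tree, outgroup_leaf)
            phylo.write_newick(tree, emit("tree.nwk"))
        else:
            logger.warning("[tree] fewer than 3 haplotypes; skipping tree")
            emit("tree.nwk").write_text(";\n")

        stage = "geography"
        comp = geography.clade_composition(sample_clades, metadata,
                                           group_by="population")
        geography.distribution_report(comp, emit("composition.tsv"))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "python": sys.version.split()[0],
            "seed": config.seed,
            "parameters": dataclasses.asdict(config),
            "inputs": {k: _sha256(getattr(config, k))
                       for k in ("fasta", "reference", "metadata")},
            "n_samples": len(fragments),
            "n_haplotypes": len(haps),
            "artifacts": [p.name for p in written],
        }
        path = emit("manifest.json")
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return {p.name: p for p in written}
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
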