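#!/usr/bin/env python
"""Fetch the three reference mitogenome accessions from GenBank.

Optional, network-requiring helper: downloads the Chinese wild boar
(EF545568.1) and European wild boar (AF304201.1) mitogenomes and the
African warthog outgroup (DQ409327.1) so the worked example can be
rerun against the real accessions instead of the packaged synthetic
stand-ins.  Not used by the test suite or the acceptance script.

Usage:
    python scripts/fetch_references.py --email you@example.org \
        --outdir references/
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

ACCESSIONS = {
    "EF545568.1": "Chinese wild boar mitogenome (coordinate reference)",
    "AF304201.1": "European wild boar mitogenome (contrast)",
    "DQ409327.1": "African warthog mitogenome (outgroup)",
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True,
                        help="Contact email required by NCBI Entrez.")
    parser.add_argument("--outdir", type=Path, default=Path("references"))
    args = parser.parse_args()
    Entrez.email = args.email
    args.outdir.mkdir(parents=True, exist_ok=True)
    for acc, desc in ACCESSIONS.items():
        out = args.outdir / f"{acc}.fasta"
        print(f"fetching {acc} ({desc}) -> {out}")
        with Entrez.efetch(db="nucleotide", id=acc, rettype="fasta",
                           retmode="text") as handle:
            record = SeqIO.read(handle, "fasta")
        SeqIO.write(record, str(out), "fasta")


if __name__ == "__main__":
    main()
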