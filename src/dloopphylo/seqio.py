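"""Sequence and metadata IO, fragment anchoring and variant calling.

Fragments are placed onto the reference mitogenome coordinate system
(1-based, fully closed, GenBank convention) by an infix alignment:
global over the fragment with free end gaps on the reference, so the
fragment finds its best-matching reference window.  Variant calls are
made per sample against the reference, with maximal gap runs merged
into single indel events anchored at their leftmost reference position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_POPULATIONS = frozenset({"NC", "LY", "CC", "SC", "SW", "PT"})
_ALLOWED = frozenset("ACGTN-")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SequenceRecord(NamedTuple):
    """A named nucleotide sequence over the alphabet {A,C,G,T,N,-}."""

    id: str
    seq: str


class FastaError(ValueError):
    pass


class UnanchorableError(ValueError):
    """Fragment could not be placed on the reference (identity < 70%)."""


def _normalize(seq: str, rec_id: str) -> str:
    s = seq.upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in _ALLOWED:
            raise FastaError(
                f"record {rec_id!r}: invalid character {c!r} at "
                f"position {i + 1} (only A/C/G/T/N/- accepted)")
    return s


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated, uppercased records.

    Lowercase bases are uppercased and U is normalized to T.  Duplicate
    ids, empty files/sequences and non-IUPAC characters beyond N are
    rejected with a message naming the offender.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = _normalize(str(rec.seq), rec.id)
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    records = list(records)
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(bio)


def read_metadata(path: str | Path,
                  fasta_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Read the sample metadata table (TSV or CSV).

    Requires columns sample_id, breed, province, population; population
    labels are validated against the six geographic types NC, LY, CC,
    SC, SW, PT.  When ``fasta_ids`` is given, FASTA samples missing from
    the metadata are reported; metadata rows without a FASTA sequence
    are tolerated with a log line.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["sample_id", "breed", "province", "population"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    bad = sorted(set(df["population"]) - VALID_POPULATIONS)
    if bad:
        raise ValueError(
            f"{path}: unknown population label(s) {bad}; expected one of "
            f"{sorted(VALID_POPULATIONS)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample_id(s) {sorted(set(dup))}")
    if fasta_ids is not None:
        fasta_ids = set(fasta_ids)
        meta_ids = set(df["sample_id"])
        absent = sorted(fasta_ids - meta_ids)
        if absent:
            logger.warning("samples in FASTA but not metadata: %s", absent)
        extra = sorted(meta_ids - fasta_ids)
        if extra:
            logger.info("metadata rows without FASTA sequence (ignored): %s",
                        extra)
    return df


# ---------------------------------------------------------------------------
# Anchoring


@dataclass(frozen=True)
class AnchoredRow:
    """One fragment aligned onto reference coordinates."""

    sample_id: str
    fragment_start: int  # 1-based reference coordinate of first aligned base
    ref_aln: str  # aligned reference slice, '-' marks insertions
    frag_aln: str  # aligned fragment, '-' marks deletions
    identity: float


@dataclass
class AnchoredAlignment:
    """Samples stacked on reference mitogenome coordinates.

    ``positions[c]`` is the 1-based reference coordinate of column ``c``
    or ``None`` for an insertion column; ``ref_bases[c]`` the reference
    base ('-' at insertions); ``matrix[i]`` the aligned symbols of
    sample ``samples[i]``, one per column.
    """

    reference_id: str
    fragment_start: int
    positions: list[int | None]
    ref_bases: list[str]
    samples: list[str]
    matrix: list[str] = field(default_factory=list)

    def sequences(self) -> list[str]:
        return list(self.matrix)

    def column_of(self, position: int) -> int:
        """Column index of a reference coordinate (non-insertion)."""
        for c, p in enumerate(self.positions):
            if p == position:
                return c
        raise KeyError(f"reference position {position} not in alignment")


def _make_anchoring_aligner(match: float = 1.0, mismatch: float = -1.0,
                            gap_open: float = -5.0,
                            gap_extend: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps opposite the reference overhangs only: infix
    # placement of the fragment within the reference
    if hasattr(aligner, "open_end_deletion_score"):
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # older attribute names
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def anchor_fragment(reference: SequenceRecord, fragment: SequenceRecord,
                    reference_offset: int = 1,
                    min_identity: float = 0.70,
                    aligner: PairwiseAligner | None = None) -> AnchoredRow:
    """Place a fragment on the reference, returning its anchored row.

    ``reference_offset`` is the 1-based mitogenome coordinate of the
    first base of the reference string (so a 431-bp reference slice
    starting at 15,459 uses offset 15,459).  Scoring: match +1,
    mismatch -1, gap open -5, gap extend -1; ties resolved
    deterministically (the aligner's first, leftmost/high-road
    alignment).  Identity below ``min_identity`` over the aligned
    fragment span raises :class:`UnanchorableError`.
    """
    if len(fragment.seq) < 50:
        raise ValueError(
            f"fragment {fragment.id!r} shorter than 50 bp "
            f"({len(fragment.seq)})")
    if aligner is None:
        aligner = _make_anchoring_aligner()
    aln = aligner.align(reference.seq, fragment.seq)[0]
    ref_full, frag_full = str(aln[0]), str(aln[1])
    # trim the free reference overhangs (fragment-gap prefix/suffix)
    start = 0
    while frag_full[start] == "-":
        start += 1
    end = len(frag_full)
    while frag_full[end - 1] == "-":
        end -= 1
    ref_aln = ref_full[start:end]
    frag_aln = frag_full[start:end]
    matches = sum(1 for a, b in zip(ref_aln, frag_aln)
                  if a == b and a != "-")
    identity = matches / max(len(frag_aln), 1)
    if identity < min_identity:
        raise UnanchorableError(
            f"fragment {fragment.id!r}: best placement identity "
            f"{identity:.2f} < {min_identity:.2f}")
    ref_consumed_before = start - ref_full[:start].count("-")
    fragment_start = reference_offset + ref_consumed_before
    return AnchoredRow(fragment.id, fragment_start, ref_aln, frag_aln,
                       identity)


def build_alignment(reference: SequenceRecord, rows: list[AnchoredRow],
                    reference_offset: int = 1) -> AnchoredAlignment:
    """Stack anchored rows into a multi-sample reference alignment.

    Columns are keyed by (reference position, insertion rank); samples
    not covering a reference column get 'N', samples lacking an
    insertion present in another sample get '-'.
    """
    col_keys: set[tuple[int, int]] = set()
    per_row: list[dict[tuple[int, int], str]] = []
    for row in rows:
        cells: dict[tuple[int, int], str] = {}
        pos = row.fragment_start - 1  # coordinate of last consumed ref base
        ins_rank = 0
        for rbase, fbase in zip(row.ref_aln, row.frag_aln):
            if rbase == "-":
                ins_rank += 1
                key = (pos, ins_rank)
            else:
                pos += 1
                ins_rank = 0
                key = (pos, 0)
            cells[key] = fbase
        col_keys.update(cells)
        per_row.append(cells)
    keys = sorted(col_keys)
    positions = [k[0] if k[1] == 0 else None for k in keys]
    ref_bases = [reference.seq[k[0] - reference_offset] if k[1] == 0 else "-"
                 for k in keys]
    matrix = []
    for row, cells in zip(rows, per_row):
        lo = row.fragment_start
        hi = row.fragment_start + len(row.ref_aln) - row.ref_aln.count("-") - 1
        symbols = []
        for key in keys:
            if key in cells:
                symbols.append(cells[key])
            elif key[1] > 0:
                symbols.append("-")  # insertion absent from this sample
            elif lo <= key[0] <= hi:
                symbols.append("-")
            else:
                symbols.append("N")  # outside the row's covered window
        matrix.append("".join(symbols))
    fragment_start = min((r.fragment_start for r in rows), default=1)
    return AnchoredAlignment(reference.id, fragment_start, positions,
                             ref_bases, [r.sample_id for r in rows], matrix)


# ---------------------------------------------------------------------------
# Variant calling


class VariantCall(NamedTuple):
    """One difference of a sample against the reference.

    ``kind`` is "transition" ({ref,alt} within {A,G} or {C,T}),
    "transversion", or "indel" (a maximal contiguous gap run merged into
    one event, ``alt`` holding a del:/ins: descriptor, ``position`` its
    leftmost reference anchor).
    """

    position: int
    ref_base: str
    alt_base: str
    kind: str
    sample_id: str


def substitution_kind(ref: str, alt: str) -> str:
    if {ref, alt} <= PURINES or {ref, alt} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def call_variants(anchored: AnchoredAlignment) -> list[VariantCall]:
    """Call per-sample variants from a reference-anchored alignment.

    One call per substituted column per sample; N columns are skipped;
    each maximal gap run (deletion in the sample, or insertion relative
    to the reference) becomes a single indel event anchored at its
    leftmost reference position.
    """
    calls: list[VariantCall] = []
    ncol = len(anchored.positions)
    for sid, row in zip(anchored.samples, anchored.matrix):
        c = 0
        while c < ncol:
            pos, rbase, sbase = (anchored.positions[c], anchored.ref_bases[c],
                                 row[c])
            if pos is not None and sbase == "-":  # deletion run
                run_start = pos
                deleted = []
                while (c < ncol and anchored.positions[c] is not None
                       and row[c] == "-"):
                    deleted.append(anchored.ref_bases[c])
                    c += 1
                calls.append(VariantCall(
                    run_start, "".join(deleted), f"del:{''.join(deleted)}",
                    "indel", sid))
                continue
            if pos is None:  # insertion column(s)
                anchor = anchored.positions[c - 1] if c > 0 else 0
                inserted = []
                while c < ncol and anchored.positions[c] is None:
                    if row[c] != "-":
                        inserted.append(row[c])
                    c += 1
                if inserted:
                    calls.append(VariantCall(
                        anchor if anchor else 1, "-",
                        f"ins:{''.join(inserted)}", "indel", sid))
                continue
            if sbase not in ("N",) and sbase != rbase:
                calls.append(VariantCall(
                    pos, rbase, sbase, substitution_kind(rbase, sbase), sid))
            c += 1
    return calls


def write_variants_tsv(calls: Iterable[VariantCall], path: str | Path,
                       chrom: str = "mtDNA") -> None:
    """Export calls as a minimal VCF-like TSV (not a full VCF)."""
    df = pd.DataFrame(
        [(chrom, c.position, c.ref_base, c.alt_base, c.sample_id, c.kind)
         for c in calls],
        columns=["CHROM", "POS", "REF", "ALT", "SAMPLE", "KIND"])
    df.to_csv(path, sep="\t", index=False)
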