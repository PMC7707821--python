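"""Barcode-to-variant dictionary reconstruction.

From merged amplicon reads (15-nt barcode + variant-region sequence) this
module rebuilds the barcode map in four stages: read collapsing, three
contamination filters, per-position consensus calling, and classification of
each consensus as a designed missense variant, a frameshift, a synonymous /
wild-type sequence, or unassigned.

The three filters target distinct failure modes of a segmented, chip-
synthesised library:

* offset filter  — cross-segment chimeras: any observed sequence whose local
  alignment to the full reference starts >5 nt from the modal sequence's
  start marks the barcode contaminated;
* length filter  — single-base synthesis deletions: any two observed
  sequence lengths differing marks the barcode contaminated;
* collision filter — two designed variants sharing one barcode: a non-modal
  sequence with >1 read at Levenshtein distance >= 4 (designed variants
  differ by ~4 edits: two bases of each of two codons) from the modal
  sequence marks the barcode contaminated.

Residue coordinates are 1-based; nucleotide intervals 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .design import ReceptorDesign, Variant
from .synthetic import BARCODE_LEN

logger = logging.getLogger(__name__)

MIN_READS = 3
MAX_OFFSET = 5
COLLISION_DIST = 4

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class BarcodeRecord:
    """Observed sequences and filter verdicts for one barcode."""

    barcode: str
    seq_counts: dict[str, int]
    low_reads: bool = False
    offset_contaminated: bool = False
    length_contaminated: bool = False
    collision_contaminated: bool = False
    consensus: str | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.seq_counts.values())

    @property
    def contaminated(self) -> bool:
        return (self.offset_contaminated or self.length_contaminated
                or self.collision_contaminated)

    @property
    def flags(self) -> list[str]:
        names = ("low_reads", "offset_contaminated", "length_contaminated",
                 "collision_contaminated")
        return [n for n in names if getattr(self, n)]

    def modal_seq(self) -> str:
        """Most common observed sequence; count ties broken lexicographically."""
        return min(self.seq_counts, key=lambda s: (-self.seq_counts[s], s))


@dataclass(frozen=True)
class VariantCall:
    barcode: str
    call_class: str  # missense | frameshift | synonymous | wildtype | unassigned
    position: int | None = None
    wt_aa: str | None = None
    mut_aa: str | None = None
    indel: str | None = None  # frameshift spec, e.g. "del1@87"


def collapse_reads(
    reads, barcode_len: int = BARCODE_LEN, min_reads: int = MIN_READS
) -> list[BarcodeRecord]:
    """Group reads by barcode prefix into records; flag low-read barcodes.

    Reads shorter than ``barcode_len + 1`` cannot carry an insert and are
    skipped (counted in a log message). Records with fewer than ``min_reads``
    total reads are flagged ``low_reads`` and excluded from downstream
    calling by the pipeline.
    """
    groups: dict[str, Counter] = {}
    n_malformed = 0
    for read in reads:
        seq = str(read)
        if len(seq) <= barcode_len:
            n_malformed += 1
            continue
        bc, insert = seq[:barcode_len], seq[barcode_len:]
        groups.setdefault(bc, Counter())[insert] += 1
    if n_malformed:
        logger.warning("skipped %d malformed reads (shorter than barcode)", n_malformed)
    records = [
        BarcodeRecord(bc, dict(cnt), low_reads=sum(cnt.values()) < min_reads)
        for bc, cnt in sorted(groups.items())
    ]
    return records


def make_offset_aligner() -> PairwiseAligner:
    """Affine-gap Smith-Waterman: match 1, mismatch -1, open -2, extend -1."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


#: max edit-distance fraction for a sequence to count as aligned at all
MAX_ALIGN_ERROR = 0.3


def alignment_start(seq: str, reference: str, aligner=None) -> int | None:
    """Start coordinate of the best fit alignment of ``seq`` on ``reference``.

    Uses infix (fit) alignment — the whole query is placed on the reference,
    like a read mapper's reported position — so mismatches near the read
    head cost edits instead of silently shifting the start the way a
    soft-clipping local aligner would. Returns None when the best placement
    needs more than ``MAX_ALIGN_ERROR`` edits per query base, which the
    offset filter treats as contamination.
    """
    res = edlib.align(seq, reference, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > MAX_ALIGN_ERROR * len(seq):
        return None
    return int(res["locations"][0][0])


def filter_offset(
    record: BarcodeRecord,
    reference: str,
    max_offset: int = MAX_OFFSET,
    aligner=None,
) -> BarcodeRecord:
    """Flag barcodes whose sequences align >``max_offset`` nt apart."""
    modal_start = alignment_start(record.modal_seq(), reference, aligner)
    if modal_start is None:
        record.offset_contaminated = True
        logger.warning("barcode %s: modal sequence fails to align", record.barcode)
        return record
    for seq in record.seq_counts:
        start = alignment_start(seq, reference, aligner)
        if start is None or abs(start - modal_start) > max_offset:
            record.offset_contaminated = True
            break
    return record


def filter_lengths(record: BarcodeRecord) -> BarcodeRecord:
    """Flag barcodes observing more than one distinct sequence length."""
    if len({len(s) for s in record.seq_counts}) > 1:
        record.length_contaminated = True
    return record


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def filter_collisions(
    record: BarcodeRecord, d_min: int = COLLISION_DIST, exact: bool = False
) -> BarcodeRecord:
    """Flag barcodes with a multi-read sequence far from the modal sequence.

    A sequence with more than one read at Levenshtein distance >= ``d_min``
    (or exactly ``d_min`` with ``exact=True``) from the modal sequence marks
    a within-segment collision; single-read outliers and 1-2-edit sequencing
    errors are spared.
    """
    modal = record.modal_seq()
    for seq, count in record.seq_counts.items():
        if seq == modal or count <= 1:
            continue
        d = levenshtein(seq, modal)
        hit = d == d_min if exact else d >= d_min
        if hit:
            record.collision_contaminated = True
            break
    return record


def call_consensus(record: BarcodeRecord) -> BarcodeRecord:
    """Per-position majority base call weighted by read count; ties give N.

    The consensus is computed over sequences of the modal length (after the
    length filter all retained sequences agree in length anyway).
    """
    lengths = Counter()
    for seq, cnt in record.seq_counts.items():
        lengths[len(seq)] += cnt
    modal_len = min(lengths, key=lambda n: (-lengths[n], n))
    seqs = [(s, c) for s, c in record.seq_counts.items() if len(s) == modal_len]

    mat = np.zeros((modal_len, 5), dtype=np.int64)  # A C G T other
    index = {65: 0, 67: 1, 71: 2, 84: 3}  # ord codes
    for seq, cnt in seqs:
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        for col, code in enumerate(codes):
            mat[col, index.get(int(code), 4)] += cnt
    best = mat.max(axis=1)
    ties = (mat == best[:, None]).sum(axis=1) > 1
    letters = np.array(list("ACGTN"))
    cons = letters[mat.argmax(axis=1)]
    cons[ties] = "N"
    record.consensus = "".join(cons)
    return record


def apply_filters(
    record: BarcodeRecord,
    reference: str,
    max_offset: int = MAX_OFFSET,
    collision_dist: int = COLLISION_DIST,
    aligner: PairwiseAligner | None = None,
) -> BarcodeRecord:
    """All three contamination filters; verdicts are order-insensitive."""
    filter_offset(record, reference, max_offset, aligner)
    filter_lengths(record)
    filter_collisions(record, collision_dist)
    return record


def _parse_indels(cigar: str) -> tuple[int, int, str | None]:
    """Total inserted/deleted bases and a spec string from an edlib CIGAR."""
    ins = dele = 0
    first: str | None = None
    pos = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op == "I":
            ins += n
            first = first or f"ins{n}@{pos}"
        elif op == "D":
            dele += n
            first = first or f"del{n}@{pos}"
            pos += n
        else:
            pos += n
    return ins, dele, first


def _nearest_segment(design: ReceptorDesign, nt_start: int) -> int:
    starts = [design.segment_nt_range(i)[0] for i in range(len(design.segments))]
    return int(np.argmin([abs(nt_start - s) for s in starts]))


def classify(
    record: BarcodeRecord,
    design: ReceptorDesign,
    variant_lookup: dict[str, Variant] | None = None,
    aligner: PairwiseAligner | None = None,
) -> VariantCall:
    """Determine a consensus sequence's identity.

    1. exact nucleotide match against the designed-variant dictionary gives
       a missense call;
    2. otherwise a global alignment to the barcode's segment reference is
       parsed for indels: a net frame-disrupting shift gives frameshift,
       an in-frame indel is left unassigned;
    3. otherwise the sequence is trimmed to whole codons, translated, and a
       perfect full-length protein match gives synonymous (wildtype when the
       nucleotides are identical to the reference).

    A consensus containing N can never match exactly and falls through to
    unassigned unless its translation is still unambiguous.
    """
    if record.consensus is None:
        call_consensus(record)
    cons = record.consensus
    assert cons is not None

    if variant_lookup is None:
        variant_lookup = design.variant_lookup()
    hit = variant_lookup.get(cons)
    if hit is not None:
        return VariantCall(record.barcode, "missense", hit.position, hit.wt_aa, hit.mut_aa)

    nt_start = alignment_start(cons, design.cds)
    if nt_start is None:
        logger.info("barcode %s: consensus does not align; unassigned", record.barcode)
        return VariantCall(record.barcode, "unassigned")
    seg = _nearest_segment(design, nt_start)
    seg_seq = design.segment_seq(seg)

    # net frame shift of a global alignment equals the length difference;
    # an edit-distance path can misrepresent substitution clusters as
    # compensating indels, so equal-length sequences take the protein route
    shift = len(cons) - len(seg_seq)
    if shift != 0:
        aln = edlib.align(cons, seg_seq, mode="NW", task="path")
        ins, dele, spec = _parse_indels(aln["cigar"])
        if shift % 3 != 0:
            return VariantCall(record.barcode, "frameshift", indel=spec)
        return VariantCall(record.barcode, "unassigned", indel=spec)

    # no indels: trim to whole codons relative to the CDS frame and translate
    seg_nt_start, _ = design.segment_nt_range(seg)
    lead = (-seg_nt_start) % 3
    trimmed = cons[lead:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if not trimmed:
        return VariantCall(record.barcode, "unassigned")
    prot = str(Seq(trimmed).translate())
    res_start = (seg_nt_start + lead) // 3
    ref_prot = design.protein[res_start : res_start + len(prot)]
    if len(prot) == len(ref_prot) and prot == ref_prot and "X" not in prot:
        ref_nt = design.cds[seg_nt_start + lead : seg_nt_start + lead + len(trimmed)]
        cls = "wildtype" if trimmed == ref_nt else "synonymous"
        return VariantCall(record.barcode, cls)
    return VariantCall(record.barcode, "unassigned")


def map_barcodes(
    reads,
    design: ReceptorDesign,
    min_reads: int = MIN_READS,
    max_offset: int = MAX_OFFSET,
    collision_dist: int = COLLISION_DIST,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: collapse, filter, call consensus, classify.

    Returns a barcode-map table (one row per barcode that survived read
    collapsing, including flagged ones with class ``filtered``) and a summary
    dict of per-class and per-flag counts.
    """
    records = collapse_reads(reads, min_reads=min_reads)
    aligner = None
    lookup = design.variant_lookup()

    rows = []
    for rec in records:
        if rec.low_reads:
            rows.append({"barcode": rec.barcode, "call_class": "filtered",
                         "flags": "low_reads", "n_reads": rec.total_reads,
                         "position": pd.NA, "wt_aa": "", "mut_aa": "", "variant": ""})
            continue
        apply_filters(rec, design.cds, max_offset, collision_dist, aligner)
        if rec.contaminated:
            rows.append({"barcode": rec.barcode, "call_class": "filtered",
                         "flags": ",".join(rec.flags), "n_reads": rec.total_reads,
                         "position": pd.NA, "wt_aa": "", "mut_aa": "", "variant": ""})
            continue
        call = classify(rec, design, lookup, aligner)
        if call.call_class == "missense":
            variant = f"{call.wt_aa}{call.position}{call.mut_aa}"
        elif call.call_class == "frameshift":
            variant = f"fs_{rec.barcode}"
        else:
            variant = call.call_class
        rows.append({"barcode": rec.barcode, "call_class": call.call_class,
                     "flags": "", "n_reads": rec.total_reads,
                     "position": call.position if call.position is not None else pd.NA,
                     "wt_aa": call.wt_aa or "", "mut_aa": call.mut_aa or "",
                     "variant": variant})
    table = pd.DataFrame(rows)
    summary = {
        "n_barcodes": len(table),
        "by_class": table["call_class"].value_counts().to_dict(),
        "by_flag": Counter(f for fl in table["flags"] for f in fl.split(",") if f),
    }
    summary["by_flag"] = dict(summary["by_flag"])
    return table, summary
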