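"""Per-read repeat sizing from flank anchors.

Each read is oriented to the plus strand, the 150-bp flank anchors are
located by local alignment, the tract between them is extracted, and the
triplet count is the floor of the tract length over three — interrupted
triplets still count toward the expansion.  Calls are then filtered
(zero-length tracts discarded, weak anchor alignments flagged), classified
into normal / intermediate / expanded alleles, and summarised per sample.

Anchor alignment scores are normalised to [0, 1] by the maximum attainable
local-alignment score (match score times anchor length), giving a portable
quality scale; the default pass threshold is 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import pandas as pd
from Bio import Align, SeqIO

from .locus import ANCHOR_LEN, LocusModel, reverse_complement

# local alignment scoring for anchor location
MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXTEND = -1

DEFAULT_MIN_SCORE = 0.5
# below this normalised score an anchor is considered not found at all
ANCHOR_FLOOR = 0.3

NORMAL_BOUND = 35  # counts below this are in the normal range
PATHOGENIC_BOUND = 50  # counts above this are disease-range expansions

PASS = "pass"
ZERO_LENGTH = "zero_length"
LOW_SCORE = "low_score"
NO_ANCHOR = "no_anchor"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class RepeatCall:
    """Result of anchoring and counting one read."""

    read_id: str
    strand: str
    prefix_score: float
    suffix_score: float
    repeat_seq: str
    repeat_count: int
    filter_status: str
    allele_class: str = "unassigned"


@dataclass
class AnchorHit:
    """Read-coordinate anchor locations (0-based, half-open convention)."""

    prefix_end: int  # one past the end of the prefix-anchor alignment
    suffix_start: int  # start of the suffix-anchor alignment
    prefix_score: float
    suffix_score: float


@dataclass
class SampleRepeatSummary:
    shortest_expanded: int | None
    median_expanded: int | None
    longest_expanded: int | None
    coverage_expanded: int
    coverage_normal: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


# ---------------------------------------------------------------------------
# Orientation and anchor location
# ---------------------------------------------------------------------------

def _orientation_score(sequence: str, locus: LocusModel) -> float:
    """Combined (prefix + suffix) local-alignment score of one orientation."""
    score = 0.0
    for anchor in (locus.prefix_anchor, locus.suffix_anchor):
        s = _ALIGNER.score(sequence, anchor)
        if s > 0:
            score += s
    return score


def orient_read(sequence: str, locus: LocusModel) -> tuple[str, str]:
    """Return (plus-strand-oriented sequence, strand of the input read).

    The orientation with the higher combined anchor score wins; ties keep
    the input orientation.  Orientation never fails — anchor adequacy is
    judged by :func:`locate_anchors`.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    rc = reverse_complement(sequence)
    if _orientation_score(rc, locus) > _orientation_score(sequence, locus):
        return rc, "-"
    return sequence, "+"


def locate_anchors(oriented: str, locus: LocusModel) -> AnchorHit | None:
    """Locate both flank anchors in a plus-strand-oriented read.

    The prefix anchor (last 150 nt of the upstream flank) is aligned
    locally against the whole read; the suffix anchor (first 150 nt of the
    downstream flank) is then searched only downstream of the prefix end.
    Scores are normalised by the maximum attainable score.  Returns None
    (anchor not found) when either normalised score falls below
    ``ANCHOR_FLOOR`` or the geometry is inconsistent.
    """
    max_score = MATCH * ANCHOR_LEN
    try:
        pre = _ALIGNER.align(oriented, locus.prefix_anchor)
        if pre.score <= 0:
            return None
        pre_blocks = pre[0].aligned[0]
    except (ValueError, IndexError, OverflowError):
        return None
    prefix_end = int(pre_blocks[-1][1])
    prefix_score = pre.score / max_score
    if prefix_score < ANCHOR_FLOOR or prefix_end >= len(oriented):
        return None
    tail = oriented[prefix_end:]
    try:
        suf = _ALIGNER.align(tail, locus.suffix_anchor)
        if suf.score <= 0:
            return None
        suf_blocks = suf[0].aligned[0]
    except (ValueError, IndexError, OverflowError):
        return None
    suffix_start = prefix_end + int(suf_blocks[0][0])
    suffix_score = suf.score / max_score
    if suffix_score < ANCHOR_FLOOR or suffix_start < prefix_end:
        return None
    return AnchorHit(prefix_end, suffix_start, prefix_score, suffix_score)


def count_repeats(oriented: str, anchors: AnchorHit, read_id: str = "", strand: str = "+") -> RepeatCall:
    """Extract the tract between the anchors and count triplets.

    ``repeat_count = floor(len(tract) / 3)``: interrupted triplets count
    toward the expansion; a leftover 1–2 nt (from indel noise) is ignored.
    """
    repeat_seq = oriented[anchors.prefix_end : anchors.suffix_start]
    count = len(repeat_seq) // 3
    return RepeatCall(
        read_id=read_id,
        strand=strand,
        prefix_score=round(anchors.prefix_score, 4),
        suffix_score=round(anchors.suffix_score, 4),
        repeat_seq=repeat_seq,
        repeat_count=count,
        filter_status=PASS if count > 0 else ZERO_LENGTH,
    )


def process_read(read_id: str, sequence: str, locus: LocusModel) -> RepeatCall:
    """Orient, anchor and count a single read (unfiltered, unclassified)."""
    oriented, strand = orient_read(sequence, locus)
    anchors = locate_anchors(oriented, locus)
    if anchors is None:
        return RepeatCall(
            read_id=read_id,
            strand=strand,
            prefix_score=0.0,
            suffix_score=0.0,
            repeat_seq="",
            repeat_count=0,
            filter_status=NO_ANCHOR,
        )
    return count_repeats(oriented, anchors, read_id=read_id, strand=strand)


def process_reads(reads, locus: LocusModel) -> list[RepeatCall]:
    """Vector form of :func:`process_read` over (read_id, sequence) pairs."""
    return [process_read(rid, seq, locus) for rid, seq in reads]


# ---------------------------------------------------------------------------
# Filtering, classification, summarisation
# ---------------------------------------------------------------------------

def filter_calls(calls: list[RepeatCall], min_score: float = DEFAULT_MIN_SCORE) -> list[RepeatCall]:
    """Mark failing calls without deleting them (order preserved).

    Zero-length tracts are discarded regardless of score; anchored calls
    whose weaker anchor scores below ``min_score`` are flagged low_score.
    Idempotent.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must be in [0, 1]")
    out = []
    for call in calls:
        if call.filter_status == NO_ANCHOR:
            out.append(call)
        elif call.repeat_count == 0:
            out.append(replace(call, filter_status=ZERO_LENGTH))
        elif min(call.prefix_score, call.suffix_score) < min_score:
            out.append(replace(call, filter_status=LOW_SCORE, allele_class="unassigned"))
        else:
            out.append(replace(call, filter_status=PASS))
    return out


def assign_alleles(
    calls: list[RepeatCall],
    normal_bound: int = NORMAL_BOUND,
    pathogenic_bound: int = PATHOGENIC_BOUND,
) -> list[RepeatCall]:
    """Classify passing calls: count < normal_bound is normal, count >
    pathogenic_bound is expanded, the premutation range in between is
    intermediate.  Non-passing calls stay unassigned."""
    if normal_bound > pathogenic_bound:
        raise ValueError("normal_bound must be <= pathogenic_bound")
    out = []
    for call in calls:
        if call.filter_status != PASS:
            out.append(replace(call, allele_class="unassigned"))
        elif call.repeat_count < normal_bound:
            out.append(replace(call, allele_class="normal"))
        elif call.repeat_count > pathogenic_bound:
            out.append(replace(call, allele_class="expanded"))
        else:
            out.append(replace(call, allele_class="intermediate"))
    return out


def summarize_sample(calls: list[RepeatCall]) -> SampleRepeatSummary:
    """Shortest / median / longest expanded-allele count and per-class
    coverage.  Median of an even-sized set is the lower-middle element, so
    the summary is always an observed integer count."""
    expanded = sorted(c.repeat_count for c in calls if c.allele_class == "expanded")
    normal = sum(1 for c in calls if c.allele_class == "normal")
    if not expanded:
        return SampleRepeatSummary(None, None, None, 0, normal)
    median = expanded[(len(expanded) - 1) // 2]
    return SampleRepeatSummary(expanded[0], median, expanded[-1], len(expanded), normal)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sequences(path) -> list[tuple[str, str]]:
    """Load (read_id, sequence) pairs from FASTQ or FASTA."""
    path = str(path)
    fmt = "fasta" if path.endswith((".fa", ".fasta", ".fna")) else "fastq"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, fmt)]


def calls_to_frame(calls: list[RepeatCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "strand": c.strand,
                "prefix_score": c.prefix_score,
                "suffix_score": c.suffix_score,
                "repeat_count": c.repeat_count,
                "filter_status": c.filter_status,
                "allele_class": c.allele_class,
            }
            for c in calls
        ],
        columns=[
            "read_id",
            "strand",
            "prefix_score",
            "suffix_score",
            "repeat_count",
            "filter_status",
            "allele_class",
        ],
    )


def write_calls(calls: list[RepeatCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_calls_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
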