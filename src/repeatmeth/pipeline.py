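"""End-to-end orchestration and run-level QC.

Runs the full analysis over one sample: orient/anchor/count every read,
filter and classify the calls, summarise mosaicism, profile interruptions
on the expanded reads, aggregate methylation calls (per caller, consensus,
allele-specific, smoothed, optionally correlated against an array
profile), compute QC metrics, and write all tabular outputs plus a joined
JSON report.

QC is self-contained: on-target status and coverage derive from the
pipeline's own anchor alignments (no external genome aligner), and read
accuracy is the identity of each read against its own locus template (the
reference with the repeat tract set to the called length).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from . import interruptions as itx
from . import methylation as meth
from . import repeats
from .locus import LocusModel, reverse_complement

logger = logging.getLogger(__name__)

_CIGAR_NUM = "0123456789"


@dataclass
class QCMetrics:
    total_throughput_bases: int
    pct_reads_on_target: float
    n_reads_at_roi: int
    median_coverage_roi: float
    mean_read_accuracy_pct: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one sample run."""

    reads: str
    locus: str
    out_dir: str
    call_tables: dict[str, str] = field(default_factory=dict)  # caller_id -> path
    array_table: str | None = None
    min_score: float = repeats.DEFAULT_MIN_SCORE
    normal_bound: int = repeats.NORMAL_BOUND
    pathogenic_bound: int = repeats.PATHOGENIC_BOUND
    llr_cutoff: float = meth.LLR_CUTOFF
    span: float = meth.LOWESS_SPAN
    terminal_len: int = itx.TERMINAL_NT
    purity_threshold: float = itx.PURITY_THRESHOLD
    inspection_min_count: int = itx.INSPECTION_MIN_COUNT
    roi: tuple[int, int] | None = None  # default: +/-150 nt around the repeat


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _cigar_columns_matches(cigar: str, edit_distance: int) -> tuple[int, int]:
    """Alignment columns and match count from an edlib cigar."""
    cols = 0
    num = ""
    for ch in cigar:
        if ch in _CIGAR_NUM:
            num += ch
        else:
            cols += int(num)
            num = ""
    return cols, cols - edit_distance


def read_identity(sequence: str, template: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps count)."""
    res = edlib.align(sequence, template, mode="NW", task="path")
    cols, matches = _cigar_columns_matches(res["cigar"], res["editDistance"])
    return matches / cols if cols else 0.0


def compute_qc(
    reads: list[tuple[str, str]],
    locus: LocusModel,
    roi: tuple[int, int],
    calls: list[repeats.RepeatCall] | None = None,
) -> QCMetrics:
    """Table-1-style QC over a read set.

    A read is on target when its anchor-implied reference span overlaps
    the ROI by at least one base; coverage is per-base depth over the ROI
    from those spans; accuracy is mean identity against each read's
    called-length locus template.
    """
    if roi[1] < roi[0]:
        raise ValueError("roi must be a non-empty (start, end) interval")
    if calls is None:
        calls = repeats.process_reads(reads, locus)
    seq_by_id = dict(reads)
    throughput = sum(len(s) for _, s in reads)
    roi_start, roi_end = roi
    depth = np.zeros(roi_end - roi_start + 1, dtype=np.int64)
    n_on = 0
    identities = []
    for call in calls:
        if call.filter_status == repeats.NO_ANCHOR:
            continue
        seq = seq_by_id[call.read_id]
        oriented = seq if call.strand == "+" else reverse_complement(seq)
        anchors = repeats.locate_anchors(oriented, locus)
        if anchors is None:
            continue
        # anchor-implied span in repeat-collapsed coordinates
        span_start = locus.repeat_start - anchors.prefix_end
        tail = len(oriented) - anchors.suffix_start
        span_end = locus.repeat_start + tail - 1
        if span_start <= roi_end and span_end >= roi_start:
            n_on += 1
            lo = max(span_start, roi_start) - roi_start
            hi = min(span_end, roi_end) - roi_start
            depth[lo : hi + 1] += 1
        template = locus.reference_sequence(call.repeat_count)
        identities.append(read_identity(oriented, template))
    return QCMetrics(
        total_throughput_bases=int(throughput),
        pct_reads_on_target=round(100.0 * n_on / len(reads), 4) if reads else 0.0,
        n_reads_at_roi=n_on,
        median_coverage_roi=float(np.median(depth)),
        mean_read_accuracy_pct=round(100.0 * float(np.mean(identities)), 4) if identities else 0.0,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _region_means(consensus: pd.DataFrame, locus: LocusModel) -> dict[str, float | None]:
    """Mean consensus fraction over CpGs strictly up/downstream of the repeat."""
    if consensus.empty:
        return {"upstream_mean": None, "downstream_mean": None}
    up = consensus.loc[consensus["position"] < locus.repeat_start, "methylated_fraction"]
    down = consensus.loc[consensus["position"] >= locus.repeat_start, "methylated_fraction"]
    return {
        "upstream_mean": round(float(up.mean()), 6) if len(up) else None,
        "downstream_mean": round(float(down.mean()), 6) if len(down) else None,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the joined report dict (also written as ``report.json``).
    Deterministic: rerunning on the same inputs reproduces every output
    byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in [config.reads, config.locus, *config.call_tables.values()] + (
        [config.array_table] if config.array_table else []
    ):
        if not Path(path).exists():
            raise FileNotFoundError(path)

    locus = LocusModel.from_yaml(config.locus)
    reads = repeats.read_sequences(config.reads)
    logger.info("loaded %d reads", len(reads))

    # repeat sizing
    calls = repeats.process_reads(reads, locus)
    calls = repeats.filter_calls(calls, config.min_score)
    calls = repeats.assign_alleles(calls, config.normal_bound, config.pathogenic_bound)
    n_excluded = sum(1 for c in calls if c.filter_status != repeats.PASS)
    logger.info("%d of %d reads excluded by filters", n_excluded, len(calls))
    repeats.write_calls(calls, out / "repeat_calls.tsv")
    summary = repeats.summarize_sample(calls)
    (out / "sample_summary.json").write_text(summary.to_json())

    # interruption profiling
    inspected = itx.select_for_inspection(calls, config.inspection_min_count)
    pattern_dict = None
    if inspected:
        profiles = [
            itx.profile_read(c, motif=locus.motif, terminal_len=config.terminal_len)
            for c in inspected
        ]
        itx.profiles_to_frame(profiles).to_csv(
            out / "sections.tsv", sep="\t", index=False, float_format="%.6f"
        )
        pattern = itx.classify_pattern(profiles, config.purity_threshold)
        (out / "pattern.json").write_text(pattern.to_json())
        pattern_dict = pattern.__dict__
        dist_frames = []
        for klass in ("expanded", "normal"):
            seqs = [c.repeat_seq for c in calls if c.allele_class == klass]
            if seqs:
                dist = itx.trinuc_distribution(seqs)
                dist_frames.append(
                    pd.DataFrame(
                        {
                            "allele_class": klass,
                            "triplet": sorted(dist.counts),
                            "count": [dist.counts[t] for t in sorted(dist.counts)],
                            "fraction": [dist.fractions[t] for t in sorted(dist.counts)],
                        }
                    )
                )
        if dist_frames:
            pd.concat(dist_frames, ignore_index=True).to_csv(
                out / "trinuc_distribution.tsv", sep="\t", index=False, float_format="%.6f"
            )

    # methylation profiling
    calls_frame = repeats.calls_to_frame(calls)
    consensus = pd.DataFrame()
    strata_means: dict[str, dict] = {}
    if config.call_tables:
        per_caller: dict[str, pd.DataFrame] = {}
        first_records = None
        for caller, path in sorted(config.call_tables.items()):
            records = meth.parse_call_table(path, caller_id=caller)
            if first_records is None:
                first_records = records
            profile = meth.site_fractions(records, config.llr_cutoff)
            profile.to_csv(
                out / f"sites_{caller}.tsv", sep="\t", index=False, float_format="%.6f"
            )
            per_caller[caller] = profile
        consensus = meth.consensus_profile(per_caller)
        consensus.to_csv(out / "sites_consensus.tsv", sep="\t", index=False, float_format="%.6f")
        # allele-specific stratification uses the first caller's single-read data
        strata = meth.allele_specific_profiles(first_records, calls_frame, config.llr_cutoff)
        for name, profile in strata.items():
            profile.to_csv(
                out / f"sites_{name}.tsv", sep="\t", index=False, float_format="%.6f"
            )
            strata_means[name] = _region_means(profile, locus)
        if len(consensus.dropna(subset=["methylated_fraction"])) >= 2:
            meth.smooth_profile(consensus, config.span).to_csv(
                out / "smoothed_consensus.tsv", sep="\t", index=False, float_format="%.6f"
            )
        if config.array_table:
            array = meth.read_array_table(config.array_table)
            cmp_ = meth.correlate_methods(consensus, array)
            (out / "method_comparison.json").write_text(json.dumps(cmp_.__dict__, indent=2))

    # QC
    roi = config.roi or (locus.repeat_start - 150, locus.repeat_start + 149)
    qc = compute_qc(reads, locus, roi, calls=calls)
    (out / "qc.json").write_text(qc.to_json())

    report = {
        "qc": qc.__dict__,
        "repeat_summary": summary.__dict__,
        "allele_counts": calls_frame["allele_class"].value_counts().to_dict(),
        "filter_counts": calls_frame["filter_status"].value_counts().to_dict(),
        "interruption_pattern": pattern_dict,
        "methylation_region_means": {"consensus": _region_means(consensus, locus), **strata_means},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("report bundle written to %s", out)
    return report
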