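"""Sectioned interruption profiling of expanded repeat tracts.

Repeat-primed PCR can only see interruptions within roughly 80 triplets
(240 nt) of either end of the tract, so each read's tract is split into a
240-nt 5' section, a middle of varying length, and a 240-nt 3' section,
and the fraction of motif (CTG) triplets is computed per section.  Reads
whose ends are pure CTG but whose middle is interrupted carry expansions
that RP-PCR genotyping would call uninterrupted.

Triplet decomposition uses frame 0 from the anchor-defined tract start;
because indel errors make the frame drift along a read, each section's
fraction is also computed in the best of the three frames (the one
maximising the motif count), and that best-frame value is the default
output.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .repeats import PASS, RepeatCall

TERMINAL_NT = 240  # 80 triplets; RP-PCR's confident detection window
INSPECTION_MIN_COUNT = 35  # tracts above this are screened for interruptions
PURITY_THRESHOLD = 0.95


@dataclass
class SectionCTGProfile:
    """Per-read motif fractions in the 5' / middle / 3' tract sections."""

    read_id: str
    five_prime_fraction: float
    middle_fraction: float | None  # None when the tract is <= 2 terminal lengths
    three_prime_fraction: float
    section_lengths: tuple[int, int, int]
    frames: tuple[int, int, int] = (0, 0, 0)  # frame used per section


@dataclass
class TrinucDistribution:
    counts: dict[str, int]
    fractions: dict[str, float]


@dataclass
class PatternReport:
    """Sample-level interruption pattern and its RP-PCR visibility."""

    five_prime_max: float
    middle_median: float | None
    three_prime_max: float
    pure_five_prime: bool
    pure_three_prime: bool
    label: str
    rp_pcr_detectable: bool
    n_reads: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def select_for_inspection(
    calls: list[RepeatCall], min_count: int = INSPECTION_MIN_COUNT
) -> list[RepeatCall]:
    """Passing calls with strictly more than ``min_count`` triplets."""
    return [c for c in calls if c.filter_status == PASS and c.repeat_count > min_count]


def section_repeat(
    repeat_seq: str, terminal_len: int = TERMINAL_NT
) -> tuple[str, str | None, str]:
    """Split a tract into (five_prime, middle, three_prime) sections.

    Terminal sections are ``min(terminal_len, L)`` nt from each end; the
    middle exists only when ``L > 2 * terminal_len``.  For short tracts the
    terminal sections overlap but are both reported.
    """
    if not repeat_seq:
        raise ValueError("repeat_seq must be non-empty")
    L = len(repeat_seq)
    five = repeat_seq[: min(terminal_len, L)]
    three = repeat_seq[max(0, L - terminal_len) :]
    middle = repeat_seq[terminal_len : L - terminal_len] if L > 2 * terminal_len else None
    return five, middle, three


def ctg_fraction(section: str, motif: str = "CTG", frame: int = 0) -> float:
    """Fraction of non-overlapping frame-``frame`` triplets equal to motif.

    Trailing 1–2 nt beyond the last whole triplet are ignored.
    """
    if len(section) - frame < 3:
        raise ValueError("section must contain at least one whole triplet")
    triplets = [section[i : i + 3] for i in range(frame, len(section) - 2, 3)]
    return sum(1 for t in triplets if t == motif) / len(triplets)


def best_frame_fraction(section: str, motif: str = "CTG") -> tuple[float, int]:
    """Motif fraction in the frame that maximises the motif count."""
    best = (-1.0, 0)
    for frame in range(3):
        if len(section) - frame < 3:
            continue
        f = ctg_fraction(section, motif, frame)
        if f > best[0]:
            best = (f, frame)
    if best[0] < 0:
        raise ValueError("section must contain at least one whole triplet")
    return best


def profile_read(
    call: RepeatCall,
    motif: str = "CTG",
    terminal_len: int = TERMINAL_NT,
    frame: str = "best",
) -> SectionCTGProfile:
    """Section a read's tract and compute per-section motif fractions.

    ``frame='best'`` (default) drift-corrects each section independently;
    ``frame='fixed'`` uses frame 0 throughout.
    """
    five, middle, three = section_repeat(call.repeat_seq, terminal_len)
    sections = (five, middle, three)
    fractions: list[float | None] = []
    frames: list[int] = []
    for sec in sections:
        if sec is None:
            fractions.append(None)
            frames.append(0)
        elif frame == "best":
            f, fr = best_frame_fraction(sec, motif)
            fractions.append(f)
            frames.append(fr)
        else:
            fractions.append(ctg_fraction(sec, motif, 0))
            frames.append(0)
    return SectionCTGProfile(
        read_id=call.read_id,
        five_prime_fraction=fractions[0],
        middle_fraction=fractions[1],
        three_prime_fraction=fractions[2],
        section_lengths=(len(five), len(middle) if middle is not None else 0, len(three)),
        frames=tuple(frames),
    )


def trinuc_distribution(repeat_seqs: list[str]) -> TrinucDistribution:
    """Pooled frame-0 triplet composition over a set of tracts."""
    if not repeat_seqs:
        raise ValueError("repeat_seqs must be non-empty")
    counts: Counter[str] = Counter()
    for seq in repeat_seqs:
        counts.update(seq[i : i + 3] for i in range(0, len(seq) - 2, 3))
    total = sum(counts.values())
    fractions = {t: n / total for t, n in counts.items()} if total else {}
    return TrinucDistribution(dict(counts), fractions)


def classify_pattern(
    profiles: list[SectionCTGProfile], purity_threshold: float = PURITY_THRESHOLD
) -> PatternReport:
    """Label the sample-level interruption pattern.

    An end is *pure* if any read reaches ``purity_threshold`` motif fraction
    there (mirroring what an end-anchored assay can latch onto in any single
    molecule).  The middle is judged by its *median* fraction across reads:
    a single read with a chance-clean middle must not override a tract that
    is typically interrupted.  Interruptions confined to the middle with
    both ends pure are invisible to RP-PCR; an end that is never pure is
    RP-PCR detectable.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    five = [p.five_prime_fraction for p in profiles]
    three = [p.three_prime_fraction for p in profiles]
    middles = [p.middle_fraction for p in profiles if p.middle_fraction is not None]
    five_max, three_max = max(five), max(three)
    middle_median = float(np.median(middles)) if middles else None
    pure5 = five_max >= purity_threshold
    pure3 = three_max >= purity_threshold
    middle_pure = middle_median is None or middle_median >= purity_threshold
    if min(five + three) >= purity_threshold and middle_pure:
        label = "uninterrupted"
    elif pure5 and pure3 and not middle_pure:
        label = "ends-pure-middle-interrupted"
    elif pure5 and not pure3:
        label = "end-interrupted-3prime"
    elif pure3 and not pure5:
        label = "end-interrupted-5prime"
    else:
        label = "uniform"
    return PatternReport(
        five_prime_max=round(five_max, 6),
        middle_median=round(middle_median, 6) if middle_median is not None else None,
        three_prime_max=round(three_max, 6),
        pure_five_prime=pure5,
        pure_three_prime=pure3,
        label=label,
        rp_pcr_detectable=not (pure5 and pure3),
        n_reads=len(profiles),
    )


def profiles_to_frame(profiles: list[SectionCTGProfile]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": p.read_id,
                "five_prime_len": p.section_lengths[0],
                "middle_len": p.section_lengths[1],
                "three_prime_len": p.section_lengths[2],
                "five_prime_fraction": p.five_prime_fraction,
                "middle_fraction": p.middle_fraction,
                "three_prime_fraction": p.three_prime_fraction,
                "frames": ",".join(map(str, p.frames)),
            }
            for p in profiles
        ],
        columns=[
            "read_id",
            "five_prime_len",
            "middle_len",
            "three_prime_len",
            "five_prime_fraction",
            "middle_fraction",
            "three_prime_fraction",
            "frames",
        ],
    )
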