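"""Reference description of a triplet-repeat locus and its flanking CpG island.

The locus is modelled in *repeat-collapsed* coordinates: the upstream flank
occupies positions ``[repeat_start - len(upstream), repeat_start - 1]``
(1-based, inclusive), the repeat tract is an insertion point at
``repeat_start``, and the downstream flank occupies
``[repeat_start, repeat_start + len(downstream) - 1]``.  Collapsing the
repeat keeps CpG coordinates independent of per-read repeat length, which is
what makes per-site aggregation across alleles of different sizes possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

ANCHOR_LEN = 150  # flank anchor length (nt) used to delimit the repeat

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusModel:
    """A repeat locus: flank sequences, motif, and CpG site coordinates.

    Parameters
    ----------
    contig_name
        Name used in coordinate-bearing outputs.
    upstream_flank, downstream_flank
        Plus-strand flank sequences, each at least ``ANCHOR_LEN`` nt.
    motif
        Plus-strand repeat unit, exactly 3 nt (e.g. ``CTG``).
    repeat_start
        1-based coordinate of the repeat insertion point (first repeat base).
    cpg_positions
        Strictly increasing 1-based plus-strand coordinates of the CpG
        cytosines tracked in the flanking island.
    """

    contig_name: str
    upstream_flank: str
    downstream_flank: str
    motif: str
    repeat_start: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream_flank", self.upstream_flank.upper())
        object.__setattr__(self, "downstream_flank", self.downstream_flank.upper())
        object.__setattr__(self, "motif", self.motif.upper())
        object.__setattr__(self, "cpg_positions", tuple(int(p) for p in self.cpg_positions))
        if len(self.motif) != 3:
            raise ValueError(f"motif must be a triplet, got {self.motif!r}")
        for name in ("upstream_flank", "downstream_flank"):
            flank = getattr(self, name)
            if len(flank) < ANCHOR_LEN:
                raise ValueError(f"{name} shorter than anchor length {ANCHOR_LEN}")
            for m in (self.motif, reverse_complement(self.motif)):
                if m * 3 in flank:
                    raise ValueError(
                        f"{name} contains a run of >=3 {m} copies; anchors would be ambiguous"
                    )
        if any(b - a <= 0 for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError("cpg_positions must be strictly increasing")
        lo, hi = self.span
        for pos in self.cpg_positions:
            if not lo <= pos <= hi:
                raise ValueError(f"CpG position {pos} outside locus span {lo}-{hi}")
            if self.base_at(pos) != "C" or self.base_at(pos + 1) != "G":
                raise ValueError(f"no CpG dinucleotide at position {pos}")

    # -- coordinate helpers ------------------------------------------------

    @property
    def upstream_start(self) -> int:
        return self.repeat_start - len(self.upstream_flank)

    @property
    def downstream_end(self) -> int:
        return self.repeat_start + len(self.downstream_flank) - 1

    @property
    def span(self) -> tuple[int, int]:
        """(first, last) reference coordinate covered by the flanks."""
        return self.upstream_start, self.downstream_end

    def base_at(self, pos: int) -> str:
        """Reference base at a collapsed coordinate ('' outside the span)."""
        if self.upstream_start <= pos < self.repeat_start:
            return self.upstream_flank[pos - self.upstream_start]
        if self.repeat_start <= pos <= self.downstream_end:
            return self.downstream_flank[pos - self.repeat_start]
        return ""

    def is_upstream(self, pos: int) -> bool:
        return pos < self.repeat_start

    # -- anchors and references --------------------------------------------

    @property
    def prefix_anchor(self) -> str:
        """Last ``ANCHOR_LEN`` nt of the upstream flank."""
        return self.upstream_flank[-ANCHOR_LEN:]

    @property
    def suffix_anchor(self) -> str:
        """First ``ANCHOR_LEN`` nt of the downstream flank."""
        return self.downstream_flank[:ANCHOR_LEN]

    def reference_sequence(self, repeat_count: int) -> str:
        """Full plus-strand locus sequence with ``repeat_count`` motif copies."""
        if repeat_count < 0:
            raise ValueError("repeat_count must be >= 0")
        return self.upstream_flank + self.motif * repeat_count + self.downstream_flank

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["cpg_positions"] = list(self.cpg_positions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LocusModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            contig_name=data["contig_name"],
            upstream_flank=data["upstream_flank"],
            downstream_flank=data["downstream_flank"],
            motif=data["motif"],
            repeat_start=int(data["repeat_start"]),
            cpg_positions=tuple(data["cpg_positions"]),
        )
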