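"""Synthetic targeted long-read data for a triplet-repeat locus.

Emulates the read structure a Cas9-enriched nanopore run produces at an
expanded CTG-repeat locus: diploid read sets with one normal-length and one
expanded allele, somatic length mosaicism on the expanded allele,
non-motif triplet interruptions placed regionally within the tract,
independent per-base substitution/insertion/deletion errors, a retention
bias against long inserts, and per-read per-CpG methylation calls expressed
as log-likelihood ratios from one or more simulated callers.

All randomness flows from ``SimulationConfig.seed``; two runs with equal
seed produce identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locus import ANCHOR_LEN, LocusModel, reverse_complement

# Terminal-region length (nt) used for regional interruption placement;
# matches the sectioned analysis downstream (80 triplets).
TERMINAL_NT = 240

REGIONS = ("five_prime", "middle", "three_prime", "uniform")
METHYL_REGIONS = ("upstream_shore", "upstream_island", "downstream_island", "distal_shore")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class InterruptionSpec:
    """Regional interruption model: per-triplet substitution probability.

    ``region`` selects which triplet slots are eligible by the slot's start
    offset within the tract: the first ``TERMINAL_NT`` nt (five_prime), the
    last ``TERMINAL_NT`` nt (three_prime), everything in between (middle),
    or the whole tract (uniform).
    """

    motif: str
    region: str
    density: float

    def __post_init__(self) -> None:
        if len(self.motif) != 3:
            raise ValueError("interruption motif must be a triplet")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")


@dataclass(frozen=True)
class LengthLaw:
    """Distribution of expanded-allele triplet counts.

    family ``lognormal``: parameterised by the median count and a geometric
    spread factor (sigma of the underlying normal = ln(spread)); this is the
    skewed, long-tailed shape somatic mosaicism produces.  family ``fixed``:
    every expanded read has exactly ``median`` triplets.
    """

    family: str = "lognormal"
    median: float = 650.0
    spread: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "fixed"):
            raise ValueError("length law family must be 'lognormal' or 'fixed'")
        if self.median <= 50:
            raise ValueError("expanded median must exceed 50 triplets")
        if self.family == "lognormal" and self.spread <= 1.0:
            raise ValueError("geometric spread must be > 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, int(round(self.median)), dtype=np.int64)
        draws = rng.lognormal(mean=np.log(self.median), sigma=np.log(self.spread), size=n)
        return np.maximum(51, np.rint(draws).astype(np.int64))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror a targeted nanopore run on an expanded CTG locus:
    7% total read error (substitution 3%, insertion 2%, deletion 2%,
    i.e. 91–94% read accuracy), a normal allele of 13 triplets, an expanded
    allele with lognormal mosaicism around a median of 650 triplets, a
    retention bias of 0.15 per kb against long inserts (which makes
    normal-allele reads slightly overrepresented), and a methylation state
    coupled to the allele: the expanded allele hypermethylated in the
    island flanks of the repeat and hypomethylated at the distal shore,
    the normal allele methylated only at the shores.
    """

    seed: int = 0
    n_reads: int = 200
    normal_count: int = 13
    expanded_length_law: LengthLaw = field(default_factory=LengthLaw)
    interruption_spec: tuple[InterruptionSpec, ...] = ()
    error_rates: tuple[float, float, float] = (0.03, 0.02, 0.02)
    length_bias: float = 0.15  # retention decay per kb of read length
    methyl_profile: dict = field(
        default_factory=lambda: {
            "upstream_shore": {"normal": 0.60, "expanded": 0.60},
            "upstream_island": {"normal": 0.05, "expanded": 0.80},
            "downstream_island": {"normal": 0.05, "expanded": 0.80},
            "distal_shore": {"normal": 0.60, "expanded": 0.15},
        }
    )
    llr_emission: dict = field(
        default_factory=lambda: {
            "methylated": (4.0, 2.0),
            "unmethylated": (-4.0, 2.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if not 0 <= self.normal_count < 35:
            raise ValueError("normal_count must be in [0, 35)")
        if any(not 0.0 <= r <= 1.0 for r in self.error_rates) or sum(self.error_rates) >= 1.0:
            raise ValueError("error rates must be in [0,1] and sum to < 1")
        if self.length_bias < 0:
            raise ValueError("length_bias must be >= 0")
        for region, by_allele in self.methyl_profile.items():
            if region not in METHYL_REGIONS:
                raise ValueError(f"unknown methylation region {region!r}")
            for allele, p in by_allele.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"methylation probability {p} for {region}/{allele} not in [0,1]")


@dataclass
class SimulatedRead:
    """One simulated read plus the ground truth it was built from."""

    read_id: str
    sequence: str
    strand: str  # '+' or '-'
    true_allele: str  # 'normal' or 'expanded'
    true_count: int
    true_interruption_positions: list[tuple[int, str]]  # (nt offset in tract, motif)
    true_methyl_state: dict[int, str]  # cpg position -> 'methylated'/'unmethylated'


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

def build_locus(
    flank_length: int = 2000,
    n_cpg: int = 40,
    motif: str = "CTG",
    seed: int = 0,
    contig_name: str = "locus",
    max_tries: int = 100,
) -> LocusModel:
    """Generate a random repeat locus with ``n_cpg`` CpG sites split between
    the flanks.

    Flanks are uniform-random DNA rejected (bounded retries) until they
    contain no run of three or more motif copies on either strand, so the
    flank anchors are unambiguous against the repeat tract.
    """
    if flank_length < ANCHOR_LEN:
        raise ValueError(f"flank_length must be >= {ANCHOR_LEN}")
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    rng = np.random.default_rng(seed)
    n_up = n_cpg // 2 + n_cpg % 2
    n_down = n_cpg - n_up
    for _ in range(max_tries):
        up = _random_flank(rng, flank_length)
        down = _random_flank(rng, flank_length)
        up = _plant_cpgs(rng, up, n_up)
        down = _plant_cpgs(rng, down, n_down)
        if up is None or down is None:
            continue
        up_seq, up_offsets = up
        down_seq, down_offsets = down
        repeat_start = flank_length + 1
        positions = tuple(o + 1 for o in up_offsets) + tuple(repeat_start + o for o in down_offsets)
        try:
            return LocusModel(
                contig_name=contig_name,
                upstream_flank=up_seq,
                downstream_flank=down_seq,
                motif=motif,
                repeat_start=repeat_start,
                cpg_positions=positions,
            )
        except ValueError:
            continue  # CpG planting re-created a motif run; retry
    raise RuntimeError(f"could not build a valid locus in {max_tries} tries")


def _random_flank(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _plant_cpgs(rng: np.random.Generator, flank: str, n: int):
    """Overwrite ``n`` well-separated dinucleotides with CG; returns
    (sequence, sorted 0-based C offsets) or None if the flank is too short."""
    if n == 0:
        return flank, []
    length = len(flank)
    usable = length - 2  # C needs a following base within the flank
    if usable < 3 * n:
        return None
    # even spacing with jitter keeps sites >=2 nt apart deterministically
    slots = np.linspace(1, usable - 1, n)
    jitter = rng.integers(-1, 2, size=n)
    offsets = np.clip(np.rint(slots).astype(int) + jitter, 0, usable)
    offsets = np.sort(offsets)
    for i in range(1, n):
        if offsets[i] - offsets[i - 1] < 2:
            offsets[i] = offsets[i - 1] + 2
    if offsets[-1] > usable:
        return None
    seq = bytearray(flank.encode())
    for o in offsets:
        seq[o : o + 2] = b"CG"
    return bytes(seq).decode(), [int(o) for o in offsets]


# ---------------------------------------------------------------------------
# CpG regions and methylation truth
# ---------------------------------------------------------------------------

def cpg_region(locus: LocusModel, pos: int) -> str:
    """Classify a CpG coordinate into shore/island regions.

    Each flank is split at its midpoint: the halves nearer the repeat are
    island, the outer halves are shores (upstream shore and distal shore).
    """
    if locus.is_upstream(pos):
        mid = locus.upstream_start + len(locus.upstream_flank) // 2
        return "upstream_shore" if pos < mid else "upstream_island"
    mid = locus.repeat_start + len(locus.downstream_flank) // 2
    return "downstream_island" if pos < mid else "distal_shore"


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _build_tract(
    rng: np.random.Generator,
    motif: str,
    count: int,
    specs: tuple[InterruptionSpec, ...],
) -> tuple[str, list[tuple[int, str]]]:
    """Motif run of ``count`` triplets with regional interruptions substituted."""
    if count == 0:
        return "", []
    slots = [motif] * count
    interruptions: list[tuple[int, str]] = []
    tract_nt = 3 * count
    starts = np.arange(count) * 3
    for spec in specs:
        if spec.region == "five_prime":
            eligible = starts < TERMINAL_NT
        elif spec.region == "three_prime":
            eligible = starts >= tract_nt - TERMINAL_NT
        elif spec.region == "middle":
            eligible = (starts >= TERMINAL_NT) & (starts < tract_nt - TERMINAL_NT)
        else:
            eligible = np.ones(count, dtype=bool)
        hits = eligible & (rng.random(count) < spec.density)
        for i in np.nonzero(hits)[0]:
            if slots[i] == motif:  # first spec wins a contested slot
                slots[i] = spec.motif
                interruptions.append((int(starts[i]), spec.motif))
    interruptions.sort()
    return "".join(slots), interruptions


def corrupt_sequence(
    seq: str, error_rates: tuple[float, float, float], rng: np.random.Generator
) -> str:
    """Apply independent per-base substitution / insertion / deletion noise.

    A deletion removes the base (overriding any substitution drawn for it);
    an insertion adds one uniform-random base after the position.  No
    homopolymer weighting.
    """
    sub, ins, dele = error_rates
    if seq == "" or (sub == 0 and ins == 0 and dele == 0):
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    sub_mask = rng.random(n) < sub
    del_mask = rng.random(n) < dele
    ins_mask = rng.random(n) < ins
    if sub_mask.any():
        idx = _BASE_INDEX[arr[sub_mask]]
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        arr[sub_mask] = _BASES[(idx + shift) % 4]
    keep = ~del_mask
    counts = keep.astype(np.int64) + ins_mask
    total = int(counts.sum())
    if total == 0:
        return ""
    out = np.empty(total, dtype=np.uint8)
    ends = np.cumsum(counts)
    starts = ends - counts
    out[starts[keep]] = arr[keep]
    if ins_mask.any():
        out[ends[ins_mask] - 1] = _BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]
    return bytes(out).decode()


def simulate_reads(
    locus: LocusModel, config: SimulationConfig
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Simulate a diploid read set over the locus.

    Each attempted read draws an allele (1:1), builds
    ``upstream + tract + downstream``, corrupts it at the configured error
    rates, reverse-complements it with probability 0.5 (strand recorded in
    truth), and is retained with probability ``exp(-length_bias * kb)``.

    Returns the retained reads and a truth table covering *all* attempts
    (column ``retained`` marks which were kept), so retention bias is
    directly measurable against its closed form.
    """
    rng = np.random.default_rng(config.seed)
    alleles = np.where(rng.random(config.n_reads) < 0.5, "normal", "expanded")
    expanded_counts = config.expanded_length_law.sample(rng, config.n_reads)
    regions = [cpg_region(locus, p) for p in locus.cpg_positions]
    reads: list[SimulatedRead] = []
    rows = []
    for i in range(config.n_reads):
        allele = str(alleles[i])
        count = config.normal_count if allele == "normal" else int(expanded_counts[i])
        tract, interruptions = _build_tract(rng, locus.motif, count, config.interruption_spec)
        template = locus.upstream_flank + tract + locus.downstream_flank
        seq = corrupt_sequence(template, config.error_rates, rng)
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        methyl = {}
        for pos, region in zip(locus.cpg_positions, regions):
            p = config.methyl_profile[region][allele]
            methyl[pos] = "methylated" if rng.random() < p else "unmethylated"
        retained = rng.random() < np.exp(-config.length_bias * len(seq) / 1000.0)
        read_id = f"read{i:06d}"
        rows.append(
            {
                "read_id": read_id,
                "allele": allele,
                "true_count": count,
                "strand": strand,
                "retained": retained,
                "read_length": len(seq),
                "n_interruptions": len(interruptions),
                "interruptions": ";".join(f"{o}:{m}" for o, m in interruptions),
            }
        )
        if retained:
            reads.append(
                SimulatedRead(
                    read_id=read_id,
                    sequence=seq,
                    strand=strand,
                    true_allele=allele,
                    true_count=count,
                    true_interruption_positions=interruptions,
                    true_methyl_state=methyl,
                )
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "allele",
            "true_count",
            "strand",
            "retained",
            "read_length",
            "n_interruptions",
            "interruptions",
        ],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Methylation call simulation
# ---------------------------------------------------------------------------

def simulate_methylation_calls(
    reads: list[SimulatedRead],
    locus: LocusModel,
    config: SimulationConfig,
    caller_ids: list[str],
) -> dict[str, pd.DataFrame]:
    """Emit per-read per-CpG log-likelihood-ratio call tables, one per caller.

    Callers share the truth but draw independent emission noise.  A read
    contributes a record for a CpG only if the site is present in its
    ``true_methyl_state`` (its simulated span covers the site).
    """
    if not caller_ids:
        raise ValueError("caller_ids must be non-empty")
    mean_m, sd_m = config.llr_emission["methylated"]
    mean_u, sd_u = config.llr_emission["unmethylated"]
    if mean_m <= 2.5 or mean_u >= -2.5:
        raise ValueError("emission means must straddle the +/-2.5 call cutoffs")
    read_ids: list[str] = []
    positions: list[int] = []
    states: list[bool] = []
    for read in reads:
        for pos in sorted(read.true_methyl_state):
            read_ids.append(read.read_id)
            positions.append(pos)
            states.append(read.true_methyl_state[pos] == "methylated")
    state_arr = np.asarray(states, dtype=bool)
    tables: dict[str, pd.DataFrame] = {}
    for k, caller in enumerate(caller_ids):
        rng = np.random.default_rng([config.seed, 1009, k])
        llr = np.where(
            state_arr,
            rng.normal(mean_m, sd_m, size=state_arr.size),
            rng.normal(mean_u, sd_u, size=state_arr.size),
        )
        tables[caller] = pd.DataFrame(
            {
                "contig": locus.contig_name,
                "strand": "+",
                "position": np.asarray(positions, dtype=np.int64),
                "read_id": read_ids,
                "log_lik_ratio": np.round(llr, 4),
                "caller_id": caller,
            }
        )
    return tables


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Write reads as FASTQ with uniform quality (Q20)."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'5' * len(read.sequence)}\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_call_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def truth_methyl_table(reads: list[SimulatedRead]) -> pd.DataFrame:
    """Long-format true methylation states (read_id, position, state)."""
    rows = [
        {"read_id": r.read_id, "position": p, "state": s}
        for r in reads
        for p, s in sorted(r.true_methyl_state.items())
    ]
    return pd.DataFrame(rows, columns=["read_id", "position", "state"])


def config_to_json(config: SimulationConfig) -> str:
    """Serialise a config for run logs (not a round-trip format)."""
    def default(o):
        if isinstance(o, (InterruptionSpec, LengthLaw)):
            return o.__dict__
        raise TypeError(type(o))

    return json.dumps(config.__dict__, default=default, indent=2)
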