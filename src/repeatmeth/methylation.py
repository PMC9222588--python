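"""Per-site CpG methylation aggregation from per-read log-likelihood calls.

Nanopore methylation callers emit, per read and CpG site, a log-likelihood
ratio (methylated minus unmethylated).  Calls with LLR strictly above the
cutoff (default 2.5) are methylated, strictly below its negative are
unmethylated, and everything in between is ambiguous.  The methylated
fraction at a site is confidently methylated reads over confidently called
reads — ambiguous calls drop out of both numerator and denominator (their
count is kept in the output so the inclusive alternative remains
computable).

Profiles can be stratified by the allele class of each read (from the
repeat-sizing calls), averaged across callers into a consensus, smoothed
with local linear (tricube-weighted, lowess) regression over genomic
position, and compared against another method's per-site levels (e.g.
array beta values) by Pearson correlation at overlapping sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

LLR_CUTOFF = 2.5
LOWESS_SPAN = 0.75

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"

# column-name synonyms accepted by parse_call_table, per mandatory field
_COLUMN_ALIASES = {
    "contig": ("contig", "chromosome", "chrom", "chr"),
    "position": ("position", "start", "pos"),
    "read_id": ("read_id", "read_name", "readname", "read"),
    "log_lik_ratio": ("log_lik_ratio", "log_likelihood_ratio", "llr", "statistic"),
}


@dataclass
class MethodComparison:
    """Pearson agreement between two per-site methylation profiles."""

    n_overlapping_sites: int
    pearson_r: float
    p_value: float


# ---------------------------------------------------------------------------
# Parsing and calling
# ---------------------------------------------------------------------------

def parse_call_table(path, caller_id: str | None = None) -> pd.DataFrame:
    """Read a tab-separated per-read per-site call table.

    Accepts the common nanopore-caller dialects (column synonyms for
    contig / position / read id / log-likelihood ratio).  Records reported
    on the minus-strand G of a CpG are harmonised to the plus-strand C
    coordinate (position - 1).  Rows with unparseable ratios are dropped
    and counted in the log.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for col in df.columns:
            if col.lower() in aliases:
                rename[col] = canonical
                break
        else:
            raise ValueError(f"call table {path} is missing a {canonical!r} column")
    df = df.rename(columns=rename)
    llr = pd.to_numeric(df["log_lik_ratio"], errors="coerce")
    bad = int(llr.isna().sum())
    if bad:
        logger.warning("%s: dropped %d rows with unparseable log_lik_ratio", path, bad)
    df = df.assign(log_lik_ratio=llr).dropna(subset=["log_lik_ratio"])
    df["position"] = pd.to_numeric(df["position"]).astype(np.int64)
    if "strand" in df.columns:
        minus = df["strand"] == "-"
        df.loc[minus, "position"] -= 1
        df["strand"] = "+"
    if caller_id is not None:
        df["caller_id"] = caller_id
    elif "caller_id" not in df.columns:
        df["caller_id"] = "caller"
    if df.empty:
        logger.warning("%s: no usable call records", path)
    keep = ["contig", "position", "read_id", "log_lik_ratio", "caller_id"]
    if "strand" in df.columns:
        keep.insert(1, "strand")
    return df[keep].reset_index(drop=True)


def call_status(log_lik_ratio: float, cutoff: float = LLR_CUTOFF) -> str:
    """Three-way call from an LLR: strict inequalities, so a ratio exactly
    at +/-cutoff is ambiguous."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if log_lik_ratio > cutoff:
        return METHYLATED
    if log_lik_ratio < -cutoff:
        return UNMETHYLATED
    return AMBIGUOUS


def _status_series(llr: pd.Series, cutoff: float) -> pd.Series:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return pd.Series(
        np.select([llr > cutoff, llr < -cutoff], [METHYLATED, UNMETHYLATED], AMBIGUOUS),
        index=llr.index,
    )


# ---------------------------------------------------------------------------
# Per-site aggregation
# ---------------------------------------------------------------------------

def site_fractions(
    records: pd.DataFrame, cutoff: float = LLR_CUTOFF, stratum: str = "all"
) -> pd.DataFrame:
    """Aggregate one caller's records into per-site methylated fractions.

    Returns one row per covered position with columns position,
    n_methylated, n_unmethylated, n_ambiguous, methylated_fraction (NaN
    when no confident calls cover the site), caller_id, stratum.
    """
    cols = ["position", "n_methylated", "n_unmethylated", "n_ambiguous",
            "methylated_fraction", "caller_id", "stratum"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    status = _status_series(records["log_lik_ratio"], cutoff)
    tab = (
        pd.crosstab(records["position"], status)
        .reindex(columns=[METHYLATED, UNMETHYLATED, AMBIGUOUS], fill_value=0)
        .sort_index()
    )
    confident = tab[METHYLATED] + tab[UNMETHYLATED]
    frac = tab[METHYLATED] / confident.where(confident > 0)
    caller = records["caller_id"].iloc[0] if "caller_id" in records.columns else "caller"
    return pd.DataFrame(
        {
            "position": tab.index.to_numpy(),
            "n_methylated": tab[METHYLATED].to_numpy(),
            "n_unmethylated": tab[UNMETHYLATED].to_numpy(),
            "n_ambiguous": tab[AMBIGUOUS].to_numpy(),
            "methylated_fraction": frac.to_numpy(),
            "caller_id": caller,
            "stratum": stratum,
        },
        columns=cols,
    )


def consensus_profile(per_caller: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Average per-site fractions across callers (caller_id='consensus').

    At sites some caller leaves undefined, the mean runs over the defined
    callers only; ``n_callers_defined`` reports how many contributed.
    """
    if not per_caller:
        raise ValueError("need at least one caller profile")
    frames = [df[["position", "methylated_fraction"]] for df in per_caller.values()]
    stacked = pd.concat(frames, ignore_index=True).dropna(subset=["methylated_fraction"])
    if stacked.empty:
        return pd.DataFrame(
            columns=["position", "methylated_fraction", "n_callers_defined", "caller_id"]
        )
    grouped = stacked.groupby("position")["methylated_fraction"].agg(["mean", "size"])
    out = grouped.reset_index().rename(
        columns={"mean": "methylated_fraction", "size": "n_callers_defined"}
    )
    out["caller_id"] = "consensus"
    return out


def allele_specific_profiles(
    records: pd.DataFrame,
    repeat_calls: pd.DataFrame,
    cutoff: float = LLR_CUTOFF,
) -> dict[str, pd.DataFrame]:
    """Stratify one caller's records by each read's allele class.

    ``repeat_calls`` needs read_id and allele_class columns (the
    repeat-sizing output).  Returns profiles for strata 'all', 'normal'
    and 'expanded'; intermediate/unassigned reads and reads absent from
    the repeat calls contribute to 'all' only and are counted in the log.
    """
    classes = repeat_calls.set_index("read_id")["allele_class"]
    assigned = records["read_id"].map(classes)
    unjoined = int(assigned.isna().sum())
    if unjoined:
        logger.info("%d call records from reads without a repeat call", unjoined)
    excluded = int(assigned.isin(["intermediate", "unassigned"]).sum())
    if excluded:
        logger.info("%d call records from intermediate/unassigned reads excluded from strata", excluded)
    out = {"all": site_fractions(records, cutoff, stratum="all")}
    for stratum in ("normal", "expanded"):
        sub = records[assigned == stratum]
        out[stratum] = site_fractions(sub, cutoff, stratum=stratum)
    return out


# ---------------------------------------------------------------------------
# Smoothing and method comparison
# ---------------------------------------------------------------------------

def smooth_profile(sites: pd.DataFrame, bandwidth: float = LOWESS_SPAN) -> pd.DataFrame:
    """Lowess-smooth a per-site profile over genomic position.

    Local linear regression with tricube weights, span ``bandwidth`` of
    the sites, no robustness iterations; evaluated at each input position
    and clipped to [0, 1].
    """
    defined = sites.dropna(subset=["methylated_fraction"]).sort_values("position")
    if len(defined) < 2:
        raise ValueError("need at least 2 defined sites to smooth")
    if not 0 < bandwidth <= 1:
        raise ValueError("bandwidth must be in (0, 1]")
    fitted = lowess(
        defined["methylated_fraction"].to_numpy(),
        defined["position"].to_numpy(dtype=float),
        frac=bandwidth,
        it=0,
        return_sorted=True,
    )
    return pd.DataFrame(
        {
            "position": fitted[:, 0].astype(np.int64),
            "smoothed_fraction": np.clip(fitted[:, 1], 0.0, 1.0),
        }
    )


def _pos_value(obj) -> pd.Series:
    """Coerce a profile-like object to a position-indexed value series."""
    if isinstance(obj, pd.Series):
        return obj.dropna()
    if isinstance(obj, pd.DataFrame):
        for col in ("methylated_fraction", "smoothed_fraction", "beta", "fraction", "value"):
            if col in obj.columns:
                return obj.set_index("position")[col].dropna()
        raise ValueError("no recognisable value column in profile")
    return pd.Series(dict(obj)).dropna()


def correlate_methods(a, b) -> MethodComparison:
    """Pearson correlation between two per-site profiles at overlapping
    positions (two-sided test)."""
    sa, sb = _pos_value(a), _pos_value(b)
    common = sa.index.intersection(sb.index)
    if len(common) < 2:
        raise ValueError("need at least 2 overlapping positions")
    r, p = stats.pearsonr(sa.loc[common].to_numpy(), sb.loc[common].to_numpy())
    return MethodComparison(n_overlapping_sites=int(len(common)), pearson_r=float(r), p_value=float(p))


def read_array_table(path) -> pd.DataFrame:
    """Load an array methylation table: position and beta columns (TSV)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "position" not in cols or "beta" not in cols:
        raise ValueError("array table must have 'position' and 'beta' columns")
    out = df.rename(columns={cols["position"]: "position", cols["beta"]: "beta"})
    out["position"] = out["position"].astype(np.int64)
    return out[["position", "beta"]]
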