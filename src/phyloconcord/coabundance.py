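"""Metagenome co-proportionality screen for putative symbiont partners.

Per-(sample, genome) read-mapping records pass three false-positive
filters, are converted into normalized relative abundances, restricted
to samples where the focal genomes are actually present, transformed
with the centered log-ratio (CLR), and screened pairwise with the
proportionality statistic

    rho(x, y) = 1 - var(x - y) / (var(x) + var(y))

on CLR vectors (sample variance, n-1 denominator). A non-focal genome
proportional (rho >= 0.9 by default) to more than three focal genomes
is called a co-proportional partner — abundance covariation of that
strength and breadth across metagenomes is the signature of a shared
lifestyle such as a host-symbiont relationship.

Filters (a record is kept only if all three hold):

  i.  breadth ratio: observed breadth / expected breadth > 0.3, where
      the expected breadth under random read placement is the
      Lander-Waterman value 1 - exp(-depth) with depth = r*l/g,
  ii. observed breadth (covered fraction of the genome) > 0.1,
  iii. mapped reads r > 10.

Normalized relative abundance: Ar = (Nm/Ns) * (r*l/g), with Ns the
sample's read count and Nm the maximum read count over all input
samples (computed before any sample selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_mapping_stats",
    "filter_mappings",
    "normalized_abundance",
    "select_samples",
    "clr_transform",
    "rho",
    "rho_table",
    "call_coproportional",
    "coproportionality_screen",
    "ScreenResult",
]

STATS_COLUMNS = ["sample", "genome", "r", "l", "g", "covered_fraction", "Ns"]


def read_mapping_stats(path) -> pd.DataFrame:
    """Read the per-(sample, genome) mapping statistics TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_stats(df)


def validate_stats(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mapping stats missing columns: {missing}")
    df = df.copy()
    for col in ("r", "Ns"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in column {col!r}")
    if (df["l"] <= 0).any() or (df["g"] <= 0).any():
        raise ValueError("read length l and genome size g must be positive")
    bad = (df["covered_fraction"] < 0) | (df["covered_fraction"] > 1)
    if bad.any():
        raise ValueError("covered_fraction outside [0, 1]")
    if df.duplicated(["sample", "genome"]).any():
        raise ValueError("duplicate (sample, genome) records")
    return df


def expected_breadth(depth: np.ndarray) -> np.ndarray:
    """Lander-Waterman expected covered fraction at a given depth r*l/g."""
    return -np.expm1(-np.asarray(depth, dtype=float))


def filter_mappings(stats: pd.DataFrame,
                    min_breadth_ratio: float = 0.3,
                    min_breadth: float = 0.1,
                    min_reads: int = 10,
                    expected: Callable = expected_breadth):
    """Apply the three mapping filters; returns (kept, report).

    The report has one row per input record with the boolean outcome of
    each criterion and the final keep decision, so
    dropped-by-criterion counts plus kept always sum to the input size.
    """
    stats = validate_stats(stats)
    depth = stats["r"] * stats["l"] / stats["g"]
    exp_b = expected(depth.to_numpy())
    inconsistent = (exp_b <= 0) & (stats["covered_fraction"].to_numpy() > 0)
    if inconsistent.any():
        rows = stats.loc[inconsistent, ["sample", "genome"]].head(5)
        raise ValueError(
            "records with zero depth but positive covered fraction:\n"
            f"{rows.to_string(index=False)}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp_b > 0,
                         stats["covered_fraction"].to_numpy() / exp_b, 0.0)
    pass_i = ratio > min_breadth_ratio
    pass_ii = stats["covered_fraction"].to_numpy() > min_breadth
    pass_iii = stats["r"].to_numpy() > min_reads
    keep = pass_i & pass_ii & pass_iii
    report = stats[["sample", "genome"]].copy()
    report["breadth_ratio"] = ratio
    report["pass_breadth_ratio"] = pass_i
    report["pass_breadth"] = pass_ii
    report["pass_reads"] = pass_iii
    report["kept"] = keep
    return stats[keep].copy(), report


def normalized_abundance(stats: pd.DataFrame,
                         samples: Sequence[str] | None = None,
                         genomes: Sequence[str] | None = None,
                         n_max: float | None = None) -> pd.DataFrame:
    """Samples x genomes table of Ar = (Nm/Ns) * (r*l/g); zeros elsewhere.

    ``n_max`` (Nm) defaults to the maximum Ns over the records given —
    pass the value computed on the *unfiltered* data when filtering has
    already dropped whole samples. Ns must agree within a sample.
    """
    stats = validate_stats(stats)
    if (stats["Ns"] <= 0).any():
        raise ValueError("Ns must be positive")
    ns_per_sample = stats.groupby("sample")["Ns"].nunique()
    if (ns_per_sample > 1).any():
        raise ValueError("inconsistent Ns within a sample")
    nm = float(stats["Ns"].max()) if n_max is None else float(n_max)
    ar = nm / stats["Ns"] * (stats["r"] * stats["l"] / stats["g"])
    table = (stats.assign(Ar=ar)
             .pivot_table(index="sample", columns="genome", values="Ar",
                          fill_value=0.0, aggfunc="first"))
    if samples is not None:
        table = table.reindex(index=list(samples), fill_value=0.0)
    if genomes is not None:
        table = table.reindex(columns=list(genomes), fill_value=0.0)
    table.index.name = "sample"
    table.columns.name = "genome"
    return table.astype(float).fillna(0.0)


def select_samples(table: pd.DataFrame, focal: Iterable[str],
                   min_max: float = 1.0) -> pd.DataFrame:
    """Keep samples whose maximum focal-genome Ar is strictly above min_max."""
    focal = list(focal)
    if not focal:
        raise ValueError("empty focal genome set")
    missing = [g for g in focal if g not in table.columns]
    if missing:
        raise ValueError(f"focal genomes absent from table: {missing}")
    keep = table[focal].max(axis=1) > min_max
    return table.loc[keep]


def clr_transform(table: pd.DataFrame,
                  zero_replacement: float | None = None) -> pd.DataFrame:
    """Centered log-ratio per sample (row): ln x_i - mean_j ln x_j.

    Zeros are replaced first (default: half the smallest positive value
    anywhere in the table); a sample with no positive value is an error.
    Each CLR row sums to zero by construction.
    """
    if table.shape[1] < 2:
        raise ValueError("CLR needs >=2 genomes")
    if (table.to_numpy() < 0).any():
        raise ValueError("abundance table must be nonnegative")
    vals = table.to_numpy(dtype=float).copy()
    all_zero = ~(vals > 0).any(axis=1)
    if all_zero.any():
        bad = list(table.index[all_zero][:5])
        raise ValueError(f"samples with all-zero abundances: {bad}")
    if zero_replacement is None:
        positive = vals[vals > 0]
        zero_replacement = 0.5 * positive.min()
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be positive")
    vals[vals == 0] = zero_replacement
    logs = np.log(vals)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def rho(x, y) -> float:
    """Proportionality rho = 1 - var(x-y)/(var(x)+var(y)) on CLR vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need >=3 samples")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx + vy == 0:
        raise ValueError("rho undefined: both vectors are constant")
    return float(1.0 - (x - y).var(ddof=1) / (vx + vy))


def rho_table(clr: pd.DataFrame, focal: Sequence[str],
              others: Sequence[str] | None = None) -> pd.DataFrame:
    """Long table of rho for every focal x non-focal genome pair."""
    focal = list(focal)
    if others is None:
        others = [g for g in clr.columns if g not in set(focal)]
    rows = []
    for g in others:
        for f in focal:
            rows.append({"genome": g, "focal": f,
                         "rho": rho(clr[g].to_numpy(), clr[f].to_numpy()),
                         "n_samples": len(clr)})
    return pd.DataFrame(rows, columns=["genome", "focal", "rho", "n_samples"])


def call_coproportional(table: pd.DataFrame, focal: Iterable[str],
                        rho_min: float = 0.9, min_focal: int = 4,
                        zero_replacement: float | None = None):
    """Partner calls from a sample-selected abundance table.

    CLR-transforms the table, computes rho for every focal x non-focal
    pair and returns ``(partners, rho_long_table)`` where partners are
    the non-focal genomes with rho >= rho_min for at least ``min_focal``
    focal genomes ("more than three" read strictly as >=4).
    """
    focal = [g for g in focal]
    present = [g for g in focal if g in table.columns]
    if len(present) < min_focal:
        raise ValueError(
            f"only {len(present)} focal genomes in table; need >= {min_focal}")
    if len(table) < 3:
        raise ValueError("need >=3 samples after sample selection")
    clr = clr_transform(table, zero_replacement)
    rt = rho_table(clr, present)
    hits = (rt[rt["rho"] >= rho_min].groupby("genome")["focal"].count())
    partners = sorted(hits[hits >= min_focal].index)
    return partners, rt


@dataclass
class ScreenResult:
    """End-to-end output of the co-proportionality screen."""

    filter_report: pd.DataFrame
    abundance: pd.DataFrame       # all samples x genomes, after filtering
    selected: pd.DataFrame        # samples retained by the focal-presence rule
    rho: pd.DataFrame             # long focal x non-focal rho table
    partners: list


def coproportionality_screen(stats: pd.DataFrame, focal: Iterable[str],
                             min_max: float = 1.0, rho_min: float = 0.9,
                             min_focal: int = 4) -> ScreenResult:
    """Run filters -> Ar -> sample selection -> CLR -> rho -> partner calls."""
    stats = validate_stats(stats)
    nm = float(stats["Ns"].max())
    kept, report = filter_mappings(stats)
    table = normalized_abundance(
        kept, genomes=sorted(stats["genome"].unique()), n_max=nm)
    selected = select_samples(table, focal, min_max=min_max)
    partners, rt = call_coproportional(selected, focal,
                                       rho_min=rho_min, min_focal=min_focal)
    return ScreenResult(report, table, selected, rt, partners)
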