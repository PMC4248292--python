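"""TCRβ clone tables and clonality statistics.

Every developing T cell carries a unique V(D)J rearrangement of the TCRβ
locus, so the rearranged sequence acts as a clonal barcode: the number of
identical sequencing reads is proportional to the size of that clone.  This
module reads/writes ImmunoSeq-style clone tables and computes the summary
statistics used to monitor thymic clonality — unique-clone counts, the
frequency of the most expanded *replicated* clone (read count ≥ 2), the
productive/nonproductive read ratio, clone-frequency histograms, and a
fold-change-over-baseline rule for declaring that a lymphoma has emerged.

A healthy thymus is highly polyclonal: its top replicated clone holds only
~0.1% of reads.  An oligoclonal lymphoma concentrates most reads into a few
dominant clones, raising that top frequency by orders of magnitude; a
30-fold increase over the wild-type baseline is the default detection rule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PRODUCTIVE = "productive"
NONPRODUCTIVE = "nonproductive"

#: age_weeks sentinel for embryonic day 17 (pre-birth sample)
E17_AGE_WEEKS = -0.5

#: Mean wild-type top replicated-clone frequency used as the default
#: lymphoma-detection baseline (0.11% of reads).
DEFAULT_BASELINE_TOP_FREQUENCY = 0.0011

#: Default fold-change over baseline at which a lymphoma is called detected.
DEFAULT_FOLD_THRESHOLD = 30.0

# ImmunoSeq-style TSV header -> internal column names
_TSV_TO_INTERNAL = {
    "sequence": "sequence",
    "vGene": "v_gene",
    "dGene": "d_gene",
    "jGene": "j_gene",
    "frameStatus": "frame_status",
    "count": "read_count",
}
_INTERNAL_TO_TSV = {v: k for k, v in _TSV_TO_INTERNAL.items()}
_CANONICAL_COLUMNS = list(_TSV_TO_INTERNAL.values()) + ["frequency"]


@dataclass(frozen=True)
class CloneRecord:
    """One TCRβ rearrangement with its read support in a sample."""

    sequence: str
    v_gene: str
    d_gene: str
    j_gene: str
    frame_status: str
    read_count: int
    frequency: float


@dataclass
class RepertoireSample:
    """A sequenced TCRβ repertoire: clone table plus sample metadata.

    ``clones`` is a DataFrame with columns ``sequence, v_gene, d_gene,
    j_gene, frame_status, read_count, frequency`` (extra columns are
    preserved).  Frequencies are recomputed from counts (optionally
    weighted) on construction and always sum to 1.
    """

    sample_id: str
    clones: pd.DataFrame
    genotype: str = "wild-type"
    age_weeks: float = math.nan
    sex: str = "f"

    def __post_init__(self) -> None:
        df = self.clones
        missing = [c for c in _TSV_TO_INTERNAL.values() if c not in df.columns]
        if missing:
            raise ValueError(f"clone table missing column(s): {missing}")
        if len(df) == 0:
            raise ValueError("empty repertoire: clone table has no rows")
        if df["sequence"].duplicated().any():
            dup = df.loc[df["sequence"].duplicated(), "sequence"].iloc[0]
            raise ValueError(f"duplicate clone sequence (ambiguous identity): {dup!r}")
        if (df["read_count"] < 1).any():
            raise ValueError("stored clones must have read_count >= 1")
        if "frequency" not in df.columns:
            df = df.copy()
            df["frequency"] = df["read_count"] / df["read_count"].sum()
            self.clones = df
        total = float(self.clones["frequency"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone frequencies sum to {total!r}, expected 1")

    @property
    def total_reads(self) -> int:
        return int(self.clones["read_count"].sum())

    @property
    def unique_clone_count(self) -> int:
        return int(len(self.clones))

    def records(self) -> Iterator[CloneRecord]:
        for row in self.clones.itertuples(index=False):
            yield CloneRecord(
                sequence=row.sequence,
                v_gene=row.v_gene,
                d_gene=row.d_gene,
                j_gene=row.j_gene,
                frame_status=row.frame_status,
                read_count=int(row.read_count),
                frequency=float(row.frequency),
            )

    def filtered(self, mask) -> "RepertoireSample":
        """Subset clones by boolean mask (or callable on the DataFrame) and
        renormalize frequencies so they again sum to 1."""
        if callable(mask):
            mask = mask(self.clones)
        sub = self.clones.loc[np.asarray(mask)].copy()
        if len(sub) == 0:
            raise ValueError("filter removed every clone")
        sub["frequency"] = sub["read_count"] / sub["read_count"].sum()
        return dataclasses.replace(self, clones=sub.reset_index(drop=True))


@dataclass(frozen=True)
class ClonalitySummary:
    """Per-sample clonality statistics and the lymphoma-detection verdict."""

    sample_id: str
    unique_clone_count: int
    total_reads: int
    top_replicated_frequency: float
    top2_frequencies: tuple[float, float]
    productive_to_nonproductive_ratio: float | None
    histogram: list[tuple[float, float, int]]
    baseline_mean_top_freq: float
    fold_change_vs_baseline: float
    fold_threshold: float
    lymphoma_detected: bool

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["top2_frequencies"] = list(self.top2_frequencies)
        d["histogram"] = [list(b) for b in self.histogram]
        return d


def _apply_weights(df: pd.DataFrame, weights: Mapping[str, float] | pd.Series | None) -> pd.DataFrame:
    """Recompute frequencies, optionally applying per-clone multiplicative
    weights (a PCR amplification-bias correction hook)."""
    df = df.copy()
    counts = df["read_count"].astype(float)
    if weights is not None:
        w = pd.Series(dict(weights)) if not isinstance(weights, pd.Series) else weights
        mult = df["sequence"].map(w).fillna(1.0).astype(float)
        counts = counts * mult
    df["frequency"] = counts / counts.sum()
    return df


def read_clone_table(
    path,
    weights: Mapping[str, float] | None = None,
    sample_id: str | None = None,
    **metadata,
) -> RepertoireSample:
    """Read an ImmunoSeq-style clone TSV into a :class:`RepertoireSample`.

    Required columns: ``sequence, vGene, dGene, jGene, frameStatus, count``.
    Unknown columns are preserved.  ``weights`` maps sequence → multiplier
    applied to counts before frequencies are computed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    missing = [c for c in _TSV_TO_INTERNAL if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    df = df.rename(columns=_TSV_TO_INTERNAL)
    if len(df) == 0:
        raise ValueError(f"{path}: empty repertoire (no clone rows)")
    df = _apply_weights(df, weights)
    return RepertoireSample(
        sample_id=sample_id or str(path),
        clones=df,
        **metadata,
    )


def write_clone_table(sample: RepertoireSample, path) -> None:
    """Write a sample back to ImmunoSeq-style TSV (round-trips through
    :func:`read_clone_table`)."""
    df = sample.clones.drop(columns=["frequency"]).rename(columns=_INTERNAL_TO_TSV)
    df.to_csv(path, sep="\t", index=False)


def top_replicated_frequency(sample: RepertoireSample, min_count: int = 2) -> float:
    """Maximum frequency among replicated clones (read count ≥ min_count);
    0 when every clone is a singleton."""
    rep = sample.clones.loc[sample.clones["read_count"] >= min_count, "frequency"]
    return float(rep.max()) if len(rep) else 0.0


def top_k_fractions(sample: RepertoireSample, k: int) -> list[tuple[str, float]]:
    """The ``k`` most frequent clones as (sequence, frequency), descending.

    Ties are broken lexicographically by sequence so the ordering is
    deterministic.  ``k`` beyond the clone count returns every clone.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = sample.clones.sort_values(
        ["frequency", "sequence"], ascending=[False, True], kind="mergesort"
    )
    head = df.head(k)
    return list(zip(head["sequence"].tolist(), head["frequency"].astype(float).tolist()))


def default_bin_edges() -> np.ndarray:
    """Log10-spaced clone-frequency bin edges, one bin per decade over
    [1e-6, 1)."""
    return np.logspace(-6, 0, 7)


def frequency_histogram(
    sample: RepertoireSample, bin_edges: Sequence[float] | None = None
) -> list[tuple[float, float, int]]:
    """Histogram of clone frequencies over half-open bins [lower, upper).

    Clones falling outside the edge span are counted in explicit
    (-inf, first) / [last, inf) overflow bins — never dropped — so counts
    always sum to the unique clone count.
    """
    edges = np.asarray(default_bin_edges() if bin_edges is None else bin_edges, float)
    if len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    f = sample.clones["frequency"].to_numpy()
    # np.digitize with right=False: index i means edges[i-1] <= f < edges[i]
    idx = np.digitize(f, edges, right=False)
    bins: list[tuple[float, float, int]] = []
    bins.append((-math.inf, float(edges[0]), int(np.sum(idx == 0))))
    for i in range(len(edges) - 1):
        bins.append((float(edges[i]), float(edges[i + 1]), int(np.sum(idx == i + 1))))
    bins.append((float(edges[-1]), math.inf, int(np.sum(idx == len(edges)))))
    return bins


def productive_ratio(sample: RepertoireSample) -> float | None:
    """Ratio of productive to nonproductive read counts.

    Returns None (undefined) when the sample has no nonproductive reads.
    Thymic selection normally keeps this ratio near 1:2 at the DNA level
    being 1/3 in-frame; a strong drop marks selection acting downstream of
    rearrangement.
    """
    counts = sample.clones.groupby("frame_status")["read_count"].sum()
    prod = int(counts.get(PRODUCTIVE, 0))
    nonprod = int(counts.get(NONPRODUCTIVE, 0))
    if nonprod == 0:
        return None
    return prod / nonprod


def clonality_summary(
    sample: RepertoireSample,
    baseline_mean_top_freq: float = DEFAULT_BASELINE_TOP_FREQUENCY,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    bin_edges: Sequence[float] | None = None,
) -> ClonalitySummary:
    """Full clonality summary plus the fold-change lymphoma-detection call.

    The detection statistic is the top *replicated* clone frequency divided
    by the wild-type baseline mean; the boundary is inclusive (fold change
    exactly at the threshold counts as detected).
    """
    if baseline_mean_top_freq <= 0:
        raise ValueError("baseline_mean_top_freq must be positive")
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    top_rep = top_replicated_frequency(sample)
    ranked = top_k_fractions(sample, 2)
    top2 = tuple(freq for _, freq in ranked)
    if len(top2) < 2:
        top2 = (top2[0], 0.0)
    fold = top_rep / baseline_mean_top_freq
    return ClonalitySummary(
        sample_id=sample.sample_id,
        unique_clone_count=sample.unique_clone_count,
        total_reads=sample.total_reads,
        top_replicated_frequency=top_rep,
        top2_frequencies=top2,  # type: ignore[arg-type]
        productive_to_nonproductive_ratio=productive_ratio(sample),
        histogram=frequency_histogram(sample, bin_edges),
        baseline_mean_top_freq=baseline_mean_top_freq,
        fold_change_vs_baseline=fold,
        fold_threshold=fold_threshold,
        lymphoma_detected=bool(fold >= fold_threshold),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test of per-sample top replicated frequencies."""

    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float
    degenerate: bool = False


def compare_group_top_frequencies(
    group_a: Iterable, group_b: Iterable
) -> GroupComparison:
    """Student's t-test comparing top replicated-clone frequencies between
    two groups of samples (e.g. wild-type vs knockout thymi).

    Accepts RepertoireSample objects or raw per-sample frequencies.  Groups
    whose pooled variance is zero are flagged ``degenerate`` (the t-test is
    ill-defined); for such groups p is reported as 1 when the means agree
    and 0 otherwise.
    """

    def _freqs(group) -> np.ndarray:
        vals = [
            top_replicated_frequency(g) if isinstance(g, RepertoireSample) else float(g)
            for g in group
        ]
        return np.asarray(vals, float)

    a, b = _freqs(group_a), _freqs(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        same = a.mean() == b.mean()
        return GroupComparison(
            statistic=0.0 if same else math.inf,
            pvalue=1.0 if same else 0.0,
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
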