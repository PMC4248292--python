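"""Exome depth-ratio CNV calling and cell-fraction algebra.

The observable is the per-exon log2 ratio of tumor to normal read depth.
In a tumor where a fraction ``f`` of cells carries an integer copy change
``Δ`` at a diploid locus, the expected depth ratio is

    ratio = 1 + f·Δ/2            (so  c = log2 ratio,  f = 2(2^c − 1)/Δ)

This algebra links the calling cutoffs to cell fractions: a segment-mean
log2 ratio of −0.3 under a one-copy deletion (Δ = −1) implies f ≈ 38% of
tumor cells deleted, and +0.2 under a one-copy gain implies f ≈ 30%.

Segmentation is a circular-binary-segmentation-style recursion: at each
step the arc maximizing the two-sample t statistic between inside and
outside is tested against a permutation null; significant arcs split the
exon list and the pieces are segmented recursively.  Segment means at or
beyond the cutoffs (boundary inclusive) are called deletions or
amplifications.  A run of exons whose tumor depth collapses to a small
fraction of normal flags a focal biallelic deletion (Δ = −2), whose depth
ratio approaches 1 − f.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_DELETION_CUTOFF = -0.3
DEFAULT_AMPLIFICATION_CUTOFF = 0.2
#: focal biallelic-deletion floor: tumor retains < 15% of normal depth
DEFAULT_BIALLELIC_FLOOR = math.log2(0.15)

DELETION = "deletion"
AMPLIFICATION = "amplification"
NEUTRAL = "neutral"

_CHR_Y = {"chrY", "Y"}


class OutOfModelError(ValueError):
    """A log ratio that no cell fraction in (0, 1] can produce under the
    declared copy change."""


# ---------------------------------------------------------------------------
# algebra


def ratio_from_cell_fraction(cell_fraction: float, copy_change: int) -> float:
    """Expected log2 depth ratio for a lesion (Δ, f) on a diploid background."""
    if copy_change == 0:
        raise ValueError("copy_change must be nonzero")
    if not 0 <= cell_fraction <= 1:
        raise ValueError("cell_fraction must be in [0, 1]")
    ratio = 1.0 + cell_fraction * copy_change / 2.0
    if ratio <= 0:
        return -math.inf  # Δ=-2, f=1: both copies gone everywhere
    return math.log2(ratio)


def cell_fraction_from_ratio(log2_ratio: float, copy_change: int) -> float:
    """Invert the expected-ratio model: f = 2·(2^c − 1)/Δ.

    Raises :class:`OutOfModelError` when the implied fraction falls outside
    [0, 1] (the ratio cannot arise from the declared copy change); c = 0
    maps to f = 0 (no lesion) for every Δ.
    """
    if copy_change == 0:
        raise ValueError("copy_change must be nonzero")
    f = 2.0 * (2.0 ** log2_ratio - 1.0) / copy_change
    if f < 0 or f > 1:
        raise OutOfModelError(
            f"log2 ratio {log2_ratio:g} under copy change {copy_change:+d} "
            f"implies cell fraction {f:g} outside [0, 1]"
        )
    return f


def percent(fraction: float) -> int:
    """Cell fraction as an integer percent, half rounded away from zero."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)


# ---------------------------------------------------------------------------
# I/O and log ratios


def read_coverage(bed_path, depths_path) -> pd.DataFrame:
    """Join an exon BED (chromosome, start, end; no header) with a depth TSV
    keyed by exon index (exon_index, tumor_depth, normal_depth)."""
    exons = pd.read_csv(
        bed_path, sep="\t", header=None, names=["chromosome", "start", "end"]
    )
    depths = pd.read_csv(depths_path, sep="\t")
    for col in ("exon_index", "tumor_depth", "normal_depth"):
        if col not in depths.columns:
            raise ValueError(f"{depths_path}: missing required column {col!r}")
    if len(depths) != len(exons):
        raise ValueError(
            f"exon table ({len(exons)} rows) and depth table ({len(depths)} rows) disagree"
        )
    depths = depths.sort_values("exon_index").reset_index(drop=True)
    out = exons.copy()
    out["tumor_depth"] = depths["tumor_depth"].to_numpy()
    out["normal_depth"] = depths["normal_depth"].to_numpy()
    return out


def read_coverage_table(path) -> pd.DataFrame:
    """Read a combined coverage TSV (chromosome, start, end, tumor_depth,
    normal_depth)."""
    df = pd.read_csv(path, sep="\t")
    missing = [
        c
        for c in ("chromosome", "start", "end", "tumor_depth", "normal_depth")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return df


def compute_log_ratios(
    exons: pd.DataFrame,
    pseudocount: float = 0.5,
    normalize: bool = True,
    exclude_chr_y: bool = False,
) -> pd.DataFrame:
    """Fill ``log2_ratio`` = log2((tumor·s + pc)/(normal + pc)) per exon.

    ``normalize`` rescales the tumor library to the normal library's total
    depth (s = Σnormal/Σtumor) so sequencing-depth differences do not mimic
    copy change; disable it when depths are already matched.  The
    pseudocount keeps biallelic deletions (tumor depth 0) representable.
    ``exclude_chr_y`` drops chrY exons, for runs where the matched normal is
    from the opposite sex.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    df = exons.copy()
    if exclude_chr_y:
        df = df[~df["chromosome"].isin(_CHR_Y)]
    order = {c: i for i, c in enumerate(pd.unique(df["chromosome"]))}
    df = df.sort_values(
        ["chromosome", "start"], key=lambda s: s.map(order) if s.name == "chromosome" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    tumor = df["tumor_depth"].astype(float).to_numpy()
    normal = df["normal_depth"].astype(float).to_numpy()
    if normal.sum() == 0:
        raise ValueError("normal sample has zero total depth")
    scale = normal.sum() / tumor.sum() if (normalize and tumor.sum() > 0) else 1.0
    df["log2_ratio"] = np.log2((tumor * scale + pseudocount) / (normal + pseudocount))
    return df


# ---------------------------------------------------------------------------
# segmentation


@dataclass(frozen=True)
class CnvSegment:
    """A contiguous run of exons with a common mean log2 depth ratio."""

    chromosome: str
    first_exon: int  # chromosome-local exon index, inclusive
    last_exon: int
    start: int  # genomic, 0-based half-open over the covered exons
    end: int
    n_exons: int
    mean_log2_ratio: float
    call: str = NEUTRAL
    copy_change: int | None = None
    cell_fraction: float | None = None
    out_of_model: bool = False


def _best_arc(x: np.ndarray, min_seg: int) -> tuple[float, int, int] | None:
    """Max |t| over circular arcs x[i:j] vs the rest.

    Returns (|t|, i, j); ties resolve to the first arc in (i, j) row-major
    order.  Arcs leaving fewer than ``min_seg`` exons on either side are
    excluded.  Zero pooled variance with distinct means scores +inf.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < max(3, 2 * min_seg):
        return None
    s = np.concatenate(([0.0], np.cumsum(x)))
    q = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    nin = (j - i).astype(float)
    valid = (nin >= min_seg) & (n - nin >= min_seg)
    with np.errstate(divide="ignore", invalid="ignore"):
        sin = s[j] - s[i]
        qin = q[j] - q[i]
        nout = n - nin
        sout = s[n] - sin
        qout = q[n] - qin
        diff = sin / nin - sout / nout
        ss = (qin - sin**2 / nin) + (qout - sout**2 / nout)
        pooled = ss / (n - 2)
        t = np.abs(diff) / np.sqrt(pooled * (1.0 / nin + 1.0 / nout))
    scale = 1.0 + q[n] / n
    degen = valid & (pooled <= 1e-12 * scale)
    t[degen] = np.where(np.abs(diff[degen]) > 1e-9 * math.sqrt(scale), np.inf, 0.0)
    t[~valid] = -1.0
    k = int(np.argmax(t))
    i0, j0 = divmod(k, n + 1)
    tmax = float(t.flat[k])
    if tmax <= 0:
        return None
    return tmax, i0, j0


def _segment_breaks(
    x: np.ndarray,
    alpha: float,
    min_seg: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[int]:
    """Interior breakpoints of one chromosome's ratio profile."""
    breaks: set[int] = set()

    def rec(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        res = _best_arc(seg, min_seg)
        if res is None:
            return
        tobs, i, j = res
        exceed = 0
        for _ in range(n_perm):
            r2 = _best_arc(rng.permutation(seg), min_seg)
            if r2 is not None and r2[0] >= tobs:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        if p >= alpha:
            return
        cuts = sorted(c for c in (i, j) if 0 < c < n)
        if not cuts:
            return
        breaks.update(lo + c for c in cuts)
        for a, b in zip([0, *cuts], [*cuts, n]):
            rec(lo + a, lo + b)

    rec(0, len(x))
    return sorted(breaks)


def segment_log_ratios(
    exons: pd.DataFrame,
    alpha: float = 0.01,
    min_exons: int = 2,
    n_permutations: int = 200,
    seed: int = 0,
) -> list[CnvSegment]:
    """Partition each chromosome's exon ratios into constant-mean segments.

    ``exons`` must carry ``log2_ratio`` (see :func:`compute_log_ratios`);
    rows are taken in chromosome order of first appearance, sorted by start
    within a chromosome.  The permutation test uses ``n_permutations``
    shuffles per candidate split (p-values below 1/(n_permutations+1) are
    unattainable, so alpha must exceed that floor to ever split).
    Deterministic given ``seed``.
    """
    if "log2_ratio" not in exons.columns:
        raise ValueError("exons must carry log2_ratio; run compute_log_ratios first")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if min_exons < 1:
        raise ValueError("min_exons must be >= 1")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100 gives unstable p-values",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    segments: list[CnvSegment] = []
    for chrom in pd.unique(exons["chromosome"]):
        sub = exons[exons["chromosome"] == chrom].sort_values("start", kind="mergesort")
        x = sub["log2_ratio"].to_numpy(float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        bounds = [0, *_segment_breaks(x, alpha, min_exons, n_permutations, rng), len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segments.append(
                CnvSegment(
                    chromosome=str(chrom),
                    first_exon=a,
                    last_exon=b - 1,
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    n_exons=b - a,
                    mean_log2_ratio=float(x[a:b].mean()),
                )
            )
    return segments


def call_segments(
    segments: Sequence[CnvSegment],
    del_cutoff: float = DEFAULT_DELETION_CUTOFF,
    amp_cutoff: float = DEFAULT_AMPLIFICATION_CUTOFF,
) -> tuple[list[CnvSegment], dict[str, int]]:
    """Call each segment against the cutoffs (boundary inclusive) and infer
    its cell fraction under a single-copy change.

    mean ≤ del_cutoff → deletion (Δ = −1); mean ≥ amp_cutoff →
    amplification (Δ = +1); otherwise neutral.  Segments whose mean ratio
    no f ∈ (0, 1] can explain under the assumed Δ are flagged out-of-model
    (e.g. a ratio below −1 needs a biallelic model).  Returns the called
    segments and a count summary; ``total`` counts non-neutral segments.
    """
    if not (del_cutoff < 0 < amp_cutoff):
        raise ValueError("need del_cutoff < 0 < amp_cutoff")
    called: list[CnvSegment] = []
    counts = {DELETION: 0, AMPLIFICATION: 0, NEUTRAL: 0}
    for seg in segments:
        c = seg.mean_log2_ratio
        if c <= del_cutoff:
            call, delta = DELETION, -1
        elif c >= amp_cutoff:
            call, delta = AMPLIFICATION, +1
        else:
            call, delta = NEUTRAL, None
        frac = None
        oom = False
        if delta is not None:
            try:
                frac = cell_fraction_from_ratio(c, delta)
            except OutOfModelError:
                oom = True
        counts[call] += 1
        called.append(
            dataclasses.replace(
                seg, call=call, copy_change=delta, cell_fraction=frac, out_of_model=oom
            )
        )
    counts["total"] = counts[DELETION] + counts[AMPLIFICATION]
    return called, counts


def write_segments(segments: Sequence[CnvSegment], path) -> None:
    """Write called segments to TSV."""
    pd.DataFrame([dataclasses.asdict(s) for s in segments]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# focal biallelic deletions


@dataclass(frozen=True)
class FocalDeletion:
    """A run of exons whose tumor depth collapses toward zero: a focal
    biallelic deletion with inferred cell fraction f = 1 − 2^c."""

    chromosome: str
    first_exon: int
    last_exon: int
    start: int
    end: int
    n_exons: int
    mean_log2_ratio: float
    cell_fraction: float


def detect_focal_biallelic_deletion(
    exons: pd.DataFrame,
    window_exons: int = 3,
    ratio_floor: float = DEFAULT_BIALLELIC_FLOOR,
) -> list[FocalDeletion]:
    """Flag runs of ≥ ``window_exons`` consecutive exons with log2 ratio at
    or below ``ratio_floor`` and report the biallelic-model cell fraction.

    Under Δ = −2 the expected depth ratio is 1 − f, so a near-clonal
    biallelic deletion drives tumor depth toward zero; a heterozygous
    deletion at moderate f (ratio ≈ −0.3) never reaches the default floor.
    """
    if window_exons < 2:
        raise ValueError("window_exons must be >= 2")
    if "log2_ratio" not in exons.columns:
        raise ValueError("exons must carry log2_ratio; run compute_log_ratios first")
    regions: list[FocalDeletion] = []
    for chrom in pd.unique(exons["chromosome"]):
        sub = exons[exons["chromosome"] == chrom].sort_values("start", kind="mergesort")
        x = sub["log2_ratio"].to_numpy(float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        below = x <= ratio_floor
        i = 0
        while i < len(x):
            if not below[i]:
                i += 1
                continue
            j = i
            while j < len(x) and below[j]:
                j += 1
            if j - i >= window_exons:
                c = float(x[i:j].mean())
                regions.append(
                    FocalDeletion(
                        chromosome=str(chrom),
                        first_exon=i,
                        last_exon=j - 1,
                        start=int(starts[i]),
                        end=int(ends[j - 1]),
                        n_exons=j - i,
                        mean_log2_ratio=c,
                        cell_fraction=float(min(1.0, 1.0 - 2.0**c)),
                    )
                )
            i = j
    return regions


# ---------------------------------------------------------------------------
# recurrence across tumors


@dataclass(frozen=True)
class RecurrentRegion:
    """An exon interval carrying the same call in every tumor."""

    chromosome: str
    first_exon: int
    last_exon: int
    call: str


def recurrent_regions(
    segment_sets: Sequence[Sequence[CnvSegment]],
) -> list[RecurrentRegion]:
    """Exon-wise intersection of same-type calls across tumors.

    All tumors must be segmented on the same exon table (checked via
    per-chromosome exon counts).  Returns maximal intervals, per call type,
    present in every tumor.
    """
    if len(segment_sets) < 2:
        raise ValueError("need called segments from at least 2 tumors")

    def layout(segs: Sequence[CnvSegment]) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in segs:
            out[s.chromosome] = max(out.get(s.chromosome, 0), s.last_exon + 1)
        return out

    ref = layout(segment_sets[0])
    for segs in segment_sets[1:]:
        if layout(segs) != ref:
            raise ValueError("tumors segmented on mismatched exon tables")

    regions: list[RecurrentRegion] = []
    for call in (DELETION, AMPLIFICATION):
        for chrom, n in ref.items():
            shared = np.ones(n, bool)
            for segs in segment_sets:
                mask = np.zeros(n, bool)
                for s in segs:
                    if s.chromosome == chrom and s.call == call:
                        mask[s.first_exon : s.last_exon + 1] = True
                shared &= mask
            i = 0
            while i < n:
                if not shared[i]:
                    i += 1
                    continue
                j = i
                while j < n and shared[j]:
                    j += 1
                regions.append(RecurrentRegion(str(chrom), i, j - 1, call))
                i = j
    return regions
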