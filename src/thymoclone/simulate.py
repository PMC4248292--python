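"""Synthetic TCRβ repertoires, paired exome coverage, and mutation lists.

The generators reproduce the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any sequencing data:

* a polyclonal background repertoire with heavy-tailed clone sizes whose
  most expanded clone sits near 0.1% of reads (a wild-type thymus), onto
  which expanded clones at configured read fractions can be layered (an
  oligoclonal lymphoma);
* per-exon tumor/normal read depths where a copy-number lesion carried by a
  fraction ``f`` of tumor cells with copy change ``Δ`` scales the expected
  tumor depth by ``1 + f·Δ/2`` (diploid background);
* somatic point mutations as a Poisson count over a callable genome length.

All randomness flows from the explicit ``seed`` in each config; the same
seed reproduces the same records byte for byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .repertoire import (
    NONPRODUCTIVE,
    PRODUCTIVE,
    RepertoireSample,
    write_clone_table,
)

_BASES = np.array(list("ACGT"))

#: Small fixed V/D/J label pools (mouse TRB naming).
V_GENES = tuple(f"TRBV{i}" for i in range(1, 20))
D_GENES = ("TRBD1", "TRBD2")
J_GENES = tuple(f"TRBJ{c}-{i}" for c in (1, 2) for i in range(1, 8))


# ---------------------------------------------------------------------------
# configs


@dataclass
class RepertoireSimConfig:
    """Parameters of a simulated TCRβ repertoire.

    ``expanded_clone_fractions`` are the expected read fractions of the
    dominant clones (empty for a wild-type-like sample); the remaining reads
    are split among ``n_background_clones`` background clones whose sizes
    follow a rank power law with exponent ``background_dispersion`` (each
    background clone keeps at least one read).  The defaults describe a
    wild-type survey of 2×10^5 templates whose top background clone lands
    near 0.11% of reads.
    """

    n_reads: int = 200_000
    n_background_clones: int = 50_000
    expanded_clone_fractions: Sequence[float] = ()
    in_frame_probability: float = 1 / 3
    background_dispersion: float = 0.45
    seed: int = 0
    cdr3_length: int = 45

    def validate(self) -> None:
        fr = np.asarray(self.expanded_clone_fractions, float)
        if fr.size and (np.any(fr <= 0) or np.any(fr >= 1)):
            raise ValueError("expanded clone fractions must lie in (0, 1)")
        if fr.sum() >= 1:
            raise ValueError(
                f"expanded clone fractions sum to {fr.sum():g} >= 1 "
                "(inconsistent composition)"
            )
        if not (self.n_reads >= self.n_background_clones >= 1):
            raise ValueError("need n_reads >= n_background_clones >= 1")
        if not 0 <= self.in_frame_probability <= 1:
            raise ValueError("in_frame_probability must be in [0, 1]")
        if self.background_dispersion < 0:
            raise ValueError("background_dispersion must be >= 0")


@dataclass(frozen=True)
class Lesion:
    """A copy-number lesion: genomic interval, integer copy change Δ, and
    the fraction f of tumor cells carrying it."""

    chromosome: str
    start: int
    end: int
    copy_change: int
    cell_fraction: float

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError("lesion interval must have start < end")
        if not isinstance(self.copy_change, (int, np.integer)) or self.copy_change == 0:
            raise ValueError("copy_change must be a nonzero integer")
        if self.copy_change < -2:
            raise ValueError("copy_change below -2 is not representable (diploid locus)")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")

    @property
    def expected_ratio(self) -> float:
        return 1.0 + self.cell_fraction * self.copy_change / 2.0


@dataclass
class CoverageSimConfig:
    """Paired tumor/normal exon coverage with embedded lesions.

    ``exon_table`` is a DataFrame (chromosome, start, end; 0-based
    half-open) or an iterable of such tuples.  Noise is Poisson by default;
    ``noise_model='negative-binomial'`` adds over-dispersion with size
    parameter ``dispersion`` (variance = m + m²/dispersion).
    """

    exon_table: pd.DataFrame
    mean_depth: float = 200.0
    lesions: Sequence[Lesion] = ()
    noise_model: str = "poisson"
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.exon_table, pd.DataFrame):
            self.exon_table = pd.DataFrame(
                list(self.exon_table), columns=["chromosome", "start", "end"]
            )
        self.lesions = tuple(
            l if isinstance(l, Lesion) else Lesion(*l) for l in self.lesions
        )

    def validate(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.noise_model not in {"poisson", "negative-binomial"}:
            raise ValueError(f"unknown noise model: {self.noise_model!r}")
        if self.noise_model == "negative-binomial" and not (self.dispersion or 0) > 0:
            raise ValueError("negative-binomial noise requires dispersion > 0")
        hit_any = _lesion_exon_matrix(self.exon_table, self.lesions)
        for lesion, hits in zip(self.lesions, hit_any):
            lesion.validate()
            if lesion.chromosome not in set(self.exon_table["chromosome"]):
                raise ValueError(f"lesion chromosome {lesion.chromosome!r} not in exon table")
            if not hits.any():
                raise ValueError(f"lesion {lesion} overlaps no exon in the table")
        if len(self.lesions) > 1:
            overlap = np.asarray(hit_any).sum(axis=0)
            if (overlap > 1).any():
                i = int(np.argmax(overlap > 1))
                raise ValueError(
                    f"lesions overlap on exon index {i} (ambiguous expected ratio)"
                )


@dataclass
class MutationSimConfig:
    """Somatic point mutations: Poisson count with mean callable_mb × μ,
    positions uniform over the callable space."""

    callable_mb: float = 100.0
    rate_per_mb: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.callable_mb <= 0:
            raise ValueError("callable_mb must be positive")
        if self.rate_per_mb < 0:
            raise ValueError("rate_per_mb must be >= 0")


# ---------------------------------------------------------------------------
# repertoire simulation


def _unique_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct random nucleotide strings of the given length."""
    seqs = np.array([""], dtype=object)[:0]
    need = n
    while need > 0:
        block = rng.integers(0, 4, size=(need, length))
        new = np.array(["".join(s) for s in _BASES[block]], dtype=object)
        seqs = pd.unique(np.concatenate([seqs, new]))
        need = n - len(seqs)
    return seqs[:n]


def simulate_repertoire(
    config: RepertoireSimConfig,
    sample_id: str | None = None,
    genotype: str | None = None,
    age_weeks: float = 20.0,
    sex: str = "m",
) -> RepertoireSample:
    """Draw a repertoire sample under the configured composition.

    Reads are assigned multinomially to the expanded clones (expected share
    = configured fraction) and to a background pool.  The background pool is
    conditioned to contain exactly ``n_background_clones`` realized clones,
    each with at least one read; extra background reads are spread with
    rank-power-law weights, producing the heavy right tail of real
    repertoires.  When the background read budget is smaller than the
    requested clone count (heavily expanded samples) the realized clone
    count shrinks to that budget.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    fr = np.asarray(config.expanded_clone_fractions, float)
    probs = np.concatenate([fr, [1.0 - fr.sum()]])
    counts = rng.multinomial(config.n_reads, probs)
    expanded_counts, bg_reads = counts[:-1], int(counts[-1])

    n_bg = min(config.n_background_clones, bg_reads)
    if n_bg > 0:
        ranks = np.arange(1, n_bg + 1, dtype=float)
        w = ranks ** -config.background_dispersion
        w /= w.sum()
        bg_counts = 1 + rng.multinomial(bg_reads - n_bg, w)
    else:
        bg_counts = np.zeros(0, dtype=int)

    all_counts = np.concatenate([expanded_counts, bg_counts])
    keep = all_counts > 0
    all_counts = all_counts[keep]
    n_total = len(all_counts)

    seqs = _unique_sequences(rng, n_total, config.cdr3_length)
    frame = np.where(
        rng.random(n_total) < config.in_frame_probability, PRODUCTIVE, NONPRODUCTIVE
    )
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "v_gene": rng.choice(V_GENES, n_total),
            "d_gene": rng.choice(D_GENES, n_total),
            "j_gene": rng.choice(J_GENES, n_total),
            "frame_status": frame,
            "read_count": all_counts,
        }
    )
    df["frequency"] = df["read_count"] / df["read_count"].sum()
    if genotype is None:
        genotype = "p53-knockout" if fr.size else "wild-type"
    return RepertoireSample(
        sample_id=sample_id or f"sim-{config.seed}",
        clones=df,
        genotype=genotype,
        age_weeks=age_weeks,
        sex=sex,
    )


# ---------------------------------------------------------------------------
# coverage simulation


def _lesion_exon_matrix(exons: pd.DataFrame, lesions: Sequence[Lesion]) -> list[np.ndarray]:
    """Boolean overlap vector (one per lesion) over the exon table."""
    chrom = exons["chromosome"].to_numpy()
    start = exons["start"].to_numpy()
    end = exons["end"].to_numpy()
    out = []
    for lesion in lesions:
        out.append((chrom == lesion.chromosome) & (start < lesion.end) & (end > lesion.start))
    return out


def simulate_coverage(config: CoverageSimConfig) -> pd.DataFrame:
    """Per-exon tumor/normal depths under the configured lesions.

    Normal depths are i.i.d. with mean ``mean_depth``; tumor depths have
    mean ``mean_depth × (1 + f·Δ/2)`` inside a lesion and ``mean_depth``
    elsewhere, so the expected log2 depth ratio over a lesion is
    ``log2(1 + f·Δ/2)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    exons = config.exon_table.reset_index(drop=True)
    ratio = np.ones(len(exons))
    for lesion, hits in zip(config.lesions, _lesion_exon_matrix(exons, config.lesions)):
        ratio[hits] = lesion.expected_ratio

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.noise_model == "poisson":
            return rng.poisson(mean)
        k = float(config.dispersion)  # var = m + m^2/k
        mean = np.maximum(mean, 1e-12)
        return rng.negative_binomial(k, k / (k + mean))

    out = exons.copy()
    out["normal_depth"] = draw(np.full(len(exons), float(config.mean_depth)))
    out["tumor_depth"] = draw(float(config.mean_depth) * ratio)
    return out


# ---------------------------------------------------------------------------
# mutation simulation


def simulate_mutations(config: MutationSimConfig) -> pd.DataFrame:
    """Synthetic somatic point mutations (chrom, pos, ref, alt)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(rng.poisson(config.callable_mb * config.rate_per_mb))
    span = int(config.callable_mb * 1e6)
    pos = np.sort(rng.integers(1, span + 1, size=n))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame(
        {
            "chrom": ["chrS"] * n,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


# ---------------------------------------------------------------------------
# fixture bundle


def _config_to_manifest(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    if "exon_table" in d:
        d["exon_table"] = "exons.bed"
        d["lesions"] = [dataclasses.asdict(l) for l in cfg.lesions]
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
        if isinstance(v, np.generic):
            d[k] = v.item()
    return d


def write_fixture_bundle(
    out_dir,
    repertoire_configs: Mapping[str, RepertoireSimConfig] | None = None,
    coverage_config: CoverageSimConfig | None = None,
    mutation_config: MutationSimConfig | None = None,
) -> dict[str, str]:
    """Simulate and write a complete text fixture set plus a manifest.

    Emits one clone TSV per repertoire config, an exon BED + depth TSV for
    coverage, a mutation TSV, and ``manifest.yaml`` echoing every config and
    seed, so the bundle is exactly reproducible.  Returns a name → path map.
    """
    out = Path(out_dir)
    if not out.is_dir():
        raise FileNotFoundError(f"fixture directory does not exist: {out}")
    paths: dict[str, str] = {}
    manifest: dict = {"repertoires": {}, "coverage": None, "mutations": None}

    for name, cfg in (repertoire_configs or {}).items():
        sample = simulate_repertoire(cfg, sample_id=name)
        p = out / f"clones_{name}.tsv"
        write_clone_table(sample, p)
        paths[f"clones_{name}"] = str(p)
        manifest["repertoires"][name] = _config_to_manifest(cfg)

    if coverage_config is not None:
        cov = simulate_coverage(coverage_config)
        bed = out / "exons.bed"
        cov[["chromosome", "start", "end"]].to_csv(bed, sep="\t", index=False, header=False)
        depths = out / "depths.tsv"
        dep = cov[["tumor_depth", "normal_depth"]].copy()
        dep.insert(0, "exon_index", np.arange(len(cov)))
        dep.to_csv(depths, sep="\t", index=False)
        paths["exons"] = str(bed)
        paths["depths"] = str(depths)
        manifest["coverage"] = _config_to_manifest(coverage_config)

    if mutation_config is not None:
        mut = simulate_mutations(mutation_config)
        p = out / "mutations.tsv"
        mut.to_csv(p, sep="\t", index=False)
        paths["mutations"] = str(p)
        manifest["mutations"] = _config_to_manifest(mutation_config)

    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    paths["manifest"] = str(mpath)
    return paths
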