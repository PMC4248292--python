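"""End-to-end orchestration: simulate → clonality → CNV → ordering → rates.

One YAML config (or the built-in demo config) drives a reproducible run.
Every stage parameter defaults to the analysis's anchor values: 30-fold
detection threshold, −0.3/0.2 calling cutoffs, ordering tolerance τ = 0.05,
and the 77-day (9→20 wk) clone-emergence window.  The report JSON is a pure
function of config + inputs + seed (timestamps live in the run log only),
so replaying a config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import ordering as ord_mod
from . import repertoire as rep_mod
from . import simulate as sim_mod
from ._version import __version__

log = logging.getLogger("thymoclone")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        log.error("stage %s: failed (%s)", name, exc)
        raise PipelineError(name, exc) from exc
    log.info("stage %s: done", name)


def _defaults() -> dict:
    return {
        "clonality": {
            "baseline": rep_mod.DEFAULT_BASELINE_TOP_FREQUENCY,
            "fold_threshold": rep_mod.DEFAULT_FOLD_THRESHOLD,
        },
        "cnv": {
            "pseudocount": 0.5,
            "normalize": True,
            "exclude_chr_y": False,
            "del_cutoff": cnv_mod.DEFAULT_DELETION_CUTOFF,
            "amp_cutoff": cnv_mod.DEFAULT_AMPLIFICATION_CUTOFF,
            "alpha": 0.01,
            "min_exons": 2,
            "n_permutations": 200,
            "biallelic_window": 3,
        },
        "ordering": {
            "tolerance": ord_mod.DEFAULT_TOLERANCE,
            "dominant_min_frequency": 0.05,
            "tumor_sample": None,
            "lesion_fraction": None,
        },
        "rates": {
            "callable_mb": None,
            "window_days": ord_mod.DEFAULT_WINDOW_DAYS,
            "n_clones": None,
        },
    }


@dataclass
class RunConfig:
    """Full run configuration; unspecified stage parameters fall back to
    the anchor defaults."""

    seed: int = 0
    output_dir: str = "thymoclone-run"
    simulate: dict | None = None
    inputs: dict | None = None
    clonality: dict = field(default_factory=dict)
    cnv: dict = field(default_factory=dict)
    ordering: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, defaults in _defaults().items():
            merged = dict(defaults)
            merged.update(getattr(self, name) or {})
            setattr(self, name, merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_exon_table(specs: list[dict]) -> pd.DataFrame:
    """Build an exon BED-like table from compact per-chromosome specs:
    {chromosome, n_exons, exon_length=150, spacing=2000, offset=0}."""
    rows = []
    for spec in specs:
        n = int(spec["n_exons"])
        length = int(spec.get("exon_length", 150))
        spacing = int(spec.get("spacing", 2000))
        offset = int(spec.get("offset", 0))
        for i in range(n):
            start = offset + i * spacing
            rows.append((spec["chromosome"], start, start + length))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def _lesions_from_specs(specs: list[dict], exons: pd.DataFrame) -> list[sim_mod.Lesion]:
    """Lesion dicts may give genomic start/end or chromosome-local exon
    indices (first_exon/last_exon, inclusive)."""
    lesions = []
    for spec in specs:
        chrom = spec["chromosome"]
        if "start" in spec and "end" in spec:
            start, end = int(spec["start"]), int(spec["end"])
        else:
            sub = exons[exons["chromosome"] == chrom].sort_values("start")
            start = int(sub.iloc[int(spec["first_exon"])]["start"])
            end = int(sub.iloc[int(spec["last_exon"])]["end"])
        lesions.append(
            sim_mod.Lesion(
                chromosome=chrom,
                start=start,
                end=end,
                copy_change=int(spec["copy_change"]),
                cell_fraction=float(spec["cell_fraction"]),
            )
        )
    return lesions


def default_demo_config(seed: int = 0, output_dir: str = "demo-run") -> RunConfig:
    """An all-synthetic demonstration run: one wild-type thymus, one
    oligoclonal tumor with two dominant clones (76.7% / 9.7%), a genome of
    four chromosomes carrying a whole-chromosome gain (f = 0.5), a broad
    heterozygous deletion (f = 0.38), and a near-clonal focal biallelic
    deletion (f = 0.98), plus ~100 point mutations over 100 Mb."""
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        simulate={
            "repertoires": {
                "wt-20wk": {
                    "n_reads": 30_000,
                    "n_background_clones": 12_000,
                    "expanded_clone_fractions": [],
                    "genotype": "wild-type",
                },
                "tumor-m2": {
                    "n_reads": 50_000,
                    "n_background_clones": 5_000,
                    "expanded_clone_fractions": [0.767, 0.097],
                    "genotype": "p53-knockout",
                },
            },
            "coverage": {
                "exons": [
                    {"chromosome": "chr5", "n_exons": 70},
                    {"chromosome": "chr10", "n_exons": 70},
                    {"chromosome": "chr11", "n_exons": 70},
                    {"chromosome": "chr19", "n_exons": 70},
                ],
                "mean_depth": 200.0,
                "lesions": [
                    {"chromosome": "chr5", "first_exon": 0, "last_exon": 69,
                     "copy_change": 1, "cell_fraction": 0.5},
                    {"chromosome": "chr10", "first_exon": 20, "last_exon": 49,
                     "copy_change": -1, "cell_fraction": 0.38},
                    {"chromosome": "chr19", "first_exon": 30, "last_exon": 34,
                     "copy_change": -2, "cell_fraction": 0.98},
                ],
            },
            "mutations": {"callable_mb": 100.0, "rate_per_mb": 1.0},
        },
        ordering={"tumor_sample": "tumor-m2"},
        rates={"callable_mb": 100.0},
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _simulate_stage(config: RunConfig, out: Path) -> dict[str, str]:
    spec = config.simulate or {}
    rep_specs = spec.get("repertoires", {})
    seeds = _child_seeds(config.seed, len(rep_specs) + 2)
    rep_configs = {}
    meta = {}
    for i, (name, rspec) in enumerate(rep_specs.items()):
        rspec = dict(rspec)
        meta[name] = {
            "genotype": rspec.pop("genotype", None),
            "age_weeks": rspec.pop("age_weeks", 20.0),
            "sex": rspec.pop("sex", "m"),
        }
        rspec.setdefault("seed", seeds[i])
        rep_configs[name] = sim_mod.RepertoireSimConfig(**rspec)

    cov_config = None
    if "coverage" in spec:
        cspec = dict(spec["coverage"])
        exons = make_exon_table(cspec.pop("exons"))
        lesions = _lesions_from_specs(cspec.pop("lesions", []), exons)
        cspec.setdefault("seed", seeds[-2])
        cov_config = sim_mod.CoverageSimConfig(exon_table=exons, lesions=lesions, **cspec)

    mut_config = None
    if "mutations" in spec:
        mspec = dict(spec["mutations"])
        mspec.setdefault("seed", seeds[-1])
        mut_config = sim_mod.MutationSimConfig(**mspec)

    fixtures = out / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    paths = sim_mod.write_fixture_bundle(
        fixtures,
        repertoire_configs=rep_configs,
        coverage_config=cov_config,
        mutation_config=mut_config,
    )
    inputs = {
        "clone_tables": {
            name: paths[f"clones_{name}"] for name in rep_configs
        },
        "sample_metadata": meta,
    }
    if cov_config is not None:
        inputs["coverage"] = {"bed": paths["exons"], "depths": paths["depths"]}
    if mut_config is not None:
        inputs["mutations"] = paths["mutations"]
    return inputs


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write the consolidated report.

    Returns the report dict; also writes ``report.json``, ``segments.tsv``
    and ``clonality.tsv`` under the configured output directory and logs
    each stage to stderr and ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    report: dict = {
        "provenance": {
            "package": "thymoclone",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
        }
    }

    if config.simulate:
        with _stage("simulate"):
            inputs = _simulate_stage(config, out)
    else:
        inputs = dict(config.inputs or {})
    meta = inputs.get("sample_metadata", {})

    samples: dict[str, rep_mod.RepertoireSample] = {}
    with _stage("clonality"):
        summaries = {}
        for name, path in (inputs.get("clone_tables") or {}).items():
            if not Path(path).exists():
                raise FileNotFoundError(f"clone table not found: {path}")
            m = {k: v for k, v in (meta.get(name) or {}).items() if v is not None}
            samples[name] = rep_mod.read_clone_table(path, sample_id=name, **m)
            summaries[name] = rep_mod.clonality_summary(
                samples[name],
                baseline_mean_top_freq=config.clonality["baseline"],
                fold_threshold=config.clonality["fold_threshold"],
            ).to_dict()
            log.info(
                "clonality %s: %d clones, top replicated %.4g, fold %.3g",
                name,
                summaries[name]["unique_clone_count"],
                summaries[name]["top_replicated_frequency"],
                summaries[name]["fold_change_vs_baseline"],
            )
        report["clonality"] = summaries

    focal_regions: list[cnv_mod.FocalDeletion] = []
    if inputs.get("coverage"):
        with _stage("cnv"):
            cov = inputs["coverage"]
            if "table" in cov:
                if not Path(cov["table"]).exists():
                    raise FileNotFoundError(f"coverage table not found: {cov['table']}")
                exons = cnv_mod.read_coverage_table(cov["table"])
            else:
                for key in ("bed", "depths"):
                    if not Path(cov[key]).exists():
                        raise FileNotFoundError(f"coverage {key} file not found: {cov[key]}")
                exons = cnv_mod.read_coverage(cov["bed"], cov["depths"])
            p = config.cnv
            exons = cnv_mod.compute_log_ratios(
                exons,
                pseudocount=p["pseudocount"],
                normalize=p["normalize"],
                exclude_chr_y=p["exclude_chr_y"],
            )
            segments = cnv_mod.segment_log_ratios(
                exons,
                alpha=p["alpha"],
                min_exons=p["min_exons"],
                n_permutations=p["n_permutations"],
                seed=config.seed,
            )
            called, counts = cnv_mod.call_segments(
                segments, del_cutoff=p["del_cutoff"], amp_cutoff=p["amp_cutoff"]
            )
            focal_regions = cnv_mod.detect_focal_biallelic_deletion(
                exons, window_exons=p["biallelic_window"]
            )
            cnv_mod.write_segments(called, out / "segments.tsv")
            chrom_counts = exons["chromosome"].value_counts().to_dict()
            report["cnv"] = {
                "segments": [dataclasses.asdict(s) for s in called],
                "counts": counts,
                "focal_biallelic": [dataclasses.asdict(r) for r in focal_regions],
                "chromosome_exon_counts": {str(k): int(v) for k, v in chrom_counts.items()},
                "parameters": dict(p),
            }
            log.info("cnv: %d segments, %d CNVs, %d focal biallelic region(s)",
                     len(called), counts["total"], len(focal_regions))

    with _stage("ordering"):
        calls = []
        tumor_name = config.ordering["tumor_sample"]
        if tumor_name is None:
            detected = [n for n, s in report.get("clonality", {}).items()
                        if s["lymphoma_detected"]]
            tumor_name = detected[0] if detected else None
        dominant: list[float] = []
        if tumor_name is not None and tumor_name in samples:
            min_f = config.ordering["dominant_min_frequency"]
            dominant = [
                f for _, f in rep_mod.top_k_fractions(samples[tumor_name], 10)
                if f >= min_f
            ]
        lesion_fraction = config.ordering["lesion_fraction"]
        lesions: list[tuple[str, float]] = []
        if lesion_fraction is not None:
            lesions.append(("configured-lesion", float(lesion_fraction)))
        lesions.extend(
            (f"focal-biallelic-{r.chromosome}:{r.start}-{r.end}", r.cell_fraction)
            for r in focal_regions
        )
        if dominant:
            for lesion_id, f_l in lesions:
                call = ord_mod.order_lesion(
                    f_l, dominant,
                    tolerance=config.ordering["tolerance"],
                    lesion_id=lesion_id,
                )
                calls.append(call.to_dict())
                log.info("ordering %s: f=%.3f vs %d clones -> %s",
                         lesion_id, f_l, len(dominant), call.verdict)
        report["ordering"] = calls

    with _stage("rates"):
        n_mut = None
        if inputs.get("mutations"):
            if not Path(inputs["mutations"]).exists():
                raise FileNotFoundError(f"mutation table not found: {inputs['mutations']}")
            n_mut = len(pd.read_csv(inputs["mutations"], sep="\t"))
        callable_mb = config.rates["callable_mb"]
        if callable_mb is None and config.simulate and "mutations" in config.simulate:
            callable_mb = config.simulate["mutations"].get("callable_mb")
        n_clones = config.rates["n_clones"]
        if n_clones is None and dominant:
            n_clones = len(dominant)
        rates = ord_mod.estimate_rates(
            n_mutations=n_mut,
            callable_mb=callable_mb,
            n_clones=n_clones,
            window_days=config.rates["window_days"],
        )
        report["rates"] = rates.to_dict()
        log.info("rates: %s mutations/Mb, %s clones/day",
                 rates.mutations_per_mb, rates.clones_per_day)

    with _stage("report"):
        if report.get("clonality"):
            pd.DataFrame(
                [
                    {"sample_id": k, **{kk: vv for kk, vv in v.items()
                                        if not isinstance(vv, (list, dict))}}
                    for k, v in report["clonality"].items()
                ]
            ).to_csv(out / "clonality.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


# ---------------------------------------------------------------------------
# report validation


def validate_report(path) -> tuple[bool, list[str]]:
    """Schema and invariant checks on a pipeline report.

    Verifies that histogram counts sum to the unique-clone count, fold
    changes and detection flags are consistent, CNV segments partition each
    chromosome and respect the cutoffs, ordering verdicts reproduce under
    the stated rule, and rates match their echoed inputs.
    """
    msgs: list[str] = []
    p = Path(path)
    if not p.exists():
        return False, [f"report file not found: {path}"]
    text = p.read_text()
    if not text.strip():
        return False, [f"report file is empty: {path}"]
    try:
        report = json.loads(text)
    except json.JSONDecodeError as exc:
        return False, [f"malformed JSON at line {exc.lineno} col {exc.colno}: {exc.msg}"]
    if not isinstance(report, dict):
        return False, ["report root must be a JSON object"]

    for key in ("provenance", "clonality", "ordering", "rates"):
        if key not in report:
            msgs.append(f"missing top-level key: {key}")
    if msgs:
        return False, msgs

    for name, s in report["clonality"].items():
        hist_total = sum(b[2] for b in s["histogram"])
        if hist_total != s["unique_clone_count"]:
            msgs.append(
                f"{name}: histogram counts sum to {hist_total}, "
                f"expected unique_clone_count {s['unique_clone_count']}"
            )
        expect_fold = s["top_replicated_frequency"] / s["baseline_mean_top_freq"]
        if not math.isclose(s["fold_change_vs_baseline"], expect_fold, rel_tol=1e-9):
            msgs.append(f"{name}: fold_change_vs_baseline inconsistent with "
                        "top_replicated_frequency / baseline")
        if s["lymphoma_detected"] != (
            s["fold_change_vs_baseline"] >= s["fold_threshold"]
        ):
            msgs.append(f"{name}: lymphoma_detected inconsistent with fold threshold")
        if not 0 <= s["top_replicated_frequency"] <= 1:
            msgs.append(f"{name}: top_replicated_frequency outside [0, 1]")

    if "cnv" in report:
        c = report["cnv"]
        per_chrom: dict[str, int] = {}
        for seg in c["segments"]:
            per_chrom[seg["chromosome"]] = per_chrom.get(seg["chromosome"], 0) + seg["n_exons"]
            del_cut = c["parameters"]["del_cutoff"]
            amp_cut = c["parameters"]["amp_cutoff"]
            m = seg["mean_log2_ratio"]
            want = ("deletion" if m <= del_cut
                    else "amplification" if m >= amp_cut else "neutral")
            if seg["call"] != want:
                msgs.append(f"segment {seg['chromosome']}:{seg['start']}-{seg['end']}: "
                            f"call {seg['call']!r} inconsistent with mean ratio {m:.3f}")
        for chrom, n in c["chromosome_exon_counts"].items():
            if per_chrom.get(chrom, 0) != n:
                msgs.append(f"{chrom}: segments cover {per_chrom.get(chrom, 0)} exons, "
                            f"table has {n} (segments must partition the chromosome)")

    for call in report["ordering"]:
        redo = ord_mod.order_lesion(
            call["lesion_cell_fraction"],
            call["clone_fractions"],
            tolerance=call["tolerance"],
            lesion_id=call["lesion_id"],
        )
        if redo.verdict != call["verdict"]:
            msgs.append(f"ordering {call['lesion_id']}: stored verdict "
                        f"{call['verdict']!r} does not reproduce ({redo.verdict!r})")

    r = report["rates"]
    if r.get("mutations_per_mb") is not None:
        if not math.isclose(
            r["mutations_per_mb"], r["n_mutations"] / r["callable_mb"], rel_tol=1e-9
        ):
            msgs.append("rates: mutations_per_mb inconsistent with echoed inputs")
    if r.get("clones_per_day") is not None:
        if not math.isclose(
            r["clones_per_day"], r["n_clones"] / r["window_days"], rel_tol=1e-9
        ):
            msgs.append("rates: clones_per_day inconsistent with echoed inputs")

    return (len(msgs) == 0), msgs
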