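# thymoclone

Tools for analysing the clonal evolution of thymic T-cell lymphomas from
two complementary genomic readouts: **TCRβ repertoire sequencing** (each
V(D)J rearrangement is a natural clonal barcode) and **whole-exome
tumor/normal read depth** (copy-number lesions and their cell fractions).
The package targets mouse models in which loss of a genome-guardian gene
(p53) produces oligoclonal thymic lymphomas, but the statistics are
generic to any repertoire + exome design.

## What it computes

**Repertoire clonality.** For an ImmunoSeq-style clone table the package
reports the unique-clone count, the frequency of the most expanded
*replicated* clone (read count ≥ 2), clone-frequency histograms, the
productive/nonproductive read ratio, and a fold-change detection rule: a
thymus whose top replicated clone exceeds the wild-type baseline
(default 0.11% of reads) by ≥ 30-fold is called a detected lymphoma.

**Copy number from depth ratios.** Per-exon log2 tumor/normal depth
ratios are segmented by a circular-binary-segmentation-style recursion
(max-t arcs tested against a permutation null) and called against cutoffs
of −0.3 (deletion) and +0.2 (amplification), boundary inclusive. The
admixture algebra links a segment mean `c` to the fraction `f` of tumor
cells carrying an integer copy change `Δ` on a diploid background:

    ratio = 1 + f·Δ/2,      c = log2(ratio),      f = 2·(2^c − 1)/Δ

so `c = −0.3` under a one-copy deletion means `f ≈ 38%`, and `c = +0.2`
under a one-copy gain means `f ≈ 30%`. Focal biallelic deletions
(`Δ = −2`, expected ratio `1 − f`) are flagged where tumor depth
collapses below 15% of normal over a run of exons. Calls shared by every
tumor are intersected into recurrent regions.

**Clonal ordering and rates.** A lesion carried by a larger share of
tumor DNA than any single TCRβ clone — roughly the union of all clones —
must predate the rearrangements that individuate the clones:

    pre_rearrangement   if  f_L ≥ Σ clones − τ  and  f_L > max clone + τ
    post_rearrangement  if  f_L ≤ max clone + τ        (τ = 0.05 default)

Rate estimators: somatic point mutations per Mb of callable sequence
(100 mutations / 100 Mb → 1.0 per Mb) and distinct contributing clones
per day over an observation window (10 clones / 77 days → 0.13 per day).

**Synthetic data.** `thymoclone.simulate` generates repertoires (Zipf-like
background plus configured dominant clones), paired exome coverage with
embedded lesions, and mutation lists — everything needed to exercise the
pipeline end to end with known ground truth.

## Worked example

The built-in demo simulates a wild-type thymus, an oligoclonal tumor with
two dominant clones (76.7% / 9.7% of reads), and a four-chromosome exome
carrying a whole-chromosome gain (f = 0.5), a broad heterozygous deletion
(f = 0.38), and a near-clonal focal biallelic deletion (f = 0.98):

```sh
thymoclone run --demo --seed 1 --out-dir demo-run
```

prints (abridged):

```json
{
  "counts": {"amplification": 1, "deletion": 2, "neutral": 5, "total": 3},
  "ordering": [
    {
      "clone_fractions": [0.76788, 0.09698],
      "lesion_cell_fraction": 0.9767686182825449,
      "lesion_id": "focal-biallelic-chr19:60000-68150",
      "verdict": "pre_rearrangement"
    }
  ],
  "rates": {
    "mutations_per_mb": 1.02,
    "clones_per_day": 0.025974025974025976,
    "n_mutations": 102, "n_clones": 2, "window_days": 77.0
  }
}
```

Reading it: all three embedded lesions are recovered (3 CNV calls); the
focal biallelic deletion is inferred to sit in ~98% of tumor cells, more
than the two dominant TCRβ clones combined (86.5%), so it is ordered
*before* TCRβ rearrangement; the mutation-rate estimate recovers the
simulated 1 per Mb. The full `report.json` (plus `segments.tsv`,
`clonality.tsv`, and a reproducibility manifest) lands in `demo-run/`;
`thymoclone validate demo-run/report.json` re-checks its invariants.
The same subcommands (`simulate`, `clonality`, `cnv`, `order-lesions`,
`rates`, `run`, `validate`) are thin wrappers over the library API shown
in the module docstrings.

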