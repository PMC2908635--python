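# probesieve

Scoring, selection and experimental quality screening of long-oligonucleotide
gene-expression microarray probes.

## The problem

Custom 60-mer expression arrays need exactly one reliable probe per coding
sequence (CDS). Candidate probes from a design service are plentiful, but in
draft genomes the gene models behind them are shaky: intron boundaries are
mispredicted, annotations get revised, and thermodynamic predictions assume
probes in solution rather than on a surface. `probesieve` implements a
two-stage screen for this situation:

1. **In silico scoring.** Every candidate probe is scored on four criteria
   and the scores are summed into a final score:

   | criterion | measure | 0 | 1 | 4 | 20 |
   |---|---|---|---|---|---|
   | cross-hybridization identity (CHI) | max % identity vs any non-target CDS | ≤ 60% | 61–84% | ≥ 85% | — |
   | self-folding | hairpin ΔG (kcal/mol, 37 °C) | > −8 | ≤ −8 | — | — |
   | position in CDS | nt from the CDS 3′ end | 1–500 | 501–1000 | > 1000 | — |
   | intron relation | class 1 / 2 / 3 (exonic / just downstream of an intron 3′ end / overlapping an intron) | class 1 | class 2 | class 3 | — |
   | sequence match | after genome re-annotation | perfect match | — | — | mismatch |

   CHI comes from a word-seeded ungapped search (word 7, +2/−3 scoring)
   tuned to detect ≥ 70% identity over 20 contiguous bases, or from an
   external 12-column tabular alignment file. A first selection round admits
   probes with final score < 4 that start more than 100 nt from the CDS
   3′ end and keeps the four closest to the 3′ end; a second round tops up
   short panels with probes scoring ≤ 8 (recovering intron-overlapping
   probes whose introns are EST-confirmed), excluding CHI > 85% and starts
   beyond the 3′-terminal 1500 nt. After a re-annotation, probes whose
   sequence no longer matches their target CDS get score 20 and drop out.

2. **Experimental QC.** The selected panels are printed on a test array and
   hybridized (conditions × biological replicates against a common reference
   pool). Per probe: discard when SSR = (fg − bg)/bg_sd < 10 **and**
   SBR = fg/bg < 2 in all samples or all but one; discard when the CV of the
   normalized signal exceeds 0.75 in any condition (unless an expert rescue
   list retains it); discard when the probe's median reference-channel
   intensity M_probe falls outside the interquartile range of its CDS
   siblings, or its sample-channel intensity is outside the CDS mean
   ± 1.5 × 95% CI on every array. One probe per CDS is then elected — the
   qualified probe closest to the 3′ end — with a supervised-rescue fallback
   for probe-deficient CDS and a QC bypass for probes (e.g. mitochondrial)
   that only undergo computational screening.

A deterministic synthetic-data generator (`probesieve.simulate`) produces
genomes, annotations, probes and spot-level two-channel intensities with
planted, ground-truthed defects, so every rule above is testable without
array data.

## Worked example

Simulate a 200-gene study and run the whole pipeline:

```sh
probesieve simulate --seed 1 --n-genes 200 --out fx
probesieve run --config run.yaml --out out      # run.yaml lists the fx/ paths
```

The printed summary (also written to `out/summary.json`):

```json
{
  "n_probes": 800,
  "per_filter": {
    "SNR_FAIL":    {"rejected": 32,  "qualified": 768},
    "CV_FAIL":     {"rejected": 8,   "qualified": 792},
    "MPROBE_FAIL": {"rejected": 400, "qualified": 400},
    "MARRAY_FAIL": {"rejected": 8,   "qualified": 792}
  },
  "n_cds": 200,
  "cds_with_qualified_probe": 190,
  "probe_deficient_cds": 10,
  "rescued_cds": 10
}
```

Reading it: the 32 probes of the 8 unexpressed genes fail the
signal-to-noise rule, the 8 planted high-variance probes fail the CV rule,
and the 8 planted intensity outliers fail the confidence-interval rule. The
interquartile filter is by far the most selective (half of all probes —
with four near-equal probes per CDS, the extreme two always fall strictly
outside the interpolated quartiles), which is why a representative-intensity
criterion dominates rejections on real platforms too. Every CDS ends with
exactly one elected probe: 190 from its qualified set, 10 by supervised
rescue. `out/scorecards.tsv`, `out/probe_stats.tsv` and `out/election.tsv`
carry the per-probe detail; `out/manifest.json` echoes every threshold used.

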