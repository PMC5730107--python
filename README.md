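# sleepsweep

Evolve-and-resequence (E&R) analysis toolkit for artificial selection on
*Drosophila* night sleep, with a fully synthetic data generator carrying
known ground truth.

The package covers the complete analysis chain of a sleep-selection
experiment:

| module | what it does |
| --- | --- |
| `sleepsweep.simulate` | founder panels, the truncation-selection experiment (drift, X hemizygosity, pooled binomial read sampling), DAM-style activity traces, diallel phenotype tables |
| `sleepsweep.sleep` | sleep scoring from per-minute activity counts (5-minute immobility rule, transient pauses, bouts, latency, waking activity, deprivation deltas) |
| `sleepsweep.selection` | CV_E, cumulative selection differentials/responses, realized heritability, long-vs-short divergence |
| `sleepsweep.afc` | minor-allele calling, coverage filtering, Beta-posterior HPD intervals, Cochran–Mantel–Haenszel scans per generation pair, control-overlap filter, grouped-binomial logistic trajectory filter |
| `sleepsweep.drift` | variance-Ne estimation, binomial Wright–Fisher drift simulation, 99.9%-quantile divergence thresholds and per-candidate verdicts |
| `sleepsweep.ld` | r² on phased founder lines, minor-allele-frequency bounds for high LD, LD persistence across pooled generations |
| `sleepsweep.diallel` | Griffing Method 1 Model I GCA/SCA/REC estimation, variance partition, effect tests |
| `sleepsweep.io` / `sleepsweep.cli` / `sleepsweep.pipeline` | sync / long-TSV / DAM / founder-TSV / VCF readers and writers, YAML-configured end-to-end pipeline, `sleepsweep` CLI |

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact in-text
arithmetic, oracle equivalence of the core statistics, stochastic
parameter recovery, planted-signal recovery of the full scan pipeline,
and determinism). The scan-power test runs ~50 simulated experiments and
takes several minutes; everything else is fast.

## CLI

```bash
sleepsweep run --seed 1 --out demo_out          # full synthetic pipeline
sleepsweep simulate --seed 1 --out sim_out      # counts + founders only
sleepsweep score-sleep monitor.tsv --schedule schedule.tsv --out traits.csv
sleepsweep scan counts.sync --out scan.tsv --min-coverage 10 --max-coverage 2000
sleepsweep logit-filter counts.sync --out logit.tsv
sleepsweep drift-threshold --ne 42 --out thresholds.tsv
sleepsweep ld founders.tsv --n-per-chrom 3600 --out pairs.tsv
sleepsweep diallel crosses.csv --out-prefix diallel
```

`sleepsweep run` executes simulate → sleep scoring → selection QG →
CMH scan → logistic filter → drift thresholds/verdicts → LD → diallel and
writes TSV/CSV artifacts plus a deterministic `report.json`. Reruns with
the same config are byte-identical.

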