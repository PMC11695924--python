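# confret

Model-agnostic calibration for protein search: turn raw similarity or
distance scores from any homology / function-annotation model into

* **retrieval sets with risk guarantees** — a threshold calibrated so the
  expected loss of deployed sets is at most a user-chosen level `alpha`:
  conformal risk control (CRC) for monotone losses such as the false
  negative rate or the hierarchical EC/SCOPe mismatch loss, and
  Learn-then-Test (LTT, fixed-sequence testing with a Hoeffding bound) for
  non-monotone losses such as the false discovery rate;
* **calibrated match probabilities** — isotonic regression
  (pool-adjacent-violators) and Venn-Abers probability intervals
  `[p0, p1]`, with expected-calibration-error evaluation;
* **selection and evaluation utilities** — retrieval-set construction,
  Kneedle elbow detection for structural Z-score cutoffs, prefilter
  FNR/TPR/FDR reports, max-separation and empirical p-value baseline
  selectors, and a two-sample loss-CDF exchangeability diagnostic;
* **synthetic generators** — seeded, exchangeable score/label instances
  (flat Pfam-style, hierarchical distograms, joint similarity/Z) so every
  calibration path is testable without external data.

Everything operates on plain TSV score matrices (`query_id  lookup_id
score` triples, or dense tables) and annotation tables (Pfam accession
sets, or dot-notation EC/SCOPe labels with `*` wildcards).

## CLI

```sh
# generate a synthetic instance
confret simulate --preset flat --seed 1 --out demo/

# calibrate an FNR-controlling threshold at alpha = 0.1
confret calibrate --scores demo/scores.tsv --annotations demo/annotations.tsv \
    --loss fnr --alpha 0.1 --method auto --out result.json

# apply the threshold
confret retrieve --scores demo/scores.tsv --threshold 0.83 --out sets.tsv

# Venn-Abers probability intervals for new scores
confret calibrate-prob --scores cal.tsv --test-scores new.tsv --out probs.tsv

# evaluate a prefilter against structural Z ground truth
confret simulate --preset prefilter --seed 1 --out pf/
confret prefilter-eval --scores pf/scores.tsv --threshold 0.7 \
    --z-table pf/z_scores.tsv --z-threshold kneedle --out report.json

# exchangeability diagnostic between two loss samples
confret diagnose-exchangeability --losses-a a.txt --losses-b b.txt --out d.json
```

`--method auto` picks CRC when every per-query loss curve is monotone in
the threshold and LTT otherwise.  Similarity scores use a `>=` inclusion
rule, distances `<=` (strict variants behind `--rule`).

## Layout

| module | contents |
| --- | --- |
| `confret.core_types` | `ScoreMatrix`, `HierarchyLabel`, `AnnotationTable`, `RetrievalSet`, TSV loaders |
| `confret.losses` | cost vectors, match predicates, FDR / FNR / hierarchical set losses |
| `confret.conformal_calibration` | loss curves, `crc_threshold`, `ltt_threshold`, per-level risk certificate |
| `confret.probability_calibration` | PAVA, isotonic prediction, Venn-Abers, ECE |
| `confret.selection_eval` | retrieval sets, Kneedle, prefilter reports, baselines, CDF diagnostic |
| `confret.synthetic_data` | seeded flat / hierarchy / prefilter generators |
| `confret.experiments` | resampled calibration/test trial runners used by the acceptance suite |

All calibration internals work in a single canonical "permissiveness"
orientation (similarity thresholds are negated, distances pass through), so
retrieval sets are nested nondecreasing in the internal threshold
regardless of the score kind.
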