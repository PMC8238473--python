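# cardiowell

A desk-scale decision-support pipeline for cardiac well-being indexes:

1. **Synthetic data** (`cardiowell.synth`) — a seeded 17-attribute risk-factor
   cohort calibrated to published marginal statistics (including gross
   outlier contamination, a 54% missing smoking column, an all-missing
   diabetes marker and a near-50/50 class balance), plus three operational
   sources: slowly-varying user records, daily measurements, and a
   18-district Portugal lookup.
2. **Cleansing** (`cardiowell.cleansing`) — physiological range and
   consistency filters with a full rejection log; idempotent and
   conservative (kept + rejected = input).
3. **Modeling** (`cardiowell.modeling`) — five classifier families (pruned
   tree, random forest, naive Bayes, kNN, MLP) under two feature scenarios,
   10-fold stratified cross-validation with pooled confusion matrices,
   ranking by the composite score `(sensitivity + accuracy) / 2`, and
   persistence of the winning model.
4. **Index engine** (`cardiowell.index_engine`) — the anchored exponential
   transform `f(x) = A + B·exp(Cx)` mapping disease probability to an index
   in [−5, 5] (anchors: 0 → 5, 1 → −5, 0.55 → −2.5), with traffic-light
   colour bands at 2.5 / 0 / −2.5.
5. **Warehouse** (`cardiowell.warehouse`) — a CSV-backed star schema
   (fact + calendar/district/user dimensions) with an SCD-type-4 user
   history table and watermark-based incremental fact loading.
6. **Analytics** (`cardiowell.analytics`) — regression-weighted individual
   trend indexes, unweighted global indexes, sliced breakdowns (gender,
   region, weekday, calendar) and CSV report export.

## CLI

```bash
cardiowell demo --seed 1 --out-dir /tmp/demo        # end-to-end example

cardiowell generate --kind cohort --n 65000 --seed 42 --out-dir data/
cardiowell cleanse --in data/cohort.csv --out data/clean.csv --log data/rejects.csv
cardiowell dm-job --cohort data/cohort.csv --out-dir model/ --folds 10 --seed 0
cardiowell etl init --warehouse wh/
cardiowell etl run --warehouse wh/ --users data/source1_users.csv \
    --measurements data/source2_measurements.csv --model-dir model/
cardiowell etl status --warehouse wh/
cardiowell index --probability 0.3
cardiowell report user --warehouse wh/ --id 1
cardiowell report global --warehouse wh/ --by weekday
```

The intended operational cadence is `dm-job` monthly and `etl run` daily,
driven by any external scheduler; both commands are idempotent re-runs.

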