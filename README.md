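# ocquery

Analysis of search-engine query logs around missed oral-contraceptive (OC)
doses. Millions of women take a daily OC, and a forgotten pill is a common,
anxiety-laden event; anonymous search queries ("forgot my birth control
pill", "plan b price near me", "week 8 of pregnancy symptoms") capture both
the information gap and its outcomes at population scale. `ocquery` is for
infodemiology / digital-epidemiology researchers who have (or simulate) a
per-user query log and want reproducible estimates of what follows a
missed-dose query.

The pipeline:

1. **Classify** each query into one of five classes with auditable keyword
   rules (missed OC dose; miscarriage; abortion; emergency contraception;
   week of pregnancy), extracting pill type, missed-dose count, placebo and
   gestational-week mentions.
2. **Link** per-user timelines anchored at the first missed-OC query and
   measure follow-up incidence and gap times.
3. **Date** pregnancies: each week-of-pregnancy query implies a last
   menstrual period LMP = query date − 7·week; recurrent queries give a
   consensus LMP, a dating-consistency statistic, whether the pregnancy is
   timed to the missed-pill cycle, and the conception day within it.
4. **Weight for right-censoring**: a user who misses a pill in December
   cannot be observed querying about late pregnancy inside a one-year
   window. From the empirical week distribution p(k), each user gets an
   observability weight w(t) = Σₖ p(k)·1[t + 7k ≤ window end], and the
   censoring-corrected pregnancy rate is
   (observed pregnancy reporters) / Σ w — weights shrink the denominator
   only.
5. **Stratify and test**: rates by pill type, placebo mention and ≥2 missed
   doses; age-band likelihood ratios with chi-square tests; age/dose-count
   Spearman correlation; Cohen's kappa for label audits.

Real logs of this kind are proprietary, so the package includes a synthetic
cohort generator (`ocquery.synthetic_cohort`) whose defaults encode the
reference cohort's published statistics and which emits a ground-truth
sidecar; every estimator is validated by recovering the generator's
parameters from the generated log. See `docs/methods.md` for the model and
its assumptions.

## Worked example

```bash
ocquery simulate --seed 42 --out-log scratch/log.tsv --out-truth scratch/truth.tsv
ocquery analyze --log scratch/log.tsv --out results/report
ocquery recover --report results/report/report.json --truth scratch/truth.tsv
```

or, through the numbered analysis drivers:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_classify_and_link.py
python analysis/03_pregnancy_dating.py
python analysis/04_weighted_rates.py
python analysis/05_age_patterns.py
```

On the reference scenario (50,000 missed-OC users, calendar year 2018,
seed 42) the drivers print, among other things:

```
emergency contraception: median gap 10.5 days, 38.1% within 24 h
1686 pregnancy reporters; 20.2% timed to the missed-pill cycle; LMP estimates
from recurrent queries agree to a median of 4 days; mean conception day 14.5
weighted rate 4.25% vs raw 3.37%
age vs missed-dose count: Spearman rho=0.084 (p=9.7e-22, n=13063)
```

Reading these numbers: only ~38% of emergency-contraception seekers query
within the 24 hours when it is most effective; about 4.7% of non-placebo
users are estimated to report a pregnancy once censoring is corrected
(8.9% in the minipill stratum, 0.2% in the placebo stratum, 5.6% with ≥2
missed doses — see `results/pregnancy_rates.tsv`); the raw rate of 3.4%
illustrates the censoring bias the weights remove; and users aged 30–34 are
about 5× likelier than others to follow up with a miscarriage query
(`results/age_band_comparisons.tsv`).

As a library:

```python
from ocquery import ScenarioConfig, generate_cohort, analyze

config = ScenarioConfig(n_users=50_000, seed=42)
log, truth = generate_cohort(config)
report = analyze(log, window_end=config.window_end)
print(report["rates"]["non_placebo"]["weighted_rate"])  # ~0.047
```

## Layout

```
src/ocquery/        library: lexicon, query_model, synthetic_cohort,
                    linkage, gestation, censoring, cohort_stats, io,
                    pipeline, cli
analysis/           numbered narrative drivers writing results/
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     model, assumptions, calibrations, limitations
```
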