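# forumrx

Treatment-pattern mining from patient-forum text, with matched EMR/claims
cohort comparison.

Observational oncology research often asks a deceptively simple question:
*what treatments do patients actually receive at first, second, and third
line?* The traditional answers come from electronic medical record (EMR) or
insurance-claims databases, which are slow and expensive to access. Public
patient forums are an alternative real-world data source — if free-text posts
("started ipi 3 months ago!!") can be turned into per-patient lines of
therapy and shown to agree with the databases. `forumrx` implements that
entire workflow for advanced/metastatic melanoma (first-line initiation
2011–2017), together with a synthetic-cohort generator that stands in for
scraped forums and proprietary databases and provides labeled ground truth
for every stage.

## What the package does

1. **Ingest** — clean forum posts (URL and special-character removal),
   sentence-tokenize, derive a stable user id from (username, forum), and
   keep only users with at least one treatment mention.
2. **Lexicon** — normalize drug mentions against a melanoma systemic-therapy
   vocabulary (generic names, brands like Yervoy/Opdivo/Keytruda,
   abbreviations like ipi/nivo/pembro), with bounded fuzzy matching
   (Levenshtein distance ≤ 1, tokens ≥ 6 characters) for typos such as
   "temozolamide".
3. **Classify** — decide whether a mention-bearing sentence reports actual
   treatment receipt, comparing TF-IDF + linear SVM, multinomial naive Bayes,
   and KNN (K = 5), selecting the best by precision + recall.
4. **Context** — drop negated mentions ("I did not take temozolomide",
   NegEx-style 5-token window with scope terminators) and resolve each
   sentence to a calendar date ("three months ago" → post date − 3 months;
   "in March 2014" → 2014-03-15; otherwise the post date).
5. **Lines of therapy** — order events per patient, collapse duplicates at
   (drug, month) granularity, and derive numbered lines: a new non-regimen
   drug after the 28-day combination window opens the next line; interferon
   or docetaxel monotherapy is adjuvant and never counts as a line.
6. **Compare** — frequency-match comparator cohorts 4:1 on first-line
   initiation year, estimate per-line regimen proportions with Wald 95%
   intervals

   p̂ ± 1.96·√(p̂(1−p̂)/n),

   and flag concordance when the reported (rounded) closed intervals of two
   sources intersect.

The synthetic-cohort module generates patient journeys (1–3 lines drawn from
year-specific regimen mixes), renders them as noisy forum posts (typos, brand
names, negated decoy mentions, off-topic chatter, relative dates), writes
sentence-level receipt labels, and draws EMR/claims-style comparator tables
from the same distributions — so the whole pipeline can be validated against
known truth.

## Worked example

```python
from forumrx import PipelineConfig, run_end_to_end
from forumrx.synthetic import SimulationConfig, NoiseConfig

config = PipelineConfig(
    seed=7, classifier="svm_linear",
    sim=SimulationConfig(n_patients=1000, noise=NoiseConfig.uniform(0.1), seed=7),
)
result = run_end_to_end(config)
print(result["line_counts"])
print(result["concordance"]["per_line"])
```

prints

```
   line_number  n_patients  pct_of_first_line
0            1        1000              100.0
1            2         261               26.1
2            3          67                6.7
{1: {'n_regimens': 6, 'n_any_overlap': 6, 'fraction_any_overlap': 1.0},
 2: {'n_regimens': 6, 'n_any_overlap': 6, 'fraction_any_overlap': 1.0},
 3: {'n_regimens': 6, 'n_any_overlap': 6, 'fraction_any_overlap': 1.0}}
```

Of 1,000 simulated patients, 26.1% reached a second and 6.7% a third line
(the generator's defaults are P(2nd) = 0.277 and P(3rd | 2nd) = 0.323, so
these are within sampling error). Every one of the six most common
social-media regimens per line has a 95% CI that overlaps at least one
matched comparator database — full per-regimen estimates, numerators,
denominators, and overlap flags are in `result["comparison_rows"]`.

The same pipeline is available as shell stages:

```bash
forumrx run-all --outdir out --seed 7
# or stage by stage: forumrx simulate / preprocess / classify / extract /
#                    lines / match / compare
```

Each stage writes its tables (CSV/JSONL/JSON) plus a manifest with input
checksums, the configuration, and the seed, so every output is reproducible.

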