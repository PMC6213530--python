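# starchsugar

Construction of a starch/sugar food-composition database by stepwise value
assignment, free- vs. naturally-occurring-sugar classification under the WHO
definition, and estimation of population intakes from multi-day weighed
dietary records — including energy adjustment, EI/EER screening, WHO
free-sugar adherence, habitual-intake distribution correction (best-power
method) and food-group contribution analysis.  All stages are driven by a
synthetic-data generator with known ground truth, so the entire pipeline is
testable offline.

## Modules

| module | purpose |
| --- | --- |
| `starchsugar.composition_model` | domain types (items, saccharide profiles, food groups) and nutrient arithmetic (carbohydrate by difference, total sugar, dry weight) |
| `starchsugar.value_assignment` | the stepwise cascade filling saccharide and starch values (analytical → zero-carb → literature → same-food → similar-food → recipe → overseas → fallback) with per-item provenance |
| `starchsugar.free_sugar_classifier` | ordered rule tree splitting total sugar into free vs. naturally occurring sugar; rules ship as YAML data |
| `starchsugar.intake_pipeline` | per-person daily intakes, % of energy, EI/EER, WHO adherence, sex comparisons (t-test / chi-square), food-group contributions |
| `starchsugar.habitual_distribution` | best-power habitual intake: grid-selected power transform, one-way random-effects ANOVA, shrinkage, bias-corrected back-transform |
| `starchsugar.synthetic_data` | generators for composition tables (masked but exactly resolvable) and multi-day dietary records with known variance components |
| `starchsugar.cli_io` | CSV/YAML/JSON readers and writers, validated pipeline configuration, and the `starchsugar` CLI |

## CLI

```bash
# generate synthetic fixtures (composition table, aux sources, records)
starchsugar simulate --outdir fixtures/ --seed 42

# run the value-assignment cascade
starchsugar build-db --composition fixtures/composition.csv \
    --literature fixtures/literature.csv --links fixtures/links.csv \
    --recipes fixtures/recipes.csv --overseas fixtures/overseas.csv \
    --out db.csv --report provenance.json

# classify free vs. naturally occurring sugar
starchsugar classify-free-sugar --db db.csv --recipes fixtures/recipes.csv \
    --out db_free.csv

# apply the database to dietary records
starchsugar estimate-intake --db db_free.csv --records fixtures/records.csv \
    --persons fixtures/persons.csv --out intakes.csv --summary summary.json

# habitual (usual) intake distributions from person-day intakes
starchsugar habitual --intakes intakes.person_days.csv --out habitual.csv \
    --diagnostics diag.json

# food-group contribution table
starchsugar contributions --db db_free.csv --records fixtures/records.csv \
    --nutrient free_sugar --out contrib.csv

# everything end to end (synthetic by default), one JSON report
starchsugar run-all --seed 42 --out report.json
```

## File formats

All inputs and outputs are UTF-8 RFC 4180 CSV (empty cell = missing value,
0 is always a measured/assigned value), YAML for configuration and rules,
JSON for reports.  Column schemas are documented in
`starchsugar/cli_io/io.py`.
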