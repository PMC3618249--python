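# rulescale

Qualitative, rule-based multi-scale simulation of drug action. Components
(organs, cells, drugs, ...) carry discretely valued attributes (genes,
metabolites, hormones, channels, drug presence); rules detect state
*transitions* on source attributes and perturb target attributes. An
asynchronous engine fires one randomly chosen executable rule per step, and a
per-component **rule execution threshold** separates response timescales:
molecule/cell-scale components change state on a single firing (threshold
1.0), organ-scale components only after 60 accumulated firing-score hits
(threshold 60.0). Monte Carlo ensembles of runs yield drug-effect pathway
graphs, single-drug efficacy verdicts, and combination-drug screens; rule
converters extract rules from ODE systems (sign/monotonicity analysis) and
Petri nets (one rule per transition).

The package ships a mini type-2-diabetes model (`rulescale/data/`): a
class-level reconstruction of 22 antidiabetic drugs acting on beta-cell,
hepatocyte, adipocyte, muscle, gut and the circulation system, with a
persistent insulin-resistance disease process competing against drug-induced
rules.

## Layout

| module | contents |
| --- | --- |
| `rulescale.core_model` | state domains, attribute refs, rules, condition/action semantics, model validation |
| `rulescale.model_io` | component/rule/disease/drug file readers and writers, trace TSV |
| `rulescale.engine` | asynchronous threshold-gated simulation core |
| `rulescale.pathway` | ensembles, pathway graphs (SIF/DOT), efficacy, combination screening |
| `rulescale.converters` | ODE monotonicity analysis and Petri-net conversion to rules |
| `rulescale.fixtures` | packaged T2D model, random model generator, brute-force scheduling oracle |
| `rulescale.cli` | `rulescale` command-line entry point |

## CLI

All inputs are plain text: a YAML component file, a one-rule-per-line DSL
file (`Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,AGRP,up`,
with `&` conjunctions and `@rs/@disease/@persistent/@src/@id` annotations),
and YAML disease/drug files.

```sh
# copy the packaged model somewhere editable
python -c "from importlib.resources import files; import shutil; \
  [shutil.copy(files('rulescale')/'data'/n, '.') for n in \
   ('t2d_components.yaml','t2d_rules.txt','t2d_disease.yaml')]"
echo "drugs: [metformin]" > drugs.yaml

rulescale validate --model t2d_components.yaml --rules t2d_rules.txt
rulescale simulate --model t2d_components.yaml --rules t2d_rules.txt \
    --disease t2d_disease.yaml --drugs drugs.yaml --seed 1 --out trace.tsv
rulescale ensemble --model t2d_components.yaml --rules t2d_rules.txt \
    --disease t2d_disease.yaml --drugs drugs.yaml --seed 1 --n-runs 100 \
    --criterion organ,circulation,metabolite,glucose \
    --pathway-out metformin.sif
rulescale screen --model t2d_components.yaml --rules t2d_rules.txt \
    --disease t2d_disease.yaml --drug-list metformin,acarbose,glyburide \
    --anchor metformin --criterion organ,circulation,metabolite,glucose \
    --out screen.tsv
rulescale convert-ode --system system.yaml --out rules.txt --report report.tsv
rulescale convert-petri --net net.yaml --out rules.txt
rulescale generate --seed 4 --out-dir generated/
```

Outputs are fully reproducible: the same inputs and `--seed` give
byte-identical traces, graphs and screening tables, and every output file
starts with a `# key=value` header of the resolved configuration.

## Semantics notes

- Conditions are evaluated over a `(previous, current)` state pair; a state
  held at an extreme keeps satisfying the matching movement condition
  (`high -> high` satisfies `up`), as per the literal piecewise definitions.
- Threshold crossing uses `>=` so a unit effect score fires a unit-threshold
  component in one hit; `--strict-threshold` restores a literal `>`.
- Firing scores accumulate per component and reset to zero on crossing;
  `--rfs-per-attribute` switches to per-attribute accumulation.
- Rules flagged `@persistent` are re-enqueued every step while their
  condition holds (chronic disease processes, sustained drug action); all
  other rules leave the active set once fired.
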