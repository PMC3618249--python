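# Component universe of the packaged mini type-2-diabetes model.
# Molecule/cell/drug-scale components respond in a single rule firing
# (threshold 1.0); the organ-scale circulation system needs 60 accumulated
# firings (threshold 60.0), encoding the slower organ response timescale.
domains:
  gene:
    states: [low, normal, high]
    conditions: [up, down]
    actions: [up, down]
    default: normal
  metabolite:
    states: [low, normal, high]
    conditions: [up, down]
    actions: [up, down]
    default: normal
  hormone:
    states: [low, normal, high]
    conditions: [up, down]
    actions: [up, down]
    default: normal
  channel:
    states: [close, open]
    conditions: [close, open]
    actions: [close, open]
    default: open
  flag:
    states: [absent, present]
    conditions: [absent, present]
    actions: [absent, present]
    default: absent
  presence:
    states: [absent, present]
    conditions: [absent, present]
    actions: [absent, present]
    default: absent

components:
  - type: organ
    name: circulation
    threshold: 60.0
    attributes:
      - metabolite,glucose
      - hormone,insulin
  - type: cell
    name: beta-cell
    threshold: 1.0
    attributes:
      - channel,KATP
  - type: cell
    name: hepatocyte
    threshold: 1.0
    attributes:
      - gene,PRKAB1
      - gene,AGRP
      - gene,PEPCK
      - gene,G6PC
      - gene,GLUT4
  - type: cell
    name: adipocyte
    threshold: 1.0
    attributes:
      - gene,PPARG
      - gene,GLUT4
  - type: cell
    name: muscle
    threshold: 1.0
    attributes:
      - gene,GLUT4
      - flag,insulin_resistance
  - type: cell
    name: gut
    threshold: 1.0
    attributes:
      - gene,alpha_glucosidase

  # --- drug catalogue (one presence attribute each) ---
  - {type: drug, name: metformin, attributes: ["presence,status"]}
  - {type: drug, name: rosiglitazone, attributes: ["presence,status"]}
  - {type: drug, name: pioglitazone, attributes: ["presence,status"]}
  - {type: drug, name: troglitazone, attributes: ["presence,status"]}
  - {type: drug, name: saxagliptin, attributes: ["presence,status"]}
  - {type: drug, name: sitagliptin, attributes: ["presence,status"]}
  - {type: drug, name: vildagliptin, attributes: ["presence,status"]}
  - {type: drug, name: exenatide, attributes: ["presence,status"]}
  - {type: drug, name: liraglutide, attributes: ["presence,status"]}
  - {type: drug, name: mitiglinide, attributes: ["presence,status"]}
  - {type: drug, name: nateglinide, attributes: ["presence,status"]}
  - {type: drug, name: repaglinide, attributes: ["presence,status"]}
  - {type: drug, name: chlorpropamide, attributes: ["presence,status"]}
  - {type: drug, name: glipizide, attributes: ["presence,status"]}
  - {type: drug, name: gliquidone, attributes: ["presence,status"]}
  - {type: drug, name: tolbutamide, attributes: ["presence,status"]}
  - {type: drug, name: glimepiride, attributes: ["presence,status"]}
  - {type: drug, name: glyburide, attributes: ["presence,status"]}
  - {type: drug, name: miglitol, attributes: ["presence,status"]}
  - {type: drug, name: voglibose, attributes: ["presence,status"]}
  - {type: drug, name: acarbose, attributes: ["presence,status"]}
  - {type: drug, name: pramlintide, attributes: ["presence,status"]}
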