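# Patient model: chronic insulin resistance with elevated blood glucose.
# All other attributes start at their domain defaults (normal).
name: t2d
states:
  - {attr: "cell,muscle,flag,insulin_resistance", state: present}
  - {attr: "organ,circulation,metabolite,glucose", state: high}
rules: [T2D1]
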