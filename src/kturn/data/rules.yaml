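# Sequence rules for ion-induced k-turn folding and N-class prediction.
# The tables carry only experimentally established rows and are
# deliberately partial: pairs absent from a table are "undetermined"
# (folding) or "unknown" (N-class).  Users may extend them via a config
# file passed to RuleConfig.from_yaml / the CLI --rules flag.
version: 1
three_b_three_n:
  # 3b = C or 3n = G confers ion-induced folding (magnesium-ion contact
  # to the guanine O6 in the major groove); Watson-Crick pairs prevent it.
  confers_if_b: [C]
  confers_if_n: [G]
  watson_crick_prevents: true
  # When both clauses apply (e.g. C:G) the conferring clause wins.
  precedence: confers_over_prevents
minus1b_minus1n:
  C:G: confers
  G:C: prevents
  C:A: prevents
n_class:
  # 3b:3n sequence -> predicted core conformation
  A:U: N3
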