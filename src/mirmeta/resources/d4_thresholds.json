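{
 "D4": {
  "miranda": {"t_true_1": -0.179, "t_false_1": 0.844, "t_true_2": 0.067, "t_false_2": 0.199},
  "mirdb": {"t_true_1": -0.702, "t_false_1": 0.059, "t_true_2": -0.480, "t_false_2": -0.269},
  "pita": {"t_true_1": -0.449, "t_false_1": 0.257, "t_true_2": -0.203, "t_false_2": -0.107},
  "targetscan": {"t_true_1": 0.896, "t_false_1": 0.982, "t_true_2": 0.964, "t_false_2": 0.972}
 }
}
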