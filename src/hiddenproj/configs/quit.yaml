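# Application 1: six-component web-based smoking-cessation intervention.
# Baseline: the 16-run regular 2^(6-2) fraction actually fielded (E=ABC, F=ACD).
# Proposal: the 12-run strength-2 orthogonal array from the Paley q=11
# Hadamard matrix (first 6 columns).
name: quit
baseline:
  kind: regular
  k: 4
  generators: "E=ABC,F=ACD"
proposal:
  kind: paley1
  q: 11
  cols: 6
k_values: [3, 4]
expectations:
  baseline_runs: 16
  proposal_runs: 12
  run_reduction_pct: 25
  baseline_strength: 3
  proposal_strength: 2
  baseline_coverage: {3: 100, 4: 80}
  proposal_coverage: {3: 100, 4: 100}
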