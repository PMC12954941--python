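# Application 2: six-drug antiviral combination screen.
# Baseline: the resolution-VI 2^(6-1) half fraction (F=ABCDE), 32 runs.
# Proposal: the 28-run strength-2 orthogonal array from the Paley type-II
# q=13 Hadamard matrix — four fewer runs than the half fraction.
name: hsv1
baseline:
  kind: regular
  k: 5
  generators: "F=ABCDE"
proposal:
  kind: paley2
  q: 13
  cols: 6
k_values: [3, 4]
expectations:
  baseline_runs: 32
  proposal_runs: 28
  runs_saved: 4
  baseline_strength: 5
  proposal_strength: 2
  baseline_coverage: {3: 100, 4: 100}
  proposal_coverage: {3: 100, 4: 100}
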