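# Application 3: sixteen non-pharmaceutical influenza interventions.
# Baseline: a 2^(16-7) regular fraction, 512 runs.  The seven generator
# words of the original study are unpublished; the words below are a
# documented reconstruction (seven distinct 3-letter words over the nine
# base factors, which forces every defining word to even length >= 4, and
# the pair J=ABC, K=ABD yields the length-4 word CDJK, so resolution is
# exactly IV).  The self-check pins only run counts and the rounded
# reduction, never the specific words.
# Proposal: the 420-run Paley design from q=419, using 16 factor columns.
name: npi
baseline:
  kind: regular
  k: 9
  generators: "J=ABC,K=ABD,L=ACE,M=ADF,N=AEG,O=AFH,P=AGI"
proposal:
  kind: paley1
  q: 419
  cols: 16
k_values: [3]
expectations:
  baseline_runs: 512
  proposal_runs: 420
  run_reduction_pct: 18
  baseline_strength: 3
  proposal_strength: 2
  baseline_coverage: {3: 100}
  proposal_coverage: {3: 100}
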