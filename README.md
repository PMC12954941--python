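# hiddenproj

Construction and analysis of two-level screening designs: regular
fractional factorials defined by generator words, and non-regular designs
derived from Hadamard matrices (Sylvester, Paley type I and type II).
The analysis side verifies orthogonal-array strength by exhaustive
counting, computes alias structure and resolution for regular fractions,
and quantifies *hidden-projection* estimability — the fraction of k-factor
subsets whose intercept + main-effects + two-factor-interaction model
matrix has full column rank (rank is computed exactly over the integers,
cross-checked against a floating SVD).

## Library quick tour

```python
import hiddenproj as hp

# 12-run, 6-factor strength-2 orthogonal array from the Paley q=11 matrix
oa12 = hp.hadamard_to_oa(hp.paley_type1(11), 6)
hp.verify_strength(oa12, 2).holds          # True
hp.projection_coverage(oa12, 4).coverage_pct   # 100.0

# 16-run regular 2^(6-2) fraction with generators E=ABC, F=ACD
gen = hp.GeneratorSet.from_strings(4, "E=ABC,F=ACD")
reg = hp.build_regular(gen)
hp.resolution(hp.defining_contrast_subgroup(gen))   # 4
rep = hp.projection_coverage(reg, 4)
rep.coverage_pct           # 80.0
rep.deficient_subsets      # (A,B,C,E), (A,C,D,F), (B,D,E,F)
```

## CLI

```sh
hiddenproj construct paley1 --q 11 --cols 6 -o oa12.csv
hiddenproj construct paley2 --q 13 --cols 6 -o oa28.csv
hiddenproj construct regular --k 4 --generators "E=ABC,F=ACD" -o reg16.csv
hiddenproj strength oa12.csv --t 2
hiddenproj project reg16.csv --k 4 --list-deficient
hiddenproj compare reg16.csv oa12.csv --k 3,4 --baseline reg16.csv
hiddenproj case-study quit     # bundled: quit, hsv1, npi (or a YAML path)
```

Exit codes: 0 success, 1 expectation/strength mismatch, 2 usage or config
error.  Designs are read and written as labelled CSV (`-1`/`+1` body) or
`oa_text` (one run per line of contiguous 0/1 digits, `0 -> -1`,
`1 -> +1`; a leading `N n t` header line is tolerated on read).

Three case-study configs ship with the package
(`src/hiddenproj/configs/*.yaml`): each builds a baseline regular fraction
and a proposed orthogonal-array design, compares run counts, strength and
projection coverage, and self-checks its declared expectations.

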