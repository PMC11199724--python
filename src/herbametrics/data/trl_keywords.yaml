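# Anchor keyword sets per Technology Readiness Level category for
# herbal-medicine R&D.  TRL1 = basic research identifying extracts;
# TRL2 = isolation / fractionation / chemical characterization;
# TRL3 = in vitro and in silico testing; TRL4-5 = in vivo animal testing,
# formulation work and patenting readiness (grouped: patent activity is
# rarely visible in publications); TRL6-9 = clinical trials of any phase,
# including population-response studies of traditional use (grouped: the
# phases are not separable from abstracts).
#
# Terms are uni/bi-grams, matched on their content tokens after stopword
# removal ("in vitro" matches the token "vitro").  Replaceable via
# `--keywords my_sets.yaml`.
TRL1:
  - extract identification
  - basic research
  - ethnobotany
  - ethnopharmacology
  - bioprospecting
  - screening
TRL2:
  - isolation
  - fractionation
  - chemical characterization
  - purification
  - structure elucidation
  - compound
TRL3:
  - in vitro
  - in silico
  - assay
  - cytotoxicity
  - molecular docking
TRL4-5:
  - in vivo
  - animal
  - rats
  - mice
  - formulation
  - patent
TRL6-9:
  - clinical trial
  - phase
  - tolerability
  - pharmacokinetics
  - efficacy
  - safety
  - patients
  - volunteers
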