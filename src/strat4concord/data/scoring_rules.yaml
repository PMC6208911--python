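# Reference-method scoring configurations: ER/PR percent-staining cutoffs,
# HER2 policies (FISH reflex of IHC 2+, IHC alone with 2+ excluded, FISH
# alone), and Ki67 proliferation-rate cutoffs.
rules:
  - {rule_id: er_1pct, marker: ER, kind: hr_cutoff, params: {cutoff: 1}}
  - {rule_id: er_10pct, marker: ER, kind: hr_cutoff, params: {cutoff: 10}}
  - {rule_id: pr_1pct, marker: PR, kind: hr_cutoff, params: {cutoff: 1}}
  - {rule_id: pr_10pct, marker: PR, kind: hr_cutoff, params: {cutoff: 10}}
  - {rule_id: her2_ihc_plus_fish, marker: HER2, kind: her2, params: {policy: ihc_plus_fish}}
  - {rule_id: her2_ihc_excluding_2plus, marker: HER2, kind: her2, params: {policy: ihc_only}}
  - {rule_id: her2_fish_only, marker: HER2, kind: her2, params: {policy: fish_only}}
  - {rule_id: ki67_20pct, marker: Ki67, kind: ki67, params: {cutoff: 20}}
  - {rule_id: ki67_10pct, marker: Ki67, kind: ki67, params: {cutoff: 10}}
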