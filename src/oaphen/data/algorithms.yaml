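# Default case-identification algorithms: eight primary definitions plus the
# imaging-restricted secondary variants (same rules, additionally requiring a
# documented knee x-ray/MRI code or coded report within 730 days of a
# qualifying diagnostic code).
#
# Rule kinds: {kind: exactly, k: 1} means exactly k codes of the category in
# the whole record; {kind: at_least, k: n} means n codes satisfying the
# separation/window constraints. When both oa_rule and pain_rule are present
# the definition asks for a cross-category pair of codes within the window.
- name: one_oa_code
  oa_rule: {kind: exactly, k: 1}
- name: one_pain_code
  pain_rule: {kind: exactly, k: 1}
- name: oa_ge2_6mo
  oa_rule: {kind: at_least, k: 2}
  window_days: 183
- name: pain_ge2_6mo
  pain_rule: {kind: at_least, k: 2}
  window_days: 183
- name: oa_and_pain_6mo
  oa_rule: {kind: at_least, k: 1}
  pain_rule: {kind: at_least, k: 1}
  window_days: 183
- name: oa_ge2_12mo
  oa_rule: {kind: at_least, k: 2}
  window_days: 365
- name: pain_ge2_12mo
  pain_rule: {kind: at_least, k: 2}
  window_days: 365
- name: oa_and_pain_12mo
  oa_rule: {kind: at_least, k: 1}
  pain_rule: {kind: at_least, k: 1}
  window_days: 365

- name: one_oa_code_img
  oa_rule: {kind: exactly, k: 1}
  require_imaging_within_days: 730
- name: one_pain_code_img
  pain_rule: {kind: exactly, k: 1}
  require_imaging_within_days: 730
- name: oa_ge2_6mo_img
  oa_rule: {kind: at_least, k: 2}
  window_days: 183
  require_imaging_within_days: 730
- name: pain_ge2_6mo_img
  pain_rule: {kind: at_least, k: 2}
  window_days: 183
  require_imaging_within_days: 730
- name: oa_and_pain_6mo_img
  oa_rule: {kind: at_least, k: 1}
  pain_rule: {kind: at_least, k: 1}
  window_days: 183
  require_imaging_within_days: 730
- name: oa_ge2_12mo_img
  oa_rule: {kind: at_least, k: 2}
  window_days: 365
  require_imaging_within_days: 730
- name: pain_ge2_12mo_img
  pain_rule: {kind: at_least, k: 2}
  window_days: 365
  require_imaging_within_days: 730
- name: oa_and_pain_12mo_img
  oa_rule: {kind: at_least, k: 1}
  pain_rule: {kind: at_least, k: 1}
  window_days: 365
  require_imaging_within_days: 730
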