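# Default clinical code sets.
#
# knee_pain holds the documented Read codes for knee pain. All other lists
# are NON-AUTHORITATIVE placeholders (the original code lists were not
# published); override any category with your own YAML via --codesets.
knee_pain:
  - "1M10.00"   # knee pain
  - "1M12.00"   # anterior knee pain
  - "N094W00"   # anterior knee pain
  - "N094611"   # knee joint pain
  - "N094M00"   # arthralgia of knee
knee_oa:
  - "N05z600"   # osteoarthritis NOS, knee (placeholder list)
  - "N051911"
  - "N052z00"
imaging:
  - "5352.00"   # knee x-ray (placeholder)
  - "5690.00"   # knee MRI (placeholder)
exclusion_ra:
  - "N040.00"
exclusion_gout:
  - "C340.00"
exclusion_pseudogout:
  - "N023.00"
exclusion_psa:
  - "N045.00"
tkr:
  - "7K30.00"
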