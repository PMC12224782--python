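name: smk
template: "smoking: [MASK]"
classes: ["current", "past", "no", "unknown"]
label_words:
  "current": "yes"
  "past": "past"
  "no": "no"
  "unknown": "unknown"
keywords: ["smoking", "smoke", "cigar", "cigarette"]
label_remap:
  "smoker": "current"
  "current smoker": "current"
  "past smoker": "past"
  "non-smoker": "no"
positive_class: "current"
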