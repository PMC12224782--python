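name: dep
template: "depression: [MASK]"
classes: ["Yes", "Unmentioned"]
label_words:
  "Yes": "yes"
  "Unmentioned": "no"
keywords: ["depressive", "depression", "mood"]
positive_class: "Yes"
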