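name: oa
template: "osteoarthritis (OA): [MASK]"
classes: ["Yes", "Unmentioned"]
label_words:
  "Yes": "yes"
  "Unmentioned": "no"
keywords: ["bone", "osteo", "arthritis", "osteoarthritis", "joint", "cartilage", "oa"]
positive_class: "Yes"
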