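name: pvd
template: "peripheral vascular disease (PVD): [MASK]"
classes: ["Yes", "Unmentioned"]
label_words:
  "Yes": "yes"
  "Unmentioned": "no"
keywords: ["vascular", "peripheral vascular", "arterial"]
positive_class: "Yes"
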