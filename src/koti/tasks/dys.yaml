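name: dys
template: "dysmenorrhea: [MASK]"
classes: ["Yes", "No", "Unknown"]
label_words:
  "Yes": "yes"
  "No": "no"
  "Unknown": "unknown"
keywords: ["dysmenorrhea", "cramps", "menstrual pain", "period pain"]
positive_class: "Yes"
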