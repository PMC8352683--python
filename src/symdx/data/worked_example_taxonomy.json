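{
 "code_base": 10,
 "symptoms": ["male", "fever", "ulcer", "pain", "aching and limp", "nasal congestion", "diarrhea", "bleeding", "tumor", "drowsiness", "face yellowing"],
 "categories": [
  {"b": 1, "name": "tumor disease", "subclasses": [
   {"j": 1, "name": "benign tumor", "diseases": [
    {"t": 1, "name": "squamous cell carcinoma"},
    {"t": 2, "name": "adenocarcinoma"},
    {"t": 3, "name": "basal cell carcinoma"},
    {"t": 4, "name": "transitional cell carcinoma"},
    {"t": 5, "name": "sarcoma"}
   ]},
   {"j": 2, "name": "borderline tumor", "diseases": []},
   {"j": 3, "name": "malignant tumor", "diseases": []}
  ]},
  {"b": 2, "name": "infectious disease", "subclasses": []},
  {"b": 3, "name": "blood disease", "subclasses": []},
  {"b": 4, "name": "cardiovascular disease", "subclasses": []},
  {"b": 5, "name": "digestive disease", "subclasses": []},
  {"b": 6, "name": "endocrine system disease", "subclasses": []},
  {"b": 7, "name": "respiratory disease", "subclasses": []},
  {"b": 8, "name": "urinary system disease", "subclasses": []},
  {"b": 9, "name": "ophthalmic disease", "subclasses": []},
  {"b": 10, "name": "otolaryngology disease", "subclasses": []}
 ]
}
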