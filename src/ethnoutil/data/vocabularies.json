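{
  "ailment": {
    "BITE": "insect or snake bite",
    "BLOOD": "hematological issues including coagulation",
    "BONE": "bone related injury or disease",
    "BURN": "burns",
    "CANC": "cancer",
    "CHILD": "childhood disease",
    "CV": "cardiovascular",
    "DENT": "dental disease",
    "FEV": "fever",
    "GAST": "gasteroenterological disease",
    "HEAD": "headache",
    "INF": "infection",
    "INSECTICIDE": "delousing",
    "MAGIC": "disease of unidentified etiology ('magical poisoning')",
    "MAINT": "health promotion, including failure to thrive",
    "MAL": "malaria",
    "NUT": "nutritional supplement",
    "OCC": "ocular diseases",
    "ORG": "diseases thought to affect one particular organ",
    "OTHER": "unclear disease syndrome",
    "PAIN": "physical pain",
    "POIS": "envenomation or poisoning; sometimes this includes transnatural causation",
    "PSYCH": "psychiatric diseases or syndromes",
    "REP": "reproductive diseases including childbirth related issues",
    "RESP": "respiratory diseases",
    "SKIN": "dermal related diseases; often includes infectious disease",
    "SWELL": "swelling of whole body or part of the body",
    "URINE": "urinary conditions",
    "WOUND": "wound related diseases or syndromes"
  },
  "part": {
    "R": "rhizome",
    "L": "leaf",
    "yL": "young leaf",
    "B": "bark",
    "yShoot": "young shoot",
    "yRoot": "young root",
    "Root": "root",
    "Stem": "stem",
    "Seed": "seed",
    "Fruit": "fruit",
    "Flower": "flower",
    "Nut": "nut",
    "Shoot": "shoot",
    "Whole": "whole plant",
    "Sap": "sap",
    "Succus": "expressed juice"
  },
  "preparation": {
    "B": "burned (smoke generation)",
    "C": "cooked",
    "D": "decoction",
    "H": "heated",
    "HR": "heated then rubbed",
    "M": "masticated",
    "MAG": "magical",
    "MS": "masticated then spit on affected area(s)",
    "R": "raw",
    "S": "succus (crushed)",
    "V": "vapor"
  },
  "route": {
    "O": "oral",
    "T": "topical",
    "I": "inhalation",
    "P_to_Plant": "patient to plant transfer of blood"
  }
}
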