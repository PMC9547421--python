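[
 {
  "name": "ABRE",
  "category": "hormone",
  "pattern": "ACGTG"
 },
 {
  "name": "TGA-element",
  "category": "hormone",
  "pattern": "AACGAC"
 },
 {
  "name": "DRE",
  "category": "stress",
  "pattern": "RCCGAC"
 },
 {
  "name": "MBS",
  "category": "stress",
  "pattern": "CAACTG"
 },
 {
  "name": "LTR",
  "category": "stress",
  "pattern": "CCGAAA"
 },
 {
  "name": "ARE",
  "category": "stress",
  "pattern": "AAACCA"
 },
 {
  "name": "TC-rich",
  "category": "stress",
  "pattern": "ATTTTCTTCA"
 },
 {
  "name": "WUN-motif",
  "category": "stress",
  "pattern": "AAATTTCCT"
 },
 {
  "name": "RY-element",
  "category": "development",
  "pattern": "CATGCATG"
 },
 {
  "name": "G-box",
  "category": "light",
  "pattern": "CACGTG"
 },
 {
  "name": "Sp1",
  "category": "light",
  "pattern": "GGGCGG"
 }
]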