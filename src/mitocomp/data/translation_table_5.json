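{
 "id": 5,
 "name": "invertebrate mitochondrial",
 "codons": {
  "AAA": "K",
  "AAC": "N",
  "AAG": "K",
  "AAT": "N",
  "ACA": "T",
  "ACC": "T",
  "ACG": "T",
  "ACT": "T",
  "AGA": "S",
  "AGC": "S",
  "AGG": "S",
  "AGT": "S",
  "ATA": "M",
  "ATC": "I",
  "ATG": "M",
  "ATT": "I",
  "CAA": "Q",
  "CAC": "H",
  "CAG": "Q",
  "CAT": "H",
  "CCA": "P",
  "CCC": "P",
  "CCG": "P",
  "CCT": "P",
  "CGA": "R",
  "CGC": "R",
  "CGG": "R",
  "CGT": "R",
  "CTA": "L",
  "CTC": "L",
  "CTG": "L",
  "CTT": "L",
  "GAA": "E",
  "GAC": "D",
  "GAG": "E",
  "GAT": "D",
  "GCA": "A",
  "GCC": "A",
  "GCG": "A",
  "GCT": "A",
  "GGA": "G",
  "GGC": "G",
  "GGG": "G",
  "GGT": "G",
  "GTA": "V",
  "GTC": "V",
  "GTG": "V",
  "GTT": "V",
  "TAC": "Y",
  "TAT": "Y",
  "TCA": "S",
  "TCC": "S",
  "TCG": "S",
  "TCT": "S",
  "TGA": "W",
  "TGC": "C",
  "TGG": "W",
  "TGT": "C",
  "TTA": "L",
  "TTC": "F",
  "TTG": "L",
  "TTT": "F"
 },
 "stop_codons": [
  "TAA",
  "TAG"
 ],
 "start_codons": [
  "ATA",
  "ATC",
  "ATG",
  "ATT",
  "GTG",
  "TTG"
 ]
}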