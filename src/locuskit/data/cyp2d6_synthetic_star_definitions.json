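{
 "description": "Synthetic surrogate CYP2D6 gene reference and star-allele definition table (seeded; not the real gene sequence or PharmVar data)",
 "source": "synthetic",
 "seed": 20240817,
 "reference": "GGCCGCACTTATGTATAAAAATAGTGGAGCGGCAGGGGCACAGCGGATTCTACCGTCGACATTTACGCTCTGCTTTATCCATTGATAATCTACTATGTCAATGCAGCTTACCTATCAGCATGACCAGGAGATAACGGCAAATGCTGGTACGTTTGAGTACTCCTGCCCGCTGCTGGTCTGTGGTTCTCATGTCAATCCTCGCGTCGTTCGGCCACTTCACGCACGCACGGATGGTAGAGGCTTTCAATTGCTTGAGTTGTATTACGTTGGGACCACGACTACACGTGCTGGATCCAAGCTAGTCGCAGACGCTATTACCCAGGAAGGAGAGTGGCGCTCGGAAAGCTGCGACTGGTCAGTCTCAAGACAAGTCCCTAAAACAGCATGGTATCTTTGCCGGGTCAATTTGCAACCACCGCCAGGTAATATTCGCCCACGTGTTACTCGACTCAACACCCCAAAGAACAGTACTAGTTCATGGTTTCGGCGCAGGGAAACGCTTGACTCAAGGAAAGAAACAAAAAAATGTAAGAGAAAGTATGTGCCGCACGGGCTGCAATGTATAGGGCAATATGAACACATTGTGTGGCCTAAGGCAACGCGGGTTAGAAATTGTAAGGCGATTATCGGTCGATGGACTTCGGATTACATTTACCCCTCTTGGTCGTACAACGCACAGGTCGGGCCGCTTGGAATTGACGTCCGCGACGCATGTGGCGGGCAATGGACGCGAATCGGTCTTAGGTTTGACTTGCCAATTTCCGACCCTGAAGAACCTAACTCGACGCCGGTGGGCGGCCTAGTTGTAGCTCTAAGACTGGGAACGGTACCTCAGTCGGTGCGAGTACGTCGGCAAACATCTTATGGCGAGCCGCCCCCGTACTTGCATTGCTGTCGGTCGGGCGTCACTTGTAACTCTGCTAAACGATTCGAGTCGAAAGTTTTATTTCTGAACGTCCGACCTCCTGACTCGTTGGAGCCTGCGGTTCGCAAGACCTAAAAGGCCTTCTTGACCTATAGTCGAACCCTGTCGCGTGACATTACAGAAAACATCCTATGAAGTGCTTGTTTATTCAGCAGGTGAAGACACATGCAAATCGGGTTGCCCATCGAGCCGTCTCTCTATCTGTGGTGATGAATGGAGGGGAGA",
 "exons": [
  [
   100,
   1000
  ]
 ],
 "definitions": [
  {
   "star": "*1",
   "suballele": null,
   "variants": []
  },
  {
   "star": "*2",
   "suballele": null,
   "variants": [
    {
     "pos": 250,
     "ref": "C",
     "alt": "G"
    },
    {
     "pos": 700,
     "ref": "G",
     "alt": "A"
    }
   ]
  },
  {
   "star": "*3",
   "suballele": "*3.001",
   "variants": [
    {
     "pos": 411,
     "ref": "AC",
     "alt": "A"
    }
   ]
  },
  {
   "star": "*4",
   "suballele": "*4.001",
   "variants": [
    {
     "pos": 520,
     "ref": "A",
     "alt": "T"
    }
   ]
  },
  {
   "star": "*4",
   "suballele": "*4.013",
   "variants": [
    {
     "pos": 520,
     "ref": "A",
     "alt": "T"
    },
    {
     "pos": 905,
     "ref": "T",
     "alt": "G"
    }
   ]
  },
  {
   "star": "*6",
   "suballele": null,
   "variants": [
    {
     "pos": 629,
     "ref": "GT",
     "alt": "G"
    }
   ]
  },
  {
   "star": "*9",
   "suballele": null,
   "variants": [
    {
     "pos": 759,
     "ref": "TTCC",
     "alt": "T"
    }
   ]
  },
  {
   "star": "*10",
   "suballele": null,
   "variants": [
    {
     "pos": 180,
     "ref": "T",
     "alt": "G"
    }
   ]
  },
  {
   "star": "*17",
   "suballele": null,
   "variants": [
    {
     "pos": 340,
     "ref": "G",
     "alt": "T"
    },
    {
     "pos": 1020,
     "ref": "T",
     "alt": "C"
    }
   ]
  },
  {
   "star": "*29",
   "suballele": null,
   "variants": [
    {
     "pos": 460,
     "ref": "A",
     "alt": "C"
    },
    {
     "pos": 860,
     "ref": "C",
     "alt": "T"
    }
   ]
  },
  {
   "star": "*41",
   "suballele": null,
   "variants": [
    {
     "pos": 1110,
     "ref": "C",
     "alt": "T"
    }
   ]
  }
 ]
}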