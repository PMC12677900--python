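schema: 1
amino_acids:
- {three: GLY, one: G, era: early, rank: 1}
- {three: ALA, one: A, era: early, rank: 2}
- {three: ASP, one: D, era: early, rank: 3}
- {three: VAL, one: V, era: early, rank: 4}
- {three: PRO, one: P, era: early, rank: 5}
- {three: SER, one: S, era: early, rank: 6}
- {three: GLU, one: E, era: early, rank: 7}
- {three: LEU, one: L, era: early, rank: 8}
- {three: THR, one: T, era: early, rank: 9}
- {three: ILE, one: I, era: early, rank: 10}
- {three: ARG, one: R, era: late, rank: 11}
- {three: GLN, one: Q, era: late, rank: 12}
- {three: ASN, one: N, era: late, rank: 13}
- {three: HIS, one: H, era: late, rank: 14}
- {three: LYS, one: K, era: late, rank: 15}
- {three: CYS, one: C, era: late, rank: 16}
- {three: PHE, one: F, era: late, rank: 17}
- {three: TYR, one: Y, era: late, rank: 18}
- {three: MET, one: M, era: late, rank: 19}
- {three: TRP, one: W, era: late, rank: 20}
coenzyme_classes:
- name: ATP
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [ACP, ADP, AMP, ANP, ATP]
- name: Adenosylcobalamin
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [B12, COY]
- name: Ascorbic acid
  temporality: Post-LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [ASC]
- name: Biopterin
  temporality: Ancient
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [BIO, H4B]
- name: Biotin
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [BTI, BTN]
- name: Coenzyme A
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [ACO, COA]
- name: Coenzyme B
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: true
  ligands: [TP7]
- name: Coenzyme F420
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [F42]
- name: Coenzyme M
  temporality: Unclassified
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [COM]
- name: FAD
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [FAD]
- name: FMN
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [FMN]
- name: Factor F430
  temporality: Unclassified
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [F43]
- name: Glutathione
  temporality: Unclassified
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [GDS, GSH]
- name: Heme
  temporality: Ancient
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [HEA, HEB, HEC, HEM]
- name: Lipoic acid
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [LPA]
- name: MIO
  temporality: Post-LUCA
  nucleotide_derived: false
  phosphate_containing: false
  excluded: true
  ligands: []
- name: Menaquinone
  temporality: Post-LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [MQ7]
- name: Methanofuran
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [MFN]
- name: Molybdopterin
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: true
  ligands: [MGD, MTE]
- name: NAD
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [NAD, NAI, NAP, NDP]
- name: Orthoquinone
  temporality: Post-LUCA
  nucleotide_derived: false
  phosphate_containing: false
  excluded: true
  ligands: []
- name: Phosphopantetheine
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: true
  ligands: [PNS]
- name: Pyridoxal 5'-phosphate
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: true
  ligands: [PLP, PMP]
- name: Pyrroloquinoline quinone
  temporality: LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [PQQ]
- name: SAM
  temporality: Ancient
  nucleotide_derived: true
  phosphate_containing: false
  ligands: [SAH, SAM]
- name: Tetrahydrofolic acid
  temporality: Ancient
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [FFO, THF]
- name: Thiamine diphosphate
  temporality: Unclassified
  nucleotide_derived: false
  phosphate_containing: true
  ligands: [TDP, TPP]
- name: Ubiquinone
  temporality: Post-LUCA
  nucleotide_derived: false
  phosphate_containing: false
  ligands: [U10, UQ1]
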