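# Per-residue physical properties for the one-bead-per-residue model.
#
# volume: mean residue volume in A^3. Amino-acid values are the solution
#   partial volumes of Zamyatnin (1972, Prog. Biophys. Mol. Biol. 24:107).
#   Ribonucleotide values (one bead = base + ribose + phosphate) follow the
#   Voronoi nucleotide volumes of Voss & Gerstein (2005, J. Mol. Biol. 346:477),
#   rounded to 1 A^3.
# mass: residue mass in amu (monoisotopic-averaged residue weights; for
#   nucleotides the NMP residue within a chain).
# charge: net charge in elementary units at neutral pH and ~100 mM ionic
#   strength (Asp/Glu -1, Lys/Arg +1, His neutral, phosphate -1).
# class: interaction class (polar | hydrophobic | nucleotide) used to assign
#   the grouped well depth and solvation-repulsion parameters.
version: 1
residues:
  ALA: {letter: A, volume:  88.6, mass:  71.079, charge:  0, class: hydrophobic}
  ARG: {letter: R, volume: 173.4, mass: 156.188, charge:  1, class: polar}
  ASN: {letter: N, volume: 114.1, mass: 114.104, charge:  0, class: polar}
  ASP: {letter: D, volume: 111.1, mass: 115.089, charge: -1, class: polar}
  CYS: {letter: C, volume: 108.5, mass: 103.144, charge:  0, class: polar}
  GLN: {letter: Q, volume: 143.8, mass: 128.131, charge:  0, class: polar}
  GLU: {letter: E, volume: 138.4, mass: 129.116, charge: -1, class: polar}
  GLY: {letter: G, volume:  60.1, mass:  57.052, charge:  0, class: hydrophobic}
  HIS: {letter: H, volume: 153.2, mass: 137.142, charge:  0, class: polar}
  ILE: {letter: I, volume: 166.7, mass: 113.160, charge:  0, class: hydrophobic}
  LEU: {letter: L, volume: 166.7, mass: 113.160, charge:  0, class: hydrophobic}
  LYS: {letter: K, volume: 168.6, mass: 128.175, charge:  1, class: polar}
  MET: {letter: M, volume: 162.9, mass: 131.198, charge:  0, class: hydrophobic}
  PHE: {letter: F, volume: 189.9, mass: 147.177, charge:  0, class: hydrophobic}
  PRO: {letter: P, volume: 112.7, mass:  97.117, charge:  0, class: hydrophobic}
  SER: {letter: S, volume:  89.0, mass:  87.078, charge:  0, class: polar}
  THR: {letter: T, volume: 116.1, mass: 101.105, charge:  0, class: polar}
  TRP: {letter: W, volume: 227.8, mass: 186.213, charge:  0, class: hydrophobic}
  TYR: {letter: Y, volume: 193.6, mass: 163.176, charge:  0, class: hydrophobic}
  VAL: {letter: V, volume: 140.0, mass:  99.133, charge:  0, class: hydrophobic}
  ADE: {letter: A, volume: 315.0, mass: 329.206, charge: -1, class: nucleotide}
  GUA: {letter: G, volume: 323.0, mass: 345.205, charge: -1, class: nucleotide}
  CYT: {letter: C, volume: 288.0, mass: 305.181, charge: -1, class: nucleotide}
  URA: {letter: U, volume: 286.0, mass: 306.166, charge: -1, class: nucleotide}
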