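# Hydrogen-bond donor/acceptor flags per (residue, atom name), Sybyl-style.
# Each entry is [donor, acceptor]. Atoms not listed here are (0, 0) when the
# residue is known; unknown residue/atom names fall back to an element
# heuristic (see annotation.assign_hbond_flags).
backbone:
  N: [1, 0]
  O: [0, 1]
  OXT: [0, 1]
residues:
  ALA: {}
  GLY: {}
  VAL: {}
  LEU: {}
  ILE: {}
  PHE: {}
  PRO: {N: [0, 0]}          # no amide hydrogen
  MET: {SD: [0, 1]}
  CYS: {SG: [1, 1]}
  SER: {OG: [1, 1]}
  THR: {OG1: [1, 1]}
  TYR: {OH: [1, 1]}
  TRP: {NE1: [1, 0]}
  ASP: {OD1: [0, 1], OD2: [0, 1]}
  GLU: {OE1: [0, 1], OE2: [0, 1]}
  ASN: {OD1: [0, 1], ND2: [1, 0]}
  GLN: {OE1: [0, 1], NE2: [1, 0]}
  LYS: {NZ: [1, 0]}
  ARG: {NE: [1, 0], NH1: [1, 0], NH2: [1, 0]}
  HIS: {ND1: [1, 1], NE2: [1, 1]}
  MSE: {SE: [0, 1]}
element_fallback:
  N: [1, 1]
  O: [1, 1]
  S: [1, 1]
  SE: [0, 1]
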