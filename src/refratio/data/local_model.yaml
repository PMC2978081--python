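# Default parameters of the sequence-conditioned Markov basin model over
# backbone dihedrals: five Ramachandran basins with literature-typical centres
# and angular spreads (wrapped-normal, degrees), a first-order state chain with
# persistent helix/strand states, and residue-class-resolved transition rows
# (generic / glycine / proline / pre-proline). Users may supply their own file
# with the same schema.
states:
  - id: 0
    name: helix
    label: H
    mean_phi: -63.0
    mean_psi: -43.0
    spread: 7.0
  - id: 1
    name: strand
    label: E
    mean_phi: -118.0
    mean_psi: 130.0
    spread: 14.0
  - id: 2
    name: ppii
    label: C
    mean_phi: -70.0
    mean_psi: 148.0
    spread: 12.0
  - id: 3
    name: left_handed
    label: C
    mean_phi: 57.0
    mean_psi: 45.0
    spread: 10.0
  - id: 4
    name: extended_coil
    label: C
    mean_phi: -140.0
    mean_psi: 155.0
    spread: 25.0
initial: [0.25, 0.20, 0.25, 0.05, 0.25]
transition:
  generic:
    - [0.90, 0.01, 0.03, 0.01, 0.05]
    - [0.02, 0.85, 0.05, 0.01, 0.07]
    - [0.12, 0.20, 0.40, 0.03, 0.25]
    - [0.10, 0.10, 0.15, 0.25, 0.40]
    - [0.15, 0.22, 0.25, 0.08, 0.30]
  glycine:
    - [0.70, 0.02, 0.05, 0.08, 0.15]
    - [0.02, 0.60, 0.08, 0.10, 0.20]
    - [0.08, 0.15, 0.30, 0.17, 0.30]
    - [0.05, 0.05, 0.15, 0.40, 0.35]
    - [0.08, 0.15, 0.20, 0.22, 0.35]
  proline:
    - [0.15, 0.05, 0.44, 0.01, 0.35]
    - [0.15, 0.05, 0.44, 0.01, 0.35]
    - [0.15, 0.05, 0.44, 0.01, 0.35]
    - [0.15, 0.05, 0.44, 0.01, 0.35]
    - [0.15, 0.05, 0.44, 0.01, 0.35]
  preproline:
    - [0.40, 0.05, 0.20, 0.05, 0.30]
    - [0.03, 0.60, 0.12, 0.05, 0.20]
    - [0.05, 0.18, 0.35, 0.07, 0.35]
    - [0.05, 0.10, 0.15, 0.25, 0.45]
    - [0.06, 0.20, 0.22, 0.10, 0.42]
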