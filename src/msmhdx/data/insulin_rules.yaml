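# Default stand-in rules for the insulin monomer's elements of disorder.
# Thresholds are configurable geometry heuristics (nm / degrees / fractions);
# replace them with system-specific collective-variable definitions as needed.
elements:
  an_helix_melting:
    cv: helix_fraction
    chain: A
    start: 2
    end: 8
    op: "<"
    threshold: 0.5
  bn_detachment_partial:
    # B1-B7 loses native inter-chain contacts with A6-A11, but not completely
    cv: min_distance
    selection_a: {chain: B, start: 1, end: 7, atoms: heavy}
    selection_b: {chain: A, start: 6, end: 11, atoms: heavy}
    op: between
    lo: 0.6
    hi: 1.2
  bn_detachment_total:
    cv: min_distance
    selection_a: {chain: B, start: 1, end: 7, atoms: heavy}
    selection_b: {chain: A, start: 6, end: 11, atoms: heavy}
    op: ">"
    threshold: 1.2
  bc_detachment:
    # B24-B30 leaves the protein core (A-chain plus folded B-helix)
    cv: min_distance
    selection_a: {chain: B, start: 24, end: 30, atoms: CA}
    selection_b: {chain: A, start: 1, end: 21, atoms: CA}
    op: ">"
    threshold: 0.8
  b_helix_melting:
    cv: helix_fraction
    chain: B
    start: 9
    end: 14
    op: "<"
    threshold: 0.5
  b_helix_extension:
    cv: helix_fraction
    chain: B
    start: 19
    end: 23
    op: ">="
    threshold: 0.5
  beta_turn_shift:
    # native B23 HN...O=C B20 turn bond replaced by B22 HN...O=C B19
    cv: all_of
    rules:
      - cv: hbond
        donor: {chain: B, resid: 22}
        acceptor: {chain: B, resid: 19}
      - cv: "not"
        rule:
          cv: hbond
          donor: {chain: B, resid: 23}
          acceptor: {chain: B, resid: 20}
  a_plane_crossing:
    # B21 Ca crosses the plane through the Ca atoms of A9, A13, A20
    cv: plane_side
    plane:
      anchors: [[A, 9], [A, 13], [A, 20]]
      atom_name: CA
      reference: [B, 12, CA]
    atom: [B, 21, CA]
    op: "<"
    threshold: 0.0
  b_helix_rotation:
    # outward displacement of the top of the B-helix from the A-plane
    cv: plane_side
    plane:
      anchors: [[A, 9], [A, 13], [A, 20]]
      atom_name: CA
      reference: [B, 12, CA]
    atom: [B, 16, CA]
    op: "<"
    threshold: -0.3
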