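# Construct registry for the 12-entry esterase activity panel.
#
# panel_id 1 is the no-peptide standard (PBS/MeOH background hydrolysis) and
# has no peptide entry here; it exists only as a kinetics fixture.  Entries
# 5-11 are alanine substitutions of the CP4-Abeta fusion, listed in the order
# acids (E3, C-terminus), serines (S1, S4, S6), histidines (H9, H10).
# Entry 12 is the leupeptin-inhibited assembly (same chemistry as entry 2).
constructs:
  - name: CP4-AB
    panel_id: 2
    base_sequence: SMESLSKTHHYRFFKLVFF
    c_terminus: free
    assembled: true
  - name: CP4
    panel_id: 3
    base_sequence: SMESLSKTHHYR
    c_terminus: free
    assembled: false
  - name: CP4-GPP10
    panel_id: 4
    base_sequence: SMESLSKTHHYRGPPGPPGPPGPPGPPGPPGPPGPPGPPGPP
    c_terminus: free
    assembled: false
    method: endpoint-1200s
  - name: CP4-AB-E3A
    panel_id: 5
    base_sequence: SMESLSKTHHYRFFKLVFF
    mutations: [[3, E, A]]
    c_terminus: free
    assembled: true
  - name: CP4-AB-amide
    panel_id: 6
    base_sequence: SMESLSKTHHYRFFKLVFF
    c_terminus: amidated
    assembled: true
  - name: CP4-AB-S1A
    panel_id: 7
    base_sequence: SMESLSKTHHYRFFKLVFF
    mutations: [[1, S, A]]
    c_terminus: free
    assembled: true
  - name: CP4-AB-S4A
    panel_id: 8
    base_sequence: SMESLSKTHHYRFFKLVFF
    mutations: [[4, S, A]]
    c_terminus: free
    assembled: true
  - name: CP4-AB-S6A
    panel_id: 9
    base_sequence: SMESLSKTHHYRFFKLVFF
    mutations: [[6, S, A]]
    c_terminus: free
    assembled: true
  - name: CP4-AB-H9A
    panel_id: 10
    base_sequence: SMESLSKTHHYRFFKLVFF
    mutations: [[9, H, A]]
    c_terminus: free
    assembled: true
  - name: CP4-AB-H10A
    panel_id: 11
    base_sequence: SMESLSKTHHYRFFKLVFF
    mutations: [[10, H, A]]
    c_terminus: free
    assembled: true
  - name: CP4-AB-leupeptin
    panel_id: 12
    base_sequence: SMESLSKTHHYRFFKLVFF
    c_terminus: free
    assembled: true
    note: leupeptin-inhibited assembly
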