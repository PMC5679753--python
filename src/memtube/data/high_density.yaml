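# 50 proteins on the same tube (no pre-constriction): at this density the
# proteins spontaneously constrict the tube.
scenario: high_density
scale: 1.0
seed: 0
radius: 10.0
length: 100.0
n_proteins: 50
sweeps: 100000
burn_in: 10000
r_pr: 3.5
energy:
  k_cp: 0.0
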