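# Approximate domain boundaries for human dynamin 1 (author numbering).
# These are reasonable working defaults, not definitive annotations:
# hinge measurements on real coordinates may need range adjustment.
# Hinge 1 = Stalk/BSE junction; Hinge 2 = BSE/G-domain junction
# (around residues I289-P294, which form a continuous helix in one
# monomer of the two-start GG dimer and a kink in the other).

[Gdomain]
ranges = [[33, 293]]

[BSE]
ranges = [[1, 32], [294, 320], [711, 746]]

[Stalk]
ranges = [[321, 499], [643, 710]]

[PH]
ranges = [[500, 642]]
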