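# van der Waals radii (Å) by heavy-atom class, used to build hard cores
# sigma_ij = alpha * (r_i + r_j).  The aliphatic-carbon radius is pinned so that
# lambda * alpha * 2r = 4.7 Å for a methyl-carbon pair at alpha = 0.80, lambda = 1.6.
# Other values follow the Bondi element set.
class	radius
C_ALI	1.836
C_SP2	1.700
C_ARO	1.770
N	1.550
O	1.520
S	1.800
P	1.800
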