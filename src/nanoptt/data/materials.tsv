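# Packaged material table.
# Columns: name rho[kg/m3] RI mu_a[1/cm] mu_s[1/cm] g Cp[J/(kg.K)] alpha[mm2/s] wb[1/s] eps_re eps_im element:weight...
# Optical coefficients at 808 nm. Composition weights are normalized at load
# time. g = 0.9 for soft tissue (typical near-infrared anisotropy), 0 for
# water. The tumor_gnr row is the nanorod-loaded tumor property set: its mu_a
# lumps the nanoparticle contribution (used with nano_absorption: table);
# with the default nano_absorption: from_gnr the tissue mu_a is overridden
# and the nano channel is computed from the rod load. eps_re/eps_im is the
# host permittivity seen by embedded particles.
pancreas   1040.0    1.394  0.0388  196.8   0.9  3554.6  0.14  0.0  1.767   0.0  H:1.06 C:1.69 N:0.22 O:6.94 Na:0.02 P:0.02 S:0.01 Cl:0.02 K:0.02
tumor_gnr  1040.012  1.3939 1.6850  0.0274  0.9  3605.7  0.16  0.0  1.767   0.0  H:1.059 C:1.68 N:0.219 O:6.939 Na:0.019 P:0.019 S:0.0099 Cl:0.019 K:0.019 Au:0.0012
water      998.0     1.33   0.0220  0.0     0.0  4182.0  0.146 0.0  1.7689  0.0  H:0.112 O:0.888
water_gnr  998.6     1.33   0.0220  0.0     0.0  4182.0  0.146 0.0  1.7689  0.0  H:0.112 O:0.888
air        1.2       1.0    0.0     0.0     0.0  1005.0  19.0  0.0  1.0     0.0
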