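# Synthetic bulk-gold dielectric table: analytic Drude representation of
# measured near-infrared gold optical constants (eps_inf=9.5,
# hbar*omega_p=8.788 eV, hbar*gamma=0.0655 eV). Intended for 600-1100 nm;
# interband transitions below ~600 nm are not modelled.
# wavelength_nm  eps_re  eps_im
  500.0  -3.05118  0.33154
  510.0  -3.55788  0.35182
  520.0  -4.07458  0.37291
  530.0  -4.60129  0.39483
  540.0  -5.13800  0.41759
  550.0  -5.68470  0.44121
  560.0  -6.24141  0.46570
  570.0  -6.80810  0.49108
  580.0  -7.38480  0.51737
  590.0  -7.97148  0.54457
  600.0  -8.56815  0.57272
  610.0  -9.17481  0.60181
  620.0  -9.79146  0.63188
  630.0  -10.41809  0.66292
  640.0  -11.05470  0.69497
  650.0  -11.70129  0.72803
  660.0  -12.35786  0.76213
  670.0  -13.02440  0.79727
  680.0  -13.70092  0.83347
  690.0  -14.38740  0.87075
  700.0  -15.08385  0.90912
  710.0  -15.79027  0.94861
  720.0  -16.50666  0.98922
  730.0  -17.23300  1.03097
  740.0  -17.96930  1.07388
  750.0  -18.71556  1.11796
  760.0  -19.47177  1.16322
  770.0  -20.23793  1.20970
  780.0  -21.01405  1.25739
  790.0  -21.80010  1.30631
  800.0  -22.59611  1.35649
  810.0  -23.40205  1.40794
  820.0  -24.21793  1.46066
  830.0  -25.04374  1.51469
  840.0  -25.87949  1.57002
  850.0  -26.72517  1.62669
  860.0  -27.58077  1.68470
  870.0  -28.44630  1.74407
  880.0  -29.32175  1.80482
  890.0  -30.20712  1.86695
  900.0  -31.10240  1.93050
  910.0  -32.00760  1.99546
  920.0  -32.92271  2.06187
  930.0  -33.84772  2.12973
  940.0  -34.78263  2.19906
  950.0  -35.72745  2.26987
  960.0  -36.68216  2.34218
  970.0  -37.64677  2.41601
  980.0  -38.62126  2.49137
  990.0  -39.60565  2.56828
 1000.0  -40.59992  2.64674
 1010.0  -41.60407  2.72679
 1020.0  -42.61809  2.80843
 1030.0  -43.64199  2.89168
 1040.0  -44.67577  2.97655
 1050.0  -45.71941  3.06306
 1060.0  -46.77291  3.15123
 1070.0  -47.83627  3.24107
 1080.0  -48.90949  3.33259
 1090.0  -49.99257  3.42582
 1100.0  -51.08549  3.52076
 1110.0  -52.18826  3.61743
 1120.0  -53.30087  3.71585
 1130.0  -54.42332  3.81604
 1140.0  -55.55561  3.91800
 1150.0  -56.69772  4.02176
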