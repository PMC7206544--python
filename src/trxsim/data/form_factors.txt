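# Cromer-Mann analytic X-ray atomic form factors (4-Gaussian + constant),
# International Tables for Crystallography Vol. C convention:
#   f(q) = sum_i a_i * exp(-b_i * s^2) + c,   s = q / (4*pi)  [A^-1]
# columns: element  Z  a1 b1 a2 b2 a3 b3 a4 b4 c
H   1   0.489918  20.6593   0.262003   7.74039   0.196767  49.5519   0.049879   2.20159    0.001305
C   6   2.31000   20.8439   1.02000   10.2075    1.58860    0.568700  0.865000  51.6512    0.215600
N   7  12.2126     0.005700  3.13220   9.89330   2.01250   28.9975    1.16630    0.582600 -11.5290
O   8   3.04850   13.2771    2.28680   5.70110   1.54630    0.323900  0.867000  32.9089    0.250800
F   9   3.53920   10.2825    2.64120   4.29440   1.51700    0.261500  1.02430   26.1476    0.277600
S  16   6.90530    1.46790   5.20340  22.2151    1.43790    0.253600  1.58630   56.1720    0.866900
Cl 17  11.4604     0.010400  7.19640   1.16620   6.25560   18.5194    1.64550   47.7784   -9.55740
Fe 26  11.7695     4.76110   7.35730   0.307200  3.52220   15.3535    2.30450   76.8805    1.03690
Br 35  17.1789     2.17230   5.23580  16.5796    5.63770    0.260900  3.98510   41.4328    2.95570
Ru 44  19.2674     0.808520 12.9182    8.43467   4.86337   24.7997    1.56756   94.2928    5.37874
I  53  20.1472     4.34700  18.9949    0.381400  7.51380   27.7660    2.27350   66.8776    4.07120
Pt 78  27.0059     1.51293  17.7639    8.81174  15.7131     0.424593  5.78370   38.6103   11.6883
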