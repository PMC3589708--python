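H RADA880102
D Transfer free energy from oct to wat (Radzicka-Wolfenden, 1988)
R PMID:3401445
A Radzicka, A. and Wolfenden, R.
T Comparing the polarities of the amino acids: side-chain distribution
  coefficients between the vapor phase, cyclohexane, 1-octanol, and neutral
  aqueous solution
J Biochemistry 27, 1664-1670 (1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.52   -1.32   -0.01    0.00    0.00   -0.07   -0.79    0.00    0.95    2.04
    1.76    0.08    1.32    2.09    0.00    0.04    0.27    2.51    1.63    1.18
//
H FAUJ880103
D Normalized van der Waals volume (Fauchere et al., 1988)
R PMID:3209351
A Fauchere, J.L., Charton, M., Kier, L.B., Verloop, A. and Pliska, V.
T Amino acid side chain parameters for correlation studies in biology and
  pharmacology
J Int. J. Peptide Protein Res. 32, 269-278 (1988)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.00    6.13    2.95    2.78    2.43    3.95    3.78    0.00    4.66    4.00
    4.00    4.77    4.43    5.89    2.72    1.60    2.60    8.08    6.47    3.00
//
H ZIMJ680104
D Isoelectric point (Zimmerman et al., 1968)
R PMID:5700434
A Zimmerman, J.M., Eliezer, N. and Simha, R.
T The characterization of amino acid sequences in proteins by statistical
  methods
J J. Theor. Biol. 21, 170-201 (1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    6.00   10.76    5.41    2.77    5.05    5.65    3.22    5.97    7.59    6.02
    5.98    9.74    5.74    5.48    6.30    5.68    5.66    5.89    5.66    5.96
//
H GRAR740102
D Polarity (Grantham, 1974)
R PMID:4843792
A Grantham, R.
T Amino acid difference formula to help explain protein evolution
J Science 185, 862-864 (1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.1    10.5    11.6    13.0     5.5    10.5    12.3     9.0    10.4     5.2
     4.9    11.3     5.7     5.2     8.0     9.2     8.6     5.4     6.2     5.9
//
H CRAJ730103
D Normalized frequency of turn (Crawford et al., 1973)
R PMID:4510292
A Crawford, J.L., Lipscomb, W.N. and Schellman, C.G.
T The reverse turn as a polypeptide conformation in globular proteins
J Proc. Natl. Acad. Sci. USA 70, 538-542 (1973)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.60    0.79    1.42    1.24    1.29    0.92    0.64    1.38    0.95    0.67
    0.70    1.10    0.67    1.05    1.47    1.26    1.05    1.23    1.35    0.48
//
H DAWD720101
D Size (Dawson, 1972)
R
A Dawson, D.M.
T The Biochemical Genetics of Man
J "The Biochemical Genetics of Man" (Brock, D.J.H. and Mayo, O., eds.),
  Academic Press, New York, pp.1-38 (1972)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     2.5     7.5     5.0     2.5     3.0     6.0     5.0     0.5     6.0     5.5
     5.5     7.0     6.0     6.5     5.5     3.0     5.0     7.0     7.0     5.0
//
H CHAM820102
D Free energy of solution in water, kcal/mole (Charton-Charton, 1982)
R PMID:7183857
A Charton, M. and Charton, B.I.
T The structural dependence of amino acid hydrophobicity parameters
J J. Theor. Biol. 99, 629-644 (1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -0.368  -1.030   0.000   2.060   4.530   0.731   1.770  -0.525   0.000   0.791
   1.070   0.000   0.656   1.060  -2.240  -0.524   0.000   1.600   4.910   0.401
//
H CRAJ730101
D Normalized frequency of middle helix (Crawford et al., 1973)
R PMID:4510292
A Crawford, J.L., Lipscomb, W.N. and Schellman, C.G.
T The reverse turn as a polypeptide conformation in globular proteins
J Proc. Natl. Acad. Sci. USA 70, 538-542 (1973)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.33    0.79    0.72    0.97    0.93    1.42    1.66    0.58    1.49    0.99
    1.29    1.03    1.40    1.15    0.49    0.83    0.94    1.33    0.49    0.96
//
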