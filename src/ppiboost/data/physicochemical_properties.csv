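# Seven physicochemical properties of amino-acid side chains, the set used by
# autocovariance/autocorrelation sequence descriptors for PPI prediction
# (Guo et al. 2008, Nucleic Acids Res 36:3025; values as tabulated there and in
# the AAindex database):
#   hydrophobicity       Tanford consensus scale
#   hydrophilicity       Hopp & Woods 1981
#   side_chain_volume    Krigbaum & Komoriya side-chain volume (A^3)
#   polarity             Grantham 1974
#   polarizability       Charton & Charton 1982
#   sasa                 solvent-accessible surface area (Collantes & Dunn 1995, x100 A^2)
#   net_charge_index     net charge index of side chains (Zhou et al.)
# Values are standardized (population mean 0, SD 1 over the 20 residues) at load time.
amino_acid,hydrophobicity,hydrophilicity,side_chain_volume,polarity,polarizability,sasa,net_charge_index
A,0.62,-0.5,27.5,8.1,0.046,1.181,0.007187
C,0.29,-1.0,44.6,5.5,0.128,1.461,-0.036610
D,-0.90,3.0,40.0,13.0,0.105,1.587,-0.023820
E,-0.74,3.0,62.0,12.3,0.151,1.862,0.006802
F,1.19,-2.5,115.5,5.2,0.290,2.228,0.037552
G,0.48,0.0,0.0,9.0,0.000,0.881,0.179052
H,-0.40,-0.5,79.0,10.4,0.230,2.025,-0.010690
I,1.38,-1.8,93.5,5.2,0.186,1.810,0.021631
K,-1.50,3.0,100.0,11.3,0.219,2.258,0.017708
L,1.06,-1.8,93.5,4.9,0.186,1.931,0.051672
M,0.64,-1.3,94.1,5.7,0.221,2.034,0.002683
N,-0.78,0.2,58.7,11.6,0.134,1.655,0.005392
P,0.12,0.0,41.9,8.0,0.131,1.468,0.239531
Q,-0.85,0.2,80.7,10.5,0.180,1.932,0.049211
R,-2.53,3.0,105.0,10.5,0.291,2.560,0.043587
S,-0.18,0.3,29.3,9.2,0.062,1.298,0.004627
T,-0.05,-0.4,51.3,8.6,0.108,1.525,0.003352
V,1.08,-1.5,71.5,5.9,0.140,1.645,0.057004
W,0.81,-3.4,145.5,5.4,0.409,2.663,0.037977
Y,0.26,-2.3,117.3,6.2,0.298,2.368,0.023599
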