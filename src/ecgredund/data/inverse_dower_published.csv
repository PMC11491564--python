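# Inverse Dower transform as published (3-decimal rounding) by
# Edenbrandt & Pahlm, J Electrocardiol 1988: least-squares reconstruction of
# the VCG axes X, Y, Z from the 8 independent leads.  Kept for reference and
# cross-checking; the transform actually applied is the full-precision
# pseudoinverse of dower_forward.csv (see transforms module docs).
axis,V1,V2,V3,V4,V5,V6,I,II
X,-0.172,-0.074,0.122,0.231,0.239,0.194,0.156,-0.010
Y,0.057,-0.019,-0.106,-0.022,0.041,0.048,-0.227,0.887
Z,-0.229,-0.310,-0.246,-0.063,0.055,0.108,0.022,0.102
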