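# Dower forward lead matrix: synthesizes the 8 independent ECG leads from
# the orthogonal VCG axes X, Y, Z.  Coefficients from G.E. Dower's image
# surface model as tabulated by Edenbrandt & Pahlm, J Electrocardiol 1988.
lead,X,Y,Z
V1,-0.515,0.157,-0.917
V2,0.044,0.164,-1.387
V3,0.882,0.098,-1.277
V4,1.213,0.127,-0.601
V5,1.125,0.127,-0.086
V6,0.831,0.076,0.230
I,0.632,-0.235,0.059
II,0.235,1.066,-0.132
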