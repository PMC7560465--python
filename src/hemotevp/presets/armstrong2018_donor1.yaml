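# Fitted TEVP constants for a second donor
# (steady shear + triangular ramps + oscillatory sweeps).
G: 0.15         # Pa
eta0: 0.035     # Pa.s
tau_y: 0.006    # Pa
eps_ptt: 0.001
k1: 0.092       # 1/s
k2: 0.45
k3: 1720.0
n1: 1.67
n2: 3.41
n3: 1.67
m1: 0.91
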