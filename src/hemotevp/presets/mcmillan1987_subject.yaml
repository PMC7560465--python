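# Fitted TEVP constants for a healthy subject, hematocrit 45%
# (steady simple shear + intermittent rectangular shear steps).
G: 0.382        # Pa
eta0: 0.012     # Pa.s
tau_y: 0.0035   # Pa
eps_ptt: 0.001
k1: 0.0918      # 1/s
k2: 7.249
k3: 6974.9
n1: 3.03
n2: 4.068
n3: 3.03
m1: 0.701
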