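# Calibrated "default-cn" parameter set.
#
# Time is dimensionless; abundances are molecule counts.  The set is chosen
# so that (i) input, state and receptor dynamics are fast relative to weight
# turnover (kappa, d_B, k_plus*B >> d_H), (ii) a single bolus converts almost
# fully to internal state when the channel weight is high (k_cat * 100 >> d_B)
# but barely when the weight is zero (k_AB << d_B), and (iii) 40 receptor
# copies are present at t = 0.
E_total: 40
H_init: null
N: 2
beta: 50
coop_factor: 0.01
d_B: 20.0
d_H: 0.01
k_AB: 5.0
k_BA: 0.005
k_cat: 1.0
k_cat_rev: 0.001
k_learn: 2.0
k_learn_rev: 0.002
k_minus: 1000.0
k_plus: 10.0
kappa: 100.0
m: 1
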