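environment,arch,n_units,eta0,sigma0_x,sigma0_h,mu0_diag
unigram,gated,3,8.00e-2,0.02,0.02,0
unigram,gated,11,6.60e-2,0.43,0.21,0
unigram,gated,45,4.20e-2,1,0.02,0
unigram,no_gating,3,2.50e-2,1,0.07,0
unigram,no_gating,11,1.70e-2,1,0.07,0
unigram,no_gating,45,7.60e-3,1,0.08,0
unigram,no_gating,1000,1.34e-4,1,0.04,0
unigram,no_lateral,3,5.30e-2,0.02,0.02,1
unigram,no_lateral,11,2.70e-2,1,0.02,1
unigram,no_lateral,45,1.30e-2,1,1,1
unigram,frozen_recurrence,3,1.00e-1,1.07,0.55,0
unigram,frozen_recurrence,11,1.00e-1,2,0.41,0
unigram,frozen_recurrence,45,1.00e-1,2,0.26,0
unigram,frozen_recurrence,474,9.60e-3,1,0.1,0
bigram,gated,3,6.30e-2,0.02,1,0
bigram,gated,11,4.40e-2,1,0.02,0
bigram,gated,45,1.60e-2,1,0.02,0
bigram,no_gating,3,5.50e-2,0.02,0.13,0
bigram,no_gating,11,3.20e-2,1,0.05,0
bigram,no_gating,45,8.90e-3,1,0.06,0
bigram,no_gating,1000,5.97e-5,1,0.03,0
bigram,no_lateral,3,4.30e-2,1,0.02,0
bigram,no_lateral,11,4.30e-2,1,1,0
bigram,no_lateral,45,2.80e-2,1,1,0
bigram,frozen_recurrence,3,6.60e-2,0.73,0.55,0
bigram,frozen_recurrence,11,1.00e-1,2,0.45,0
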