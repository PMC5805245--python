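ses,age_group,tau1,tau2,tau3,tau4
all,0-4,3.7564E-03,1.9989E-03,3.2706E-08,3.3883E-02
all,5-9,5.0334E-03,2.3978E-07,4.3462E-07,1.6578E-08
all,10-14,8.6916E-04,4.8673E-03,2.2426E-02,5.8634E-13
all,15-19,1.8773E-02,5.4279E-03,4.2342E-10,2.6586E-10
all,20-24,3.3429E-02,6.3982E-03,9.1309E-08,3.2073E-08
all,25-29,3.5826E-02,1.2145E-02,9.3667E-09,5.1414E-09
all,30-34,2.7964E-02,7.9848E-03,4.3676E-08,2.6979E-08
all,35-39,2.6149E-02,8.3326E-03,1.4624E-07,1.1489E-07
all,40-44,2.4555E-02,7.5370E-03,3.3784E-08,1.3284E-08
all,45-49,1.3626E-02,7.9259E-03,3.9024E-08,4.0720E-08
all,50-54,1.1986E-02,6.6221E-03,3.7719E-08,3.3221E-08
all,55-59,7.0130E-03,2.0203E-05,9.4052E-04,1.3984E-05
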