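ses,age_group,tau1,tau2,tau3,tau4
lower,0-4,1.3101E-03,1.0178E-09,1.0385E-04,4.6690E-02
lower,5-9,5.4557E-03,9.4718E-03,3.9426E-05,1.3408E-06
lower,10-14,4.6920E-03,3.9616E-03,6.3557E-05,2.3025E-08
lower,15-19,2.1034E-02,1.2332E-02,2.1903E-07,7.4870E-09
lower,20-24,3.7871E-02,7.6258E-03,1.9824E-09,7.2788E-10
lower,25-29,3.8596E-02,1.5073E-02,5.6016E-09,7.7021E-09
lower,30-34,3.1630E-02,1.5140E-02,8.3486E-09,1.8000E-09
lower,35-39,3.3527E-02,1.2201E-02,2.7137E-08,3.1316E-08
lower,40-44,2.8545E-02,1.6784E-02,2.5729E-08,2.2934E-08
lower,45-49,1.8423E-02,1.2963E-02,5.5552E-07,4.4111E-07
lower,50-54,2.3425E-02,8.1058E-03,2.8806E-07,3.1162E-07
lower,55-59,1.4192E-02,4.1445E-03,1.1794E-06,1.7226E-07
middle,0-4,2.7128E-03,3.2160E-07,5.8332E-06,3.6038E-02
middle,5-9,5.8460E-03,5.3030E-08,2.3327E-02,1.4725E-03
middle,10-14,3.6125E-11,3.6311E-03,4.1365E-02,8.0070E-03
middle,15-19,1.7817E-02,4.1455E-03,5.8434E-07,3.1814E-08
middle,20-24,3.0706E-02,7.7520E-03,2.0614E-10,1.4237E-09
middle,25-29,3.3597E-02,1.3152E-02,4.1736E-12,6.1903E-12
middle,30-34,2.2712E-02,9.8560E-03,1.0235E-08,4.0128E-09
middle,35-39,2.2688E-02,1.2577E-02,7.0527E-08,7.7958E-08
middle,40-44,2.5588E-02,6.6106E-03,1.5016E-08,4.8602E-08
middle,45-49,1.0972E-02,1.1705E-02,2.7996E-06,2.9301E-07
middle,50-54,1.0326E-02,8.9437E-03,2.3323E-07,8.4381E-08
middle,55-59,1.0859E-02,4.3522E-08,3.4101E-03,2.1121E-03
higher,0-4,6.1520E-03,2.3632E-02,3.0024E-11,8.9323E-10
higher,5-9,3.7007E-03,1.8209E-03,5.9251E-03,2.8633E-08
higher,10-14,2.9523E-07,2.7947E-09,4.2175E-02,2.1652E-02
higher,15-19,1.7719E-02,3.4803E-03,4.0073E-08,1.0205E-08
higher,20-24,3.1893E-02,5.2272E-03,1.2582E-08,5.3230E-09
higher,25-29,3.5510E-02,9.0317E-03,1.8883E-09,1.0375E-09
higher,30-34,2.8969E-02,2.5534E-03,5.1140E-10,1.5520E-09
higher,35-39,2.3850E-02,4.1629E-03,9.7547E-10,8.0792E-09
higher,40-44,2.2747E-02,3.8605E-03,7.3569E-09,2.3592E-08
higher,45-49,1.5990E-02,4.7485E-03,8.3930E-08,8.9747E-07
higher,50-54,5.4516E-03,5.9228E-03,1.4811E-06,1.2808E-07
higher,55-59,7.0109E-03,8.2735E-08,2.6205E-03,1.9005E-03
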