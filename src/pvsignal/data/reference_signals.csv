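drug,drug_total,pt_term,n_reports,prr,ror,ic025,signal_positive
omalizumab,32457,anaphylactic reaction,1437,9.61,10.01,3.17,true
omalizumab,32457,anaphylactic shock,193,1.51,1.51,0.38,false
omalizumab,32457,anaphylactoid reaction,82,1.05,1.05,-0.26,false
omalizumab,32457,anaphylactoid shock,2,1.74,1.74,-1.99,false
omalizumab,32457,circulatory collapse,12,0.30,0.30,-2.63,false
omalizumab,32457,kounis syndrome,1,1.34,1.35,-3.53,false
omalizumab,32457,shock,12,0.51,0.51,-1.88,false
omalizumab,32457,shock symptom,1,0.91,0.91,-3.89,false
omalizumab,32457,type 1 hypersensitivity,34,6.12,6.12,1.97,true
mepolizumab,7283,anaphylactic reaction,84,2.47,2.49,0.97,true
mepolizumab,7283,anaphylactic shock,11,0.38,0.38,-2.32,false
mepolizumab,7283,anaphylactoid reaction,5,0.29,0.29,-3.24,false
mepolizumab,7283,circulatory collapse,2,0.22,0.22,-2.63,false
mepolizumab,7283,shock,1,0.19,0.19,-5.75,false
mepolizumab,7283,type 1 hypersensitivity,1,0.80,0.80,-4.03,false
benralizumab,2363,anaphylactic reaction,54,4.90,4.99,1.83,true
benralizumab,2363,anaphylactic shock,3,0.32,0.32,-3.54,false
benralizumab,2363,anaphylactoid reaction,3,0.53,0.53,-2.87,false
benralizumab,2363,circulatory collapse,2,0.68,0.68,-3.04,false
benralizumab,2363,kounis syndrome,1,18.50,18.51,-2.36,false
benralizumab,2363,shock,1,0.58,0.58,-4.37,false
benralizumab,2363,type 1 hypersensitivity,1,2.45,2.45,-3.07,false
reslizumab,313,anaphylactic reaction,4,2.74,2.76,-0.54,false
reslizumab,313,anaphylactoid reaction,1,1.33,1.33,-3.54,false
dupilumab,20548,anaphylactic reaction,37,0.39,0.38,-1.86,false
dupilumab,20548,anaphylactic shock,4,0.05,0.05,-5.92,false
dupilumab,20548,anaphylactoid reaction,1,0.02,0.02,-8.85,false
dupilumab,20548,circulatory collapse,4,0.16,0.16,-4.26,false
dupilumab,20548,shock,2,0.13,0.13,-5.22,false
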