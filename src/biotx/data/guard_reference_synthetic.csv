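compartment,smiles,average_mass,alogp,heteroatom_count,ring_count
renal_hepatic,Oc1ccccc1,94.1130,1.3922,1,1
renal_hepatic,Cc1ccc(O)cc1,108.1400,1.7006,1,1
renal_hepatic,O=C(O)CNC(=O)c1ccccc1,179.1750,0.5010,4,1
renal_hepatic,CC(=O)Nc1ccc(O)cc1,151.1650,1.3506,3,1
renal_hepatic,CC(=O)Nc1ccc(OC2OC(C(=O)O)C(O)C(O)C2O)cc1,327.2890,-1.0840,9,2
renal_hepatic,CC(=O)Nc1ccc(OS(=O)(=O)O)cc1,231.2290,0.8266,7,1
renal_hepatic,O=S(=O)(O)Oc1ccccc1,174.1770,0.8682,5,1
renal_hepatic,O=C(O)C1OC(Oc2ccccc2O)C(O)C(O)C1O,286.2360,-1.3368,8,2
renal_hepatic,Cc1ccc(OS(=O)(=O)O)cc1,188.2040,1.1766,5,1
renal_hepatic,O=S(=O)(O)Oc1cc[nH]c1,163.1540,0.1963,6,1
renal_hepatic,CN1CC(=O)N=C1N,113.1200,-1.2269,4,1
renal_hepatic,O=c1[nH]c(=O)c2[nH]c(=O)[nH]c2[nH]1,168.1120,-1.7672,7,2
renal_hepatic,O=C(O)CC(O)(CC(=O)O)C(=O)O,192.1230,-1.2485,7,0
renal_hepatic,OCC1OC(O)C(O)C(O)C1O,180.1560,-3.2214,6,1
renal_hepatic,O=C(O)C1OC(O)C(O)C(O)C1O,194.1390,-3.1291,7,1
renal_hepatic,O=C(O)c1ccccc1O,138.1220,1.0904,3,1
renal_hepatic,O=C(O)CNC(=O)c1ccccc1O,195.1740,0.2066,5,1
renal_hepatic,O=C(O)c1ccccc1,122.1230,1.3848,2,1
renal_hepatic,Nc1ccc(O)cc1,109.1280,0.9744,2,1
renal_hepatic,CC(=O)NC(CSc1ccccc1)C(=O)O,239.2960,1.3680,5,1
renal_hepatic,Cn1c(=O)c2c(ncn2C)n(C)c1=O,194.1940,-1.0293,6,2
renal_hepatic,Cn1cnc2c1c(=O)[nH]c(=O)n2C,180.1670,-1.0397,6,2
renal_hepatic,CN1CCCC1c1cccnc1,162.2360,1.8483,2,2
renal_hepatic,CN1CCCC1=O,99.1330,0.2386,2,1
renal_hepatic,O=C(O)C(O)c1ccccc1,152.1490,0.8046,3,1
renal_hepatic,NC(=O)CCC(NC(=O)Cc1ccccc1)C(=O)O,264.2810,0.0640,6,1
renal_hepatic,O=C(O)c1ccc(O)cc1,138.1220,1.0904,3,1
renal_hepatic,COc1cc(C=O)ccc1O,152.1490,1.2133,3,1
renal_hepatic,COc1cc(CC(=O)O)ccc1O,182.1750,1.0279,4,1
renal_hepatic,CC(O)C(=O)O,90.0780,-0.5482,3,0
renal_hepatic,CC(C)=O,58.0800,0.5953,1,0
renal_hepatic,CC=O,44.0530,0.2052,1,0
renal_hepatic,CC(=O)O,60.0520,0.0909,2,0
renal_hepatic,O=CO,46.0250,-0.2992,2,0
renal_hepatic,NC(CCC(=O)NC(CSCC(O)c1ccccc1)C(=O)NCC(=O)O)C(=O)O,427.4790,-0.6691,11,1
renal_hepatic,CC(C)Cc1ccc(C(C)C(=O)OC2OC(C(=O)O)C(O)C(O)C2O)cc1,382.4090,0.4240,8,2
gut_fecal,CC(=O)O,60.0520,0.0909,2,0
gut_fecal,CCC(=O)O,74.0790,0.4810,2,0
gut_fecal,CCCC(=O)O,88.1060,0.8711,2,0
gut_fecal,Oc1ccccc1,94.1130,1.3922,1,1
gut_fecal,Cc1ccc(O)cc1,108.1400,1.7006,1,1
gut_fecal,c1ccc2[nH]ccc2c1,117.1510,2.1679,1,2
gut_fecal,Cc1c[nH]c2ccccc12,131.1780,2.4763,1,2
gut_fecal,O=C(O)Cc1ccccc1,136.1500,1.3137,2,1
gut_fecal,O=C(O)Cc1ccc(O)cc1,152.1490,1.0193,3,1
gut_fecal,O=C(O)c1ccccc1,122.1230,1.3848,2,1
gut_fecal,Oc1ccccc1O,110.1120,1.0978,2,1
gut_fecal,Oc1cccc(O)c1,110.1120,1.0978,2,1
gut_fecal,Oc1ccc(O)cc1,110.1120,1.0978,2,1
gut_fecal,Nc1ccccc1,93.1290,1.2688,1,1
gut_fecal,OCC1OC(O)C(O)C(O)C1O,180.1560,-3.2214,6,1
gut_fecal,O=C(O)C1OC(O)C(O)C(O)C1O,194.1390,-3.1291,7,1
gut_fecal,NCCc1c[nH]c2ccccc12,160.2200,1.6691,2,2
gut_fecal,NCCc1ccc(O)cc1,137.1820,0.8934,2,1
gut_fecal,NCCc1ccc(O)c(O)c1,153.1810,0.5990,3,1
gut_fecal,CC(N)C(=O)O,89.0940,-0.5818,3,0
gut_fecal,NCCCC(=O)O,103.1210,-0.1901,3,0
gut_fecal,O=C(O)CCC(=O)O,118.0880,-0.0642,4,0
gut_fecal,CC(O)C(=O)O,90.0780,-0.5482,3,0
gut_fecal,CCO,46.0690,-0.0014,1,0
gut_fecal,CS,48.1100,0.5460,1,0
gut_fecal,CN(C)C,59.1120,0.1778,1,0
gut_fecal,CCCCCCCC(=O)O,144.2140,2.4315,2,0
gut_fecal,CC(C)CC(=O)O,102.1330,1.1171,2,0
gut_fecal,O=c1ccc2ccc(O)cc2o1,162.1440,1.4986,3,2
gut_fecal,O=c1oc2cc(O)ccc2c2ccc(O)cc12,228.2030,2.3574,4,3
gut_fecal,O=C(O)CCc1ccc(O)cc1,166.1760,1.4094,3,1
gut_fecal,O=C(O)/C=C/c1ccc(O)cc1,164.1600,1.4900,3,1
gut_fecal,CC12CCC3c4ccc(O)cc4CCC3C1CCC2O,272.3880,3.6092,2,4
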