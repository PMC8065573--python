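id,name,rt,rt_sd,conc_uM,conc_sd_uM,reference_uM,reference_sd_uM
M004,Alanine (2TMS),7.42,0.00,276,21,300,26
M005,Asparagine (3TMS),14.92,0.00,71.3,1.4,,
M006,Aspartic acid (3TMS),13.15,0.00,39.5,0.3,,
M008,Citric acid (4TMS),16.54,0.00,48,2.8,,
M009,Cysteine (3TMS),13.6,0.00,41.8,0.8,44.3,6.9
M012,Fructose-syn (5TMS),17.06,0.00,96.9,20.1,,
M014,Glucose-syn (5TMS),17.33,0.00,4270,366,4560,56
M015,Glutamic acid (3TMS),14.35,0.00,71.5,3.2,67.4,18
M016,Glutamine (3TMS),16.08,0.00,284,11,,
M017,Glycerol (3TMS),9.89,0.00,179,13,,
M018,Glycine (3TMS),10.38,0.00,143,8,245,16
M021,Histidine (3TMS),17.6,0.00,93,4.8,72.6,3.6
M024,Isoleucine (2TMS),10.19,0.00,59.5,2,55.5,3.4
M026,Leucine (2TMS),9.89,0.00,105,4,100,6
M027,Lysine (4TMS),17.63,0.00,80.1,11.3,140,14
M030,Methionine (2TMS),13.17,0.00,40.7,0.4,22.3,1.8
M031,Myo-inositol (6TMS),19.23,0.00,30.7,1.5,,
M032,Ornithine (4TMS),16.55,0.00,29,2.7,52.1,2.8
M034,Phenylalanine (2TMS),14.47,0.00,53.4,1.5,50.8,7
M035,Phosphoric acid (3TMS),9.87,0.00,275,47,,
M036,Proline (2TMS),10.27,0.00,158,9,177,9
M038,Pyruvic acid (1metho-oxim 1TMS),6.62,0.00,283,36,,
M040,Serine (3TMS),11.09,0.00,73.1,3.8,95.9,4.3
M042,Succinic acid (2TMS),10.49,0.00,25.6,0.7,,
M044,Threonine (3TMS),11.43,0.00,103,7,119,6
M047,Tryptophan (2TMS),20.23,0.00,69,2,,
M048,Tyrosine (3TMS),17.81,0.00,57.5,2.2,57.3,3
M050,Valine (2TMS),9.09,0.00,156,10,182,10
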