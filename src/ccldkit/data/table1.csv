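id,name,rt,rt_sd,quantifier,qualifier1,qualifier2,slope,intercept,r_squared,loq,levels
M001,4-Aminobutyric acid (3TMS),13.31,0.01,304,174,147,0.00428,-0.01677,0.997946326,5,
M002,Aconitic acid (3TMS),15.81,0.01,147,375,229,0.00939,-0.10858,0.971925122,5,
M003,Adenine (2TMS),17.12,0.01,264,279,192,0.0145,-0.1298,0.985093709,5,
M004,Alanine (2TMS),7.43,0.01,116,190,147,0.0181,-0.0537,0.998107977,5,
M005,Asparagine (3TMS),14.93,0.01,116,231,132,0.00296,-0.03480,0.969363443,5,
M006,Aspartic acid (3TMS),13.16,0.01,232,218,100,0.0148,-0.1094,0.990087236,5,
M007,Caffeine (0TMS),17.01,0.01,194,109,67,0.00655,-0.04092,0.992869316,5,
M008,Citric acid (4TMS),16.55,0.01,273,465,347,0.0186,-0.1197,0.993577885,5,
M009,Cysteine (3TMS),13.6,0.01,218,220,100,0.00555,-0.04003,0.991182834,5,
M010,Cytosine (3TMS),13.22,0.01,254,240,170,0.00398,-0.02034,0.995979412,5,
M011,Ergosterol (1TMS),27.96,0.01,211,364,129,0.00116,-0.01162,0.979552269,50,
M012,Fructose-syn (5TMS),17.07,0.01,307,217,103,0.00309,-0.00293,0.998573559,5,
M013,Fumaric acid (2TMS),10.99,0.01,245,147,73,0.0101,-0.0890,0.984258298,5,
M014,Glucose-syn (5TMS),17.33,0.01,319,205,160,0.00777,-0.04160,0.995802756,5,0;5;50;100;200;500;1000;1500
M015,Glutamic acid (3TMS),14.36,0.01,246,147,128,0.00846,-0.05905,0.991560137,5,
M016,Glutamine (3TMS),16.09,0.01,156,245,73,0.00282,-0.03872,0.952720346,5,
M017,Glycerol (3TMS),9.89,0.01,205,147,117,0.00465,-0.02928,0.989621885,5,
M018,Glycine (3TMS),10.38,0.01,174,248,73,0.0217,-0.0472,0.999309039,50,
M019,Glycolic acid (2TMS),7.04,0.01,205,177,147,0.00119,-0.01314,0.972607162,50,
M020,Guanine (3TMS),19.59,0.01,352,264,73,0.00705,-0.06942,0.980404182,5,
M021,Histidine (3TMS),17.61,0.01,154,254,0,0.0133,-0.1708,0.96381778,5,
M022,Inosine (4TMS),23.31,0.01,217,281,230,0.00624,-0.08974,0.948511774,5,
M023,Isocitric acid (4TMS),16.55,0.01,245,319,204,0.00604,-0.03097,0.996408844,5,
M024,Isoleucine (2TMS),10.19,0.01,158,232,218,0.0212,-0.0629,0.998183005,5,
M025,Lactose1 (8TMS),24.14,0.01,204,361,319,0.0159,-0.1570,0.98100185,5,
M026,Leucine (2TMS),9.89,0.01,158,232,73,0.0247,-0.0639,0.99895856,5,
M027,Lysine (4TMS),17.63,0.01,174,317,230,0.0142,-0.0658,0.997051812,5,
M028,Malic acid (3TMS),12.75,0.01,233,335,147,0.00342,-0.02041,0.993892629,5,
M029,Maltose2 (8TMS),24.7,0.01,361,204,103,0.00214,-0.02062,0.979669477,5,
M030,Methionine (2TMS),13.17,0.01,176,293,219,0.0129,-0.0779,0.994154978,5,
M031,Myo-inositol (6TMS),19.24,0.01,305,265,191,0.0153,-0.0500,0.998677671,5,
M032,Ornithine (4TMS),16.55,0.01,142,420,174,0.0219,-0.0493,0.998580314,5,
M033,Palmitic acid (1TMS),18.88,0.01,117,313,129,0.00928,-0.05299,0.992456268,5,
M034,Phenylalanine (2TMS),14.47,0.01,192,218,73,0.011,-0.0526,0.996722448,5,
M035,Phosphoric acid (3TMS),9.86,0.01,299,314,211,0.013,-0.1179,0.981330404,5,
M036,Proline (2TMS),10.27,0.01,142,216,73,0.0242,-0.1219,0.995436881,5,
M037,Putrescine (4TMS),15.72,0.01,174,214,200,0.043,-0.0501,0.999693324,5,
M038,Pyruvic acid (1metho-oxim 1TMS),6.64,0.01,174,115,89,0.000672,-0.00155,0.999376913,50,
M039,Raffinose (11TMS),28.81,0.01,361,437,217,0.0228,-0.1821,0.987840487,5,
M040,Serine (3TMS),11.09,0.01,204,278,73,0.0145,-0.0565,0.99774593,5,
M041,Stearic acid (1TMS),20.68,0.01,117,341,145,0.00862,-0.06043,0.98769425,5,
M042,Succinic acid (2TMS),10.49,0.01,147,129,73,0.0197,-0.0733,0.996924908,5,
M043,Sucrose (8TMS),23.75,0.01,361,437,217,0.0218,-0.1727,0.988630816,5,
M044,Threonine (3TMS),11.43,0.01,218,291,117,0.00732,-0.02761,0.997716556,5,
M045,Thymine (2TMS),11.64,0.01,255,147,113,0.0113,-0.0662,0.99383769,5,
M046,Trehalose (8TMS),24.55,0.01,191,217,103,0.0167,-0.0683,0.997932624,5,
M047,Tryptophan (2TMS),20.24,0.01,218,130,100,0.0121,-0.1471,0.970083386,5,
M048,Tyrosine (3TMS),17.81,0.01,218,280,179,0.0322,-0.1704,0.996105297,5,
M049,Uracil (2TMS),10.81,0.01,241,99,147,0.00851,-0.04013,0.99612372,5,
M050,Valine (2TMS),9.09,0.01,144,246,218,0.0202,-0.0626,0.99818831,5,
M051,Xanthine (3TMS),18.57,0.01,353,368,147,0.004,-0.03673,0.983502896,5,
M052,α-Ketoglutaric acid (1_metho-oxim 2TMS),13.84,0.01,198,147,89,0.000811,-0.007595,0.980432179,50,
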