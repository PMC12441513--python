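id,rt_min,name,formula,adduct,compound_class,theoretical_mz,measured_mz,error_ppm,ms2_fragments,plasma,cerebrum
P1,0.77,8-Epiloganic acid,C16H24O10,[M-H]-,terpenoids,375.1297,375.1296,-0.21,213.0770;169.0885;151.0760;125.0610,+,-
P2,1.33,Caffeic acid,C9H8O4,[M-H]-,phenolic acids,179.0350,179.0353,1.77,135.0458;89.0394,+,-
P3,1.67,p-Coumaric acid,C9H8O3,[M-H]-,phenolic acids,163.0401,163.0399,-1.27,119.0510;93.1455,+,-
P4,1.92,Protocatechuic acid,C7H6O4,[M-H]-,phenolic acids,153.0193,153.0190,-1.97,135.0091;109.0300;91.0192,+,-
P5,3.86,Ferulic acid,C10H10O4,[M+H]+,phenolic acids,195.0652,195.0652,0.06,177.0543;163.0392;145.0281;117.0334;89.0385,+,+
P6,4.54,Zedoalactone C,C15H22O4,[M+H]+,terpenoids,267.1591,267.1595,1.39,249.1497;231.1370;213.1273;203.1432;185.1320;147.1160;133.1010,+,+
P7,4.71,Chrysin 6-C-arabinoside 8-C-glucoside,C26H28O13,[M+H]+,flavonoids,549.1603,549.1612,1.62,495.1340;465.1200;363.0874,+,-
P8,5.40,"5,7-Dihydroxy-2-phenyl-6-[3,4,5-trihydroxy-6-(hydroxymethyl)oxan-2-YL]-8-(3,4,5-trihydroxyoxan-2-YL)chromen-4-one",C26H28O13,[M+H]+,flavonoids,549.1603,549.1598,-0.79,531.1546;483.1377,+,-
P9,5.46,Zedoalactone A,C15H22O4,[M+H]+,terpenoids,267.1591,267.1580,-4.17,249.1479;231.1374;213.1290;185.1377,+,-
P10,6.47,Hispidulin 7-glucuronide,C22H20O12,[M+H]+,flavonoids,477.1028,477.1050,4.74,301.0708;286.0495,+,-
P11,6.74,Isocorynoxeine,C22H26N2O4,[M+H]+,alkaloids,383.1965,383.1959,-1.70,267.1511;160.0758,+,-
P12,6.77,Corynoxeine,C22H26N2O4,[M+H]+,alkaloids,383.1965,383.1968,0.81,160.0751,+,-
P13,7.13,"3,4,5-Trihydroxy-6-[5-hydroxy-2-(4-hydroxy-3-methoxyphenyl)-3-methoxy-4-oxochromen-7-yl]oxyoxane-2-carboxylic acid",C23H22O13,[M-H]-,flavonoids,505.0988,505.0984,-0.70,329.0672;314.0440;299.0199,+,-
P14,7.18,"5,2',6'-Trihydroxy-7,8-dimethoxyflavone 2'-glucuronide",C23H22O13,[M-H]-,flavonoids,505.0988,505.0986,-0.36,329.0671;314.0435;299.0195,+,-
P15,7.25,Cynaroside,C21H20O11,[M-H]-,flavonoids,447.0933,447.0939,1.30,271.0608;256.0383,+,-
P16,7.33,Rhynchophylline,C22H28N2O4,[M+H]+,alkaloids,385.2122,385.2146,6.22,353.1868;269.1672;160.0763,+,-
P17,7.34,Baicalin,C21H18O11,[M-H]-,flavonoids,445.0776,445.0777,0.22,269.0461;251.0346;241.0511;223.0406;175.0250;169.0661,+,+
P18,7.59,"3,4,5-Trimethoxycinnamic acid",C12H14O5,[M+H]+,phenylpropanoids,239.0914,239.0914,-0.19,206.0570;193.0841;191.0338;178.0624;163.0391,+,-
P19,7.86,Viscidulin II,C17H14O7,[M+H]+,flavonoids,331.0812,331.0812,-0.06,316.0656;298.0504;270.0525;242.0575,+,-
P20,8.32,Glychionide A,C21H18O11,[M-H]-,flavonoids,445.0776,445.0783,1.59,269.0461;241.0506;225.0551;197.0608,+,-
P21,8.53,Chrysin-7-O-glucuronide,C21H18O10,[M-H]-,flavonoids,429.0827,429.0836,1.98,253.0509;175.0267;113.0245;99.0082;85.0304,+,-
P22,8.57,Oroxylin A glucuronide,C22H20O11,[M-H]-,flavonoids,459.0933,459.0930,-0.69,283.0618;268.0383,+,-
P23,8.64,DiosMetin 7-O-beta-D-glucuronide,C22H20O12,[M+H]+,flavonoids,477.1028,477.1040,2.60,301.0779;286.0511,+,+
P24,8.80,Norwogonin,C15H10O5,[M+H]+,flavonoids,271.0601,271.0611,3.85,253.0492;225.0533;169.0118;141.0676;123.0080,+,+
P25,8.86,Dihydrooroxylin A,C16H14O5,[M+H]+,flavonoids,287.0914,287.0917,1.03,183.0292;168.0050;140.0095;131.0487,+,-
P26,9.00,Oroxindin,C22H20O11,[M-H]-,flavonoids,459.0933,459.0934,0.19,283.0626;268.0384,+,+
P27,9.14,"1-Hydroxy-3,7-dimethoxyxanthone",C15H12O5,[M+H]+,xanthones,273.0758,273.0765,2.69,255.0747;227.0673,+,-
P28,9.15,Tectoridin,C22H22O11,[M-H]-,flavonoids,461.1089,461.1081,-1.83,285.0773;175.0253;165.9908;137.9956,+,-
P29,9.25,Geissoschizine methyl ether,C22H26N2O3,[M+H]+,alkaloids,367.2016,367.2023,1.79,335.1782;224.1286;170.0953;144.0794,+,-
P30,9.33,Curcumin C,C15H16O3,[M+H]+,terpenoids,245.1172,245.1167,-2.10,229.0466;199.0348;181.0748,+,-
P31,10.08,"5,2',6'-Trihydroxy-6,7,8-trimethoxyflavone",C18H16O8,[M+H]+,flavonoids,361.0918,361.0906,-3.41,346.0686;331.0447;313.0347,+,-
P32,10.10,Curdionolide B,C15H20O3,[M+H]+,terpenoids,249.1485,249.1484,-0.31,231.1378;213.1272;203.1422;185.1321;161.0991;147.0803,+,-
P33,10.18,Baicalein,C15H10O5,[M+H]+,flavonoids,271.0601,271.0605,1.33,253.0532;225.0542;169.0649;123.0074,+,+
P34,10.78,Curcolone,C15H18O3,[M+H]+,terpenoids,247.1329,247.1339,4.19,229.1234;211.1103;201.0803;183.1171;143.0845;129.0206,+,-
P35,11.69,Negletein,C16H12O5,[M+H]+,flavonoids,285.0758,285.0763,1.77,270.0540;168.0063;140.0105,+,-
P36,11.73,Curdione,C15H24O2,[M+H]+,terpenoids,237.1849,237.1851,0.94,219.1343;201.1609;175.1407;159.1173;145.1027,+,-
P37,12.31,beta-Asarone,C12H16O3,[M+H]+,phenylpropanoids,209.1172,209.1178,2.73,181.1217;179.1089;121.9462;91.0546,+,-
P38,12.32,Wogonin,C16H12O5,[M+H]+,flavonoids,285.0758,285.0765,2.71,270.0531;252.0428;242.0583;179.0492;151.0539,+,+
P39,12.61,Skullcapflavone I,C17H14O6,[M+H]+,flavonoids,315.0863,315.0868,1.50,300.0628;285.0397;282.0521;257.0438,+,+
P40,12.75,Methyl eugenol,C11H14O2,[M+H]+,phenylpropanoids,179.1067,179.1065,-0.62,151.0753;121.0622;107.0481;91.0536,+,+
P41,12.92,Oroxylin A,C16H12O5,[M+H]+,flavonoids,285.0758,285.0758,0.22,270.0523;168.0051,+,+
P42,13.86,Obtusifolin,C16H12O5,[M+H]+,anthraquinones,285.0758,285.0759,0.68,270.0510;253.0404;242.0579;225.0548;211.0752,+,-
P43,13.95,alpha-Asarone,C12H16O3,[M+H]+,phenylpropanoids,209.1172,209.1175,1.28,181.1204;179.1075;165.0722;135.1147;121.1031;91.0538,+,+
P44,14.32,Procurcumenol,C15H22O2,[M+H]+,terpenoids,235.1693,235.1692,-0.24,217.1569;189.1635;175.1105;161.0956;133.1003;119.0846,+,-
P45,15.82,Toralactone,C15H12O5,[M+H]+,naphthopyrones,273.0758,273.0760,1.08,255.0642;227.0700;212.0465;184.0515,+,+
P46,16.55,Oxyphyllanene B,C12H14O2,[M+H]+,terpenoids,191.1067,191.1069,1.29,173.0934;163.1087;145.0981;131.0888,+,+
P47,16.88,Saucernetin,C22H28O5,[M+H]+,phenylpropanoids,373.2010,373.2016,1.83,235.1309;217.1207;202.0976;179.1057;165.0887;151.0754,+,-
P48,19.05,Calamenene,C15H22,[M+H]+,terpenoids,203.1794,203.1797,1.39,203.1121;147.1136;133.1025;119.0916,+,-
P49,19.49,"4,7-Dihydroxy-3-butylphthalide",C12H14O4,[M+H]+,phthaleins,223.0965,223.0962,-1.30,207.0318;191.0009;149.0235,+,+
P50,20.44,Eremophilene,C15H24,[M+H]+,terpenoids,205.1951,205.1953,0.94,149.0234;135.1174;121.1006;107.0838;93.0698,+,+
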