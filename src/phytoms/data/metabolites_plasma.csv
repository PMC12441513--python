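id,rt_min,name,formula,adduct,compound_class,theoretical_mz,measured_mz,error_ppm,ms2_fragments,parent,chain
M1,0.73,Caffeic acid-2O,C9H8O2,[M-H]-,phenolic acids,147.0452,147.0454,1.50,145.0497;103.0576;89.0246,Caffeic acid,-O-O
M2,0.76,Ferulic acid+2H,C10H12O4,[M+H]+,phenolic acids,197.0808,197.0805,-1.77,179.0718;161.0596;151.0388;135.0446;133.0648;105.0692;91.0540,Ferulic acid,+2H
M3,0.82,Protocatechuic acid+SO3+CH3,C8H8O7S,[M-H]-,phenolic acids,246.9918,246.9918,-0.07,167.0354;152.0118;123.0453;108.0220,Protocatechuic acid,+SO3+CH2
M4,0.86,Caffeic acid+SO3+2H,C9H10O7S,[M-H]-,phenolic acids,261.0075,261.0074,-0.25,217.0182;181.0516;137.0614,Caffeic acid,+SO3+2H
M5,1.00,Caffeic acid+2H,C9H10O4,[M-H]-,phenolic acids,181.0506,181.0507,0.23,163.0408;135.0457;119.0507,Caffeic acid,+2H
M6,1.01,Protocatechuic acid-CO2+SO3,C6H6O5S,[M-H]-,phenolic acids,188.9863,188.9865,1.18,109.0310;91.0192,Protocatechuic acid,-CO2+SO3
M7,1.25,Ferulic acid-CH2,C9H8O4,[M+H]+,phenolic acids,181.0495,181.0501,3.08,163.0391;145.0274;141.0728;135.0449;117.0344;105.0701;89.0382,Ferulic acid,-CH2
M8,1.25,Caffeic acid+C6H8O6,C15H16O10,[M-H]-,phenolic acids,355.0671,355.0675,1.31,179.0358;135.0457,Caffeic acid,+C6H8O6
M9,1.35,Caffeic acid+SO3,C9H8O7S,[M-H]-,phenolic acids,258.9918,258.9924,2.45,179.0354;135.0456,Caffeic acid,+SO3
M10,1.39,Caffeic acid+CH2,C10H10O4,[M-H]-,phenolic acids,193.0506,193.0509,1.15,178.0255;134.0379,Caffeic acid,+CH2
M11,1.42,Ferulic acid+SO3,C10H10O7S,[M-H]-,phenolic acids,273.0075,273.0073,-0.45,193.0512;178.0279;149.0615;134.0380,Ferulic acid,+SO3
M12,1.49,Caffeic acid+SO3+CH2,C10H10O7S,[M-H]-,phenolic acids,273.0075,273.0073,-0.54,193.0512;178.0274;149.0609;134.0377,Caffeic acid,+SO3+CH2
M13,1.62,Caffeic acid-O,C9H8O3,[M-H]-,phenolic acids,163.0401,163.0399,-0.90,145.8898;119.0507,Caffeic acid,-O
M14,1.67,Ferulic acid-CH2-O,C9H8O3,[M-H]-,phenolic acids,163.0401,163.0399,-1.27,119.0510;93.1455,Ferulic acid,-CH2-O
M15,1.67,Caffeic acid+SO3-O,C9H8O6S,[M-H]-,phenolic acids,242.9969,242.9965,-1.60,163.0410;119.0508,Caffeic acid,+SO3-O
M16,1.93,Ferulic acid+C6H8O6,C16H18O10,[M-H]-,phenolic acids,369.0827,369.0820,-2.08,193.0510;178.0271;134.0377,Ferulic acid,+C6H8O6
M17,2.15,Zedoalactone C+2H,C15H24O4,[M+H]+,terpenoids,269.1747,269.1735,-4.63,251.1648;233.1556;215.1459;203.1461,Zedoalactone C,+2H
M18,4.08,Ferulic acid+CH2+2H,C11H14O4,[M+H]+,phenolic acids,211.0965,211.0964,-0.62,181.1248;179.0670;149.0248;131.0855;115.0516;105.0738;91.0540,Ferulic acid,+CH2+2H
M19,4.45,Baicalein-O+2H,C15H12O4,[M+H]+,flavonoids,257.0808,257.0801,-2.81,163.0395;151.1130;135.0441;123.0439,Baicalein,-O+2H
M20,6.09,Oroxindin+O,C22H20O12,[M+H]+,flavonoids,477.1028,477.1024,-0.75,301.0705,Oroxindin,+O
M21,6.11,Baicalin+C6H8O6,C27H26O17,[M-H]-,flavonoids,621.1097,621.1095,-0.37,445.0774;269.0457,Baicalin,+C6H8O6
M22,6.12,Norwogonin+C6H8O6,C21H18O11,[M-H]-,flavonoids,445.0776,445.0755,-4.85,269.0455,Norwogonin,+C6H8O6
M23,6.16,Glychionide A+C6H8O6,C27H26O17,[M-H]-,flavonoids,621.1097,621.1104,1.05,445.0779;269.0459,Glychionide A,+C6H8O6
M24,6.19,Baicalin+2O+2H,C21H20O13,[M+H]+,flavonoids,481.0977,481.0975,-0.27,305.0663;290.0445,Baicalin,+O+O+2H
M25,6.37,Oroxindin+C6H8O6,C28H28O17,[M+H]+,flavonoids,637.1399,637.1416,2.54,461.1085;285.0757,Oroxindin,+C6H8O6
M26,6.44,Baicalin+C6H8O6+CH2,C28H28O17,[M-H]-,flavonoids,635.1254,635.1253,-0.17,459.0914;283.0619;268.0382,Baicalin,+C6H8O6+CH2
M27,6.49,Ferulic acid-O+2H,C10H12O3,[M+H]+,phenolic acids,181.0859,181.0866,3.62,151.0371;137.0577;123.0797;107.0866;105.0356;89.0392,Ferulic acid,-O+2H
M28,6.77,Dihydrooroxylin A+C6H8O6,C22H22O11,[M-H]-,flavonoids,461.1089,461.1096,1.41,285.0786;270.0537;252.0435,Dihydrooroxylin A,+C6H8O6
M29,6.79,DiosMetin 7-O-beta-D-glucuronide+C6H8O6,C28H28O18,[M+H]+,flavonoids,653.1348,653.1369,3.20,477.1042;301.0715,DiosMetin 7-O-beta-D-glucuronide,+C6H8O6
M30,7.25,Tectoridin-CH2,C21H20O11,[M-H]-,flavonoids,447.0933,447.0939,1.30,271.0608;256.0383,Tectoridin,-CH2
M31,7.33,Baicalin+CH2+O,C22H20O12,[M-H]-,flavonoids,475.0882,475.0879,-0.72,299.0570;284.0351,Baicalin,+CH2+O
M32,7.95,Skullcapflavone I+C6H8O6,C23H22O12,[M+H]+,flavonoids,491.1184,491.1209,5.17,315.0875;300.0621;285.0344,Skullcapflavone I,+C6H8O6
M33,8.02,Wogonin+C6H8O6,C22H20O11,[M-H]-,flavonoids,459.0933,459.0938,1.04,283.0613;268.0382,Wogonin,+C6H8O6
M34,8.06,Baicalin+CH2,C22H20O11,[M-H]-,flavonoids,459.0933,459.0930,-0.66,283.0620;268.0386,Baicalin,+CH2
M35,8.24,Glychionide A+CH2,C22H20O11,[M-H]-,flavonoids,459.0933,459.0924,-1.91,283.0615;268.0380;240.0427,Glychionide A,+CH2
M36,8.45,Glychionide A-C6H8O6-O,C15H10O4,[M+H]+,flavonoids,255.0652,255.0654,0.99,199.0734;181.1005;153.0183,Glychionide A,-C6H8O6-O
M37,8.50,Glychionide A-O,C21H18O10,[M-H]-,flavonoids,429.0827,429.0811,-3.71,253.0512,Glychionide A,-O
M38,8.64,Baicalein+CH2+O,C16H12O6,[M+H]+,flavonoids,301.0707,301.0715,2.66,286.0472;183.9997;155.9957;127.0066,Baicalein,+CH2+O
M39,8.68,Baicalein+2H,C15H12O5,[M+H]+,flavonoids,273.0758,273.0749,-3.06,229.0489;168.8711,Baicalein,+2H
M40,8.69,Viscidulin II+CH2,C18H16O7,[M+H]+,flavonoids,345.0969,345.0965,-1.16,330.0717;312.0627;284.0689;266.0647,Viscidulin II,+CH2
M41,8.71,Chrysin-7-O-glucuronide-C6H8O6+SO3,C15H10O7S,[M-H]-,flavonoids,333.0075,333.0088,3.95,253.0515;225.0562,Chrysin-7-O-glucuronide,-C6H8O6+SO3
M42,9.03,Norwogonin-O,C15H10O4,[M+H]+,flavonoids,255.0652,255.0659,2.72,227.0705;209.0576;199.0745;181.0635;153.0697,Norwogonin,-O
M43,9.06,DiosMetin 7-O-beta-D-glucuronide-O,C22H20O11,[M-H]-,flavonoids,459.0933,459.0934,0.24,283.0620;268.0387;175.0253,DiosMetin 7-O-beta-D-glucuronide,-O
M44,9.12,Baicalin-O,C21H18O10,[M-H]-,flavonoids,429.0827,429.0841,3.17,253.0509,Baicalin,-O
M45,9.20,Viscidulin II-O,C17H14O6,[M+H]+,flavonoids,315.0863,315.0861,-0.53,300.0435;285.0328;269.0952,Viscidulin II,-O
M46,9.21,Oroxindin+CH2+O,C23H22O12,[M+H]+,flavonoids,491.1184,491.1181,-0.70,315.0863;300.0624;285.0403,Oroxindin,+CH2+O
M47,9.48,Methyl eugenol-2CH2,C9H10O2,[M+H]+,phenylpropanoids,151.0754,151.0747,-4.19,107.0857;91.0542,Methyl eugenol,-CH2-CH2
M48,9.57,DiosMetin 7-O-beta-D-glucuronide+CH2,C23H22O12,[M+H]+,flavonoids,491.1184,491.1193,1.83,315.0871;300.0621,DiosMetin 7-O-beta-D-glucuronide,+CH2
M49,9.81,Oroxylin A+SO3,C16H12O8S,[M-H]-,flavonoids,363.0180,363.0186,1.57,283.0615;268.0381,Oroxylin A,+SO3
M50,9.85,Wogonin+SO3,C16H12O8S,[M-H]-,flavonoids,363.0180,363.0184,1.17,283.0620;268.0386,Wogonin,+SO3
M51,10.27,Wogonin+O,C16H12O6,[M+H]+,flavonoids,301.0707,301.0713,2.27,286.0496;255.1266;145.0174;127.0064,Wogonin,+O
M52,10.76,beta-Asarone-2CH2,C10H12O3,[M+H]+,phenylpropanoids,181.0859,181.0864,2.71,139.0753;135.0810;107.0866,beta-Asarone,-CH2-CH2
M53,11.09,Methyl eugenol-CH2,C10H12O2,[M+H]+,phenylpropanoids,165.0910,165.0912,1.11,137.0958;121.0648;119.0853;107.0492;91.0543,Methyl eugenol,-CH2
M54,11.63,beta-Asarone-CH2,C11H14O3,[M+H]+,phenylpropanoids,195.1016,195.1022,3.07,163.0390;133.0315;121.1020;91.0529,beta-Asarone,-CH2
M55,11.88,alpha-Asarone-2CH2,C10H12O3,[M+H]+,phenylpropanoids,181.0859,181.0862,1.53,139.0732;135.0797;107.0847,alpha-Asarone,-CH2-CH2
M56,12.42,Oroxylin A+O,C16H12O6,[M+H]+,flavonoids,301.0707,301.0704,-0.87,283.0598;268.0353;240.0409;227.0692,Oroxylin A,+O
M57,12.53,Wogonin+2H,C16H14O5,[M+H]+,flavonoids,287.0914,287.0920,2.23,183.0283;175.0145;168.0052;159.0230;131.0498,Wogonin,+2H
M58,14.02,Methyl eugenol+2H,C11H16O2,[M+H]+,phenylpropanoids,181.1223,181.1226,1.66,123.0801;91.0548,Methyl eugenol,+2H
M59,14.04,Dihydrooroxylin A+CH2,C17H16O5,[M+H]+,flavonoids,301.1071,301.1072,0.59,286.9927;283.0514;255.1261,Dihydrooroxylin A,+CH2
M60,19.96,Obtusifolin+CH2,C17H14O5,[M+H]+,anthraquinones,299.0914,299.0914,0.16,283.0485;269.0814;250.9921;226.0585,Obtusifolin,+CH2
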