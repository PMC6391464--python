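table,polarity,feature,measured_mz,rt_s,formula,ion,isotope,identity
1,pos,M216T214,216.1383,214,C14H17NO,M+H,,alpha-PBP artifact (dehydro-)
1,pos,M217T214,217.1415,214,C14H17NO,M+H,13C1,alpha-PBP artifact (dehydro-) 13C-isotope
1,pos,M218T216,218.1540,216,C14H19NO,M+H,,alpha-PBP
1,pos,M219T216,219.1572,216,C14H19NO,M+H,13C1,alpha-PBP 13C-isotope
1,pos,M220T226,220.1695,226,C14H21NO,M+H,,alpha-PBP-M (dihydro-)
1,pos,M221T226,221.1728,226,C14H21NO,M+H,13C1,alpha-PBP-M (dihydro-) 13C-isotope
1,pos,M232T343,232.1331,343,C14H17NO2,M+H,,alpha-PBP-M (oxo-)
1,pos,M236T214,236.1643,214,C14H21NO2,M+H,,alpha-PBP-M (dihydro-HO-)
1,pos,M237T214,237.1676,214,C14H21NO2,M+H,13C1,alpha-PBP-M (dihydro-HO-) 13C-isotope
1,pos,M250T215,250.1435,215,C14H19NO3,M+H,,alpha-PBP-M (di-HO-)
2,pos,M215T328,215.1542,328,C14H18N2,M+H,,alpha-PBP impurity (dehydro-) artifact (imido-)
2,pos,M216T114,216.1383,114,C14H17NO,M+H,,alpha-PBP impurity (dehydro-)
2,pos,M216T347,216.1383,347,C14H17NO,M+H,,alpha-PBP artifact (dehydro-)
2,pos,M218T351,218.1541,351,C14H19NO,M+H,,alpha-PBP
2,pos,M219T350,219.1572,350,C14H19NO,M+H,13C1,alpha-PBP 13C-isotope
2,pos,M220T355,220.1694,355,C14H21NO,M+H,,alpha-PBP-M (dihydro-)
2,pos,M221T355,221.1726,355,C14H21NO,M+H,13C1,alpha-PBP-M (dihydro-) 13C-isotope
2,pos,M234T114,234.1488,114,C14H19NO2,M+H,,alpha-PBP-M (dihydro-oxo-)
2,pos,M236T367,236.1643,367,C14H21NO2,M+H,,alpha-PBP-M (dihydro-HO-)
2,pos,M237T367,237.1677,367,C14H21NO2,M+H,13C1,alpha-PBP-M (dihydro-HO-) 13C-isotope
2,pos,M243T80,243.1492,80,C15H18N2O,M+H,,alpha-PBP impurity (dehydro-) artifact (cyano-)
2,pos,M250T412,250.1436,412,C14H19NO3,M+H,,alpha-PBP-M (di-HO-)
2,pos,M471T350,471.2771,350,C14H19NO,2M+2H+Cl,,alpha-PBP adduct [2M+2H+Cl]+
2,pos,M472T350,472.2805,350,C14H19NO,2M+2H+Cl,13C1,alpha-PBP adduct [2M+2H+Cl]+ 13C-isotope
2,pos,M473T350,473.2742,350,C14H19NO,2M+2H+Cl,37Cl1,alpha-PBP adduct [2M+2H+Cl]+ M+2 isotopologue (printed identity says 13C2 but the printed mass matches the 37Cl isotopologue)
3,pos,M206T296,206.1538,296,C13H19NO,M+H,,alpha-PEP-M (N-N-dealkyl-)
3,pos,M258T312,258.1852,312,C17H23NO,M+H,,alpha-PEP artifact (dehydro-)
3,pos,M260T296,260.2008,296,C17H25NO,M+H,,alpha-PEP conformer 2
3,pos,M260T312,260.2009,312,C17H25NO,M+H,,alpha-PEP conformer 1
3,pos,M261T312,261.2042,312,C17H25NO,M+H,13C1,alpha-PEP 13C-isotope
3,pos,M262T312,262.2073,312,C17H25NO,M+H,13C2,alpha-PEP 13C2-isotope
3,pos,M262T325,262.2165,325,C17H27NO,M+H,,alpha-PEP-M (dihydro-)
3,pos,M263T324,263.2197,324,C17H27NO,M+H,13C1,alpha-PEP-M (dihydro-) 13C-isotope
3,pos,M274T425,274.1799,425,C17H23NO2,M+H,,alpha-PEP-M (oxo-)
3,pos,M276T229,276.1958,229,C17H25NO2,M+H,,alpha-PEP-M (HO-) isomer 2
3,pos,M277T229,277.1990,229,C17H25NO2,M+H,13C1,alpha-PEP-M (HO-) isomer 2 13C-isotope
3,pos,M278T307,278.2113,307,C17H27NO2,M+H,,alpha-PEP-M (dihydro-HO-)
3,pos,M292T310,292.1904,310,C17H25NO3,M+H,,alpha-PEP-M (di-HO-)
4,pos,M246T254,246.1849,254,C16H23NO,M+H,,alpha-PHP impurity
4,pos,M257T216,257.2008,216,C17H24N2,M+H,,alpha-PEP impurity (dehydro-) artifact (imido-)
4,pos,M258T198,258.1849,198,C17H23NO,M+H,,alpha-PEP impurity (dehydro-)
4,pos,M258T216,258.2042,216,C17H24N2,M+H,13C1,alpha-PEP impurity (dehydro-) artifact (imido-) 13C-isotope
4,pos,M258T249,258.1849,249,C17H23NO,M+H,,alpha-PEP artifact (dehydro-)
4,pos,M260T243,260.2007,243,C17H25NO,M+H,,alpha-PEP conformer 1
4,pos,M260T276,260.2005,276,C17H25NO,M+H,,alpha-PEP conformer 2
4,pos,M261T243,261.2040,243,C17H25NO,M+H,13C1,alpha-PEP 13C-isotope
4,pos,M262T243,262.2071,243,C17H25NO,M+H,13C2,alpha-PEP 13C2-isotope
4,pos,M262T271,262.2162,271,C17H27NO,M+H,,alpha-PEP-M (dihydro-) diastereomer 1
4,pos,M262T282,262.2162,282,C17H27NO,M+H,,alpha-PEP-M (dihydro-) diastereomer 2
4,pos,M263T270,263.2195,270,C17H27NO,M+H,13C1,alpha-PEP-M (dihydro-) diastereomer 1 13C-isotope
4,pos,M263T282,263.2195,282,C17H27NO,M+H,13C1,alpha-PEP-M (dihydro-) diastereomer 2 13C-isotope
4,pos,M272T87,272.1641,87,C17H21NO2,M+H,,alpha-PEP-M (oxo-HO-) isomer 2 artifact (water loss)
4,pos,M276T90,276.1954,90,C17H25NO2,M+H,,alpha-PEP-M (dihydro-oxo-)
4,pos,M276T269,276.1954,269,C17H25NO2,M+H,,alpha-PEP-M (HO-) isomer 1
4,pos,M276T316,276.1954,316,C17H25NO2,M+H,,alpha-PEP-M (HO-) isomer 2
4,pos,M277T269,277.1987,269,C17H25NO2,M+H,13C1,alpha-PEP-M (HO-) isomer 1 13C-isotope
4,pos,M277T316,277.1987,316,C17H25NO2,M+H,13C1,alpha-PEP-M (HO-) isomer 2 13C-isotope
4,pos,M278T291,278.2110,291,C17H27NO2,M+H,,alpha-PEP-M (dihydro-HO-)
4,pos,M285T74,285.1957,74,C18H24N2O,M+H,,alpha-PEP impurity (dehydro-) artifact (cyano-)
4,pos,M290T93,290.1746,93,C17H23NO3,M+H,,alpha-PEP-M (oxo-HO-) isomer 1
4,pos,M292T321,292.1901,321,C17H25NO3,M+H,,alpha-PEP-M (di-HO-)
4,neg,M327T82,327.2323,82,C22H32O2,M-H,,docosahexaenoic acid
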