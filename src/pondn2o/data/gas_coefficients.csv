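gas,set,coefficient,value,source
N2O,solubility_k0,A1,-62.7062,weiss_price_1980
N2O,solubility_k0,A2,97.3066,weiss_price_1980
N2O,solubility_k0,A3,24.1406,weiss_price_1980
N2O,solubility_k0,B1,-0.058420,weiss_price_1980
N2O,solubility_k0,B2,0.033193,weiss_price_1980
N2O,solubility_k0,B3,-0.0051313,weiss_price_1980
CH4,solubility_bunsen,A1,-67.1962,yamamoto_1976
CH4,solubility_bunsen,A2,99.1624,yamamoto_1976
CH4,solubility_bunsen,A3,27.9015,yamamoto_1976
CH4,solubility_bunsen,B1,-0.072909,yamamoto_1976
CH4,solubility_bunsen,B2,0.041674,yamamoto_1976
CH4,solubility_bunsen,B3,-0.0064603,yamamoto_1976
N2O,schmidt_freshwater,A,2055.6,wanninkhof_1992
N2O,schmidt_freshwater,B,-137.11,wanninkhof_1992
N2O,schmidt_freshwater,C,4.3173,wanninkhof_1992
N2O,schmidt_freshwater,D,-0.054350,wanninkhof_1992
CH4,schmidt_freshwater,A,1897.8,wanninkhof_1992
CH4,schmidt_freshwater,B,-114.28,wanninkhof_1992
CH4,schmidt_freshwater,C,3.2902,wanninkhof_1992
CH4,schmidt_freshwater,D,-0.039061,wanninkhof_1992
N2O,schmidt_seawater,A,2301.1,wanninkhof_1992
N2O,schmidt_seawater,B,-151.1,wanninkhof_1992
N2O,schmidt_seawater,C,4.7364,wanninkhof_1992
N2O,schmidt_seawater,D,-0.059431,wanninkhof_1992
CH4,schmidt_seawater,A,2039.2,wanninkhof_1992
CH4,schmidt_seawater,B,-120.31,wanninkhof_1992
CH4,schmidt_seawater,C,3.4209,wanninkhof_1992
CH4,schmidt_seawater,D,-0.040437,wanninkhof_1992
H2O,vapor_pressure,A,24.4543,weiss_price_1980
H2O,vapor_pressure,B,-67.4509,weiss_price_1980
H2O,vapor_pressure,C,-4.8489,weiss_price_1980
H2O,vapor_pressure,D,-0.000544,weiss_price_1980
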