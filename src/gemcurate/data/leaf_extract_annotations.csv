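compound,formula,printed_mass,rt_min,mass_error_ppm,adduct,polarity,confidence_level,area_percent,compound_class
Neurine,C5H13NO,103.0997,1.09,7,[M+H]+,+,3,0.86,Alkaloids and derivatives
Cannabisativine,C21H39N3O3,381.2991,5.66,4,[M+H]+,+,3,0.31,Alkaloids and derivatives
Phenylacetaldehyde,C8H8O,120.0575,3.33,5,[M+H-H2O]+,+,3,0.43,Benzenoids
Methylstyrene,C9H10,118.0783,14.59,6,[M+H]+,+,3,2.31,Benzenoids
Phenylpropanal,C9H10O,134.0732,14.59,5,[M+H]+,+,3,0.65,Benzenoids
Cyclointegrin,C21H20O6,368.1260,14.87,0,[M-H]-,-,3,0.61,Benzenoids
Cresol,C7H8O,108.0575,16.46,4,[M-H]-,-,3,1.25,Benzenoids
Levomethadyl Acetate,C23H31NO2,353.2355,16.99,6,[M+H]+,+,3,1.17,Benzenoids
Hydroxy-(pentadecatrienyl)benzoic acid,C22H30O3,342.2195,17.33,4,[M-H]-,-,3,0.30,Benzenoids
Corchoionol C glucoside,C19H30O8,386.1941,6.17,0,[M-H]-,-,2,0.46,Fatty Acyls
Trihydroxy-octadecadienoic acid,C18H32O5,328.2250,11.14,1,[M-H]-,-,2,0.42,Fatty Acyls
Octadecatetraenoic acid,C18H28O2,276.2089,15.23,1,[M-H]-,-,3,0.37,Fatty Acyls
Hydroxyoctadecatrienic acid,C18H30O3,294.2195,15.32,1,[M-H-H2O]-,-,3,1.40,Fatty Acyls
Palmitoleic acid,C16H30O2,254.2246,16.89,5,[M+H-H2O]+,+,3,0.79,Fatty Acyls
Gingerglycolipid A,C33H56O14,676.3670,14.50,1,[M-H]-,-/+,3,0.72,Glycerolipids
LPC 16:0,C24H50NO7P,495.3325,15.94,6,[M+H]+,+,2,0.43,Glycerophospholipids
LPC 8:0,C16H32NO8P,397.1866,16.21,2,[M+HCOOH-H]-,-,3,0.98,Glycerophospholipids
PI 41:7,C50H83O13P,922.5571,16.03,7,[M+HCOOH-H]-,-,3,0.39,Glycerophospholipids
PS O-37:2,C43H82NO9P,787.5727,16.51,2,[M+Na]+,+,3,0.39,Glycerophospholipids
PE 38:5,C43H76NO8P,765.5309,16.56,3,[M+H]+,+,3,0.49,Glycerophospholipids
PA O-36:4,C39H71O7P,682.4937,16.59,4,[M+Na]+,+,3,0.72,Glycerophospholipids
PA O-36:6,C39H67O7P,678.4624,16.64,6,[M+H-H2O]+,+,3,0.78,Glycerophospholipids
LPG 16:0,C22H45O9P,484.2801,16.96,10,[M+H]+,+,3,0.62,Glycerophospholipids
PG 25:3;O3,C31H55O13P,666.3380,16.67,9,[M+H]+,+,3,0.37,Glycerophospholipids
Alloisoleucine,C6H13NO2,131.0946,1.89,3,[M-H]-,-,3,0.35,Organic acids and derivatives
Dilauryl 3.3'-thiodipropionate,C30H58O4S2,546.3777,16.74,3,[M+H-H2O]+,+,3,0.60,Organic acids and derivatives
Gly-Tyr-Tyr-Pro-Thr,C29H38N5O9,600.2670,16.99,6,[M+Na]+,+,3,0.61,Organic acids and derivatives
delta-9-THC,C21H30O2,314.2246,15.76,5,[M+H]+,+,2,3.71,Organoheterocyclic compounds
delta-9-THC,C21H30O2,314.2246,16.47,5,[M+H]+,+,2,5.67,Organoheterocyclic compounds
Geranylhydroquinone,C16H22O2,246.1620,16.46,0,[M-H-H2O]-,-,3,13.35,Organoheterocyclic compounds
methyl-(4-methylpent-3-en-1-yl)-2H-chromen-ol,C16H20O2,244.1463,16.46,2,[M-H]-,-,3,3.10,Organoheterocyclic compounds
Dimethyl-prenylchromene -carboxylic acid,C17H20O3,272.1413,16.46,2,[M-H]-,-,2,2.09,Organoheterocyclic compounds
Phaeophorbide b,C35H34N4O6,606.2478,17.19,4,[M+H]+,+,3,0.55,Organoheterocyclic compounds
Tetradecylamine,C14H31N,213.2457,14.11,6,[M+H]+,+,3,0.79,Organonitrogen compounds
Palmitoleoyl-EA,C18H35NO2,297.2668,16.31,8,[M+Na]+,+,3,0.34,Organonitrogen compounds
Trehalose,C12H22O11,342.1162,1.13,0,[M-H]-,-,2,0.93,Organooxygen compounds
Kobusone,C14H22O2,222.1620,15.83,3,[M-H]-,-,2,0.51,Organooxygen compounds
Methyl-pentenone,C6H10O,98.0732,16.46,1,[M-H-H2O]-,-,3,0.75,Organooxygen compounds
Methylpicraquassioside A,C19H24O10,412.1369,16.61,10,[M+Cl]-,-,3,0.68,Organooxygen compounds
(carboxymethoxy)- trihydroxyoxane-carboxylic acid,C8H12O9,252.0481,16.81,1,[M+HCOOH-H]-,-,3,0.61,Organooxygen compounds
Epoxyprogesterone,C21H28O3,328.2038,17.39,2,[M-H]-,-,3,0.59,Organooxygen compounds
Clausarinol,C24H30O6,414.2042,14.59,4,[M+H]+,+,3,4.45,Phenylpropanoids
6-{[2-(dihydroxyphenyl)-3-(dimethylocta-dien-yl)-hydroxy-(3-methylbut-2-en-yl)-4-oxo-4H-chromen-6-yl]oxy}-trihydroxyoxane-carboxylic acid,C36H42O12,666.2676,15.58,1,[M-H]-,-,3,0.33,Phenylpropanoids
Nevskin,C24H32O5,400.2250,16.27,1,[M+H]+,+,3,0.60,Phenylpropanoids
Methoxy-abietatrienolide,C21H28O3,328.2038,16.48,1,[M-H]-,-,3,0.47,Phenylpropanoids
Nordihydroguaiaretic acid,C18H22O4,302.1518,16.65,2,[M-H]-,-,3,0.32,Phenylpropanoids
Pipercitine,C23H43NO,349.3345,15.91,5,[M+H-H2O]+,+,3,4.88,Piperidines
Cannabidiolic acid,C22H30O4,358.2144,16.26,4,[M+H-H2O]+,+,3,7.15,Polyketides
Cannflavin A,C26H28O6,436.1886,16.34,4,[M+H]+,+,3,1.84,Polyketides
Betavulgarin,C17H12O6,312.0634,16.34,3,[M+H]+,+,3,1.18,Polyketides
Cannflavin A,C26H28O6,436.1886,16.41,4,[M+H]+,-,3,2.55,Polyketides
Chlorophorin,C24H28O4,380.1988,16.46,8,[M+HCOOH-H]-,-,3,0.53,Polyketides
Quercetol B,C23H28O4,368.1988,16.51,3,[M-H]-,-,3,0.67,Polyketides
Icariside B8,C19H32O8,388.2097,6.19,2,[M-H]-,-,3,0.34,Prenol lipids
Capsularone,C27H38O8,490.2567,11.77,1,[M+HCOOH-H]-,-,3,0.66,Prenol lipids
Diterpenoid EF-D,C27H38O7,474.2618,13.60,1,[M+HCOOH-H]-,-,3,1.13,Prenol lipids
Persicachrome,C25H36O3,384.2664,14.33,4,[M+H-H2O]+,+,3,0.72,Prenol lipids
Nigellic acid,C15H20O5,280.1311,14.59,3,[M+H]+,+,3,0.37,Prenol lipids
Yucalexin,C20H26O4,330.1831,15.67,4,[M-H]-,-,3,0.49,Prenol lipids
2-(Hydroxy-methylphenyl)-5-methyl-4-hexen-3-one,C14H18O2,218.1307,15.67,7,[M-H]-,-,3,0.38,Prenol lipids
Tintinnadiol,C21H32O3,332.2351,15.76,1,[M-H]-,-,3,1.21,Prenol lipids
Hydroxymethylphenyl pentanone,C12H16O2,192.1150,15.76,5,[M+H]+,+,2,0.32,Prenol lipids
Dimethylrosmanol,C22H30O5,374.2093,16.00,1,[M-H]-,-,2,0.64,Prenol lipids
hydroxy-methoxy-(3-methylbut-2-en-1-yl)benzoic acid,C13H16O4,236.1049,16.26,4,[M+H-H2O]+,+,2,0.77,Prenol lipids
Lucidone B,C24H32O5,400.2250,16.28,1,[M-H]-,-,2,1.53,Prenol lipids
Pentylresorcinol,C11H16O2,180.1150,16.46,3,[M-H]-,-,2,2.06,Prenol lipids
Hyperforin,C35H52O4,536.3866,16.46,1,[M-H-H2O]-,-,3,0.30,Prenol lipids
Hydroxymethylphenyl)pentanone,C12H16O2,192.1150,16.47,5,[M+H]+,+/-,2,0.76,Prenol lipids
Curzerenone,C15H18O2,230.1307,16.48,3,[M-H]-,-,3,0.54,Prenol lipids
Geranyl benzoate,C17H22O2,258.1620,16.49,6,[M+H]+,+,3,0.33,Prenol lipids
Hydroxy- Caroten-3'-one,C40H54O,550.4175,16.71,9,[M+Na]+,+,3,0.73,Prenol lipids
Trimethyl-pentadecatrien-2-one,C18H30O,262.2297,17.16,6,[M+H]+,+,2,0.82,Prenol lipids
Grifolin,C22H32O2,328.2402,17.66,3,[M-H]-,-,3,0.32,Prenol lipids
Glyceryl lactopalmitate,C20H16N6O2S,404.1055,16.23,8,[M+HCOOH-H]-,-,3,1.38,Pyrazoles
Pregnadienedione,C21H28O2,312.2089,16.48,0,[M-H]-,-,3,2.24,Steroids and steroid derivatives
Neriantogenin,C23H32O4,372.2301,17.66,2,[M-H]-,-,3,2.89,Steroids and steroid derivatives
Rhodexin A,C29H44O9,536.2985,15.43,1,[M+H]+,+,3,0.45,Sterol Lipids
ST 27:0;O7,C27H48O7,484.3400,16.77,4,[M+H]+,+,3,0.35,Sterol Lipids
Dihomocholic acid,C26H44O5,436.3189,17.30,8,[M+Na]+,+,3,0.53,Sterol Lipids
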