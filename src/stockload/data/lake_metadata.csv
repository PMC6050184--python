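lake_code,area_ha,n_sampled,region,latitude,longitude,altitude,stocked
CA,746,17,Abitibi-Temiscamingue,46.54,-78.31,329,False
HA,39,36,Abitibi-Temiscamingue,48.47,-78.70,363,False
MG,622,19,Abitibi-Temiscamingue,46.53,-78.39,253,False
KI,30044,17,Abitibi-Temiscamingue,46.91,-78.99,269,True
PA,109,30,Outaouais,46.14,-76.20,252,True
CE,793,22,Outaouais,46.30,-76.11,181,True
AC,673,28,Outaouais,46.25,-77.10,283,True
CY,725,41,Outaouais,46.12,-76.27,194,True
BS,1437,30,Outaouais,46.22,-76.05,164,True
MI,4973,34,Outaouais,46.19,-75.81,159,True
BO,531,17,Laurentides,47.08,-75.85,299,False
MA,919,18,Laurentides,47.03,-75.80,329,False
TU,352,34,Laurentides,47.44,-74.85,436,False
GR,137,19,Laurentides,46.65,-74.56,485,True
PM,357,26,Laurentides,46.39,-75.29,317,True
TZ,958,24,Laurentides,46.25,-74.64,226,True
CR,1267,15,Laurentides,46.28,-75.50,209,True
PB,5475,17,Laurentides,45.97,-75.74,198,True
AL,40663,15,Nord-du-Quebec,50.90,-73.29,390,False
OF,5110,29,Nord-du-Quebec,54.55,-72.43,431,False
WA,8184,25,Nord-du-Quebec,50.15,-73.99,463,False
ES,743,32,Bas-St-Laurent,47.19,-69.56,321,True
PO,894,10,Bas-St-Laurent,47.49,-69.27,207,True
MZ,1864,23,Bas-St-Laurent,48.32,-67.80,271,True
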