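site,analyte,mean_ng_g_lipid,sd,n,bank,year
T02,DDTs,14832,,1,west,2013
T03,DDTs,1304,,1,west,2013
T01,DDTs,1280,,1,east,2013
Morrison St Bridge 2005,DDTs,1006,,1,east,2005
Morrison St Bridge 2013,DDTs,416,,1,west,2013
Campbell Slough,DDTs,1062,,1,downstream,
Ryan Island,DDTs,1018,,1,downstream,
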