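species,ecotype,climatic_region,acclimation_temp_c,heating_rate_c_per_h,o2_level_pct_airsat,ctmax_diff_c,significant,reference
Carassius auratus,benthopelagic; FW/BW,subtropical-temperate,17,10.9,200,0.9,na,13
Carassius auratus,benthopelagic; FW/BW,subtropical-temperate,17,10.9,450,1.0,na,13
Carassius auratus,benthopelagic; FW/BW,subtropical-temperate,27,7.3,200,0.21,na,13
Carassius auratus,benthopelagic; FW/BW,subtropical-temperate,27,7.3,450,0.81,na,13
Fundulus notatus,benthopelagic; FW,subtropical-temperate,30,20,160,-0.01,no,34
Notropis lutrensis,benthopelagic; FW,subtropical-temperate,30,20,160,-0.53,no,34
Pimephales vigilax,benthopelagic; FW,subtropical-temperate,30,20,160,-0.16,no,34
Fundulus heteroclitus,benthopelagic; FW/M/BW,subtropical-temperate,15,18,,0.3,no,35
Perca fluviatilis,benthopelagic (Biotest population); FW/BW,temperate,23,2,200,0.6,no,17
Perca fluviatilis,benthopelagic; FW/BW,temperate,17,2,200,1.1,yes,18
Chaenocephalus aceratus,benthopelagic; M,Antarctic,0.5,4,240,0.12,no,36
Notothenia coriiceps,benthopelagic; M,Antarctic,0.5,4,240,0.74,no,36
Bellapiscis medius,benthic (intertidal); M,temperate,21,2,200,0.13,no,9
Forsterygion lapillum,benthopelagic (intertidal/subtidal); M,temperate,21,2,200,0.43,yes,9
Atherinomorous sp.,pelagic; M,tropical,20,2,140,1.4,yes,8
Dascyllus sp.,reef associated; M,tropical,20,2,140,1.8,yes,8
Apistogramma borellii,benthopelagic; FW,tropical-subtropical,31,1.2,200,0.66,no,37
Brycon amazonicus,benthopelagic; FW,tropical,31,1.2,200,1.4,yes,37
Carnegiella strigata,pelagic; FW,tropical,31,1.2,200,0.51,yes,37
Colossoma macropomum,benthopelagic; FW,tropical,31,1.2,200,0.08,no,37
Corydoras pulcher,benthopelagic; FW,tropical,31,1.2,200,0.81,no,37
Corydoras schwartzi,benthopelagic; FW,tropical,31,1.2,200,0.48,yes,37
Paracheirodon axelrodi,pelagic; FW,tropical,31,1.2,200,0.41,yes,37
Oncorhynchus mykiss,benthopelagic; FW/M/BW,temperate,10,2,200,0.87,yes,this_study
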