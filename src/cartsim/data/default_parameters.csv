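name,default,lower,upper,varied,units,description
kon_CAR,0.1,0.001,10.0,True,per (molec um^-2) per min,CAR-antigen association rate
koff_CAR,2.0,0.02,200.0,True,per min,CAR-antigen dissociation rate
Kcat_LCKPU_CD3z,0.4,0.004,40.0,True,per min,catalytic rate of active LCK phosphorylating CD3z ITAM tyrosines
Km_LCK_CD3z,30.0,0.3,3000.0,False,au,Michaelis constant of LCK on bound CAR forms
Kcat_CD45_A1,0.8,0.008,80.0,True,per min,catalytic rate of CD45 dephosphorylating ITAM tyrosines
Km_CD45_A1,50.0,0.5,5000.0,False,au,Michaelis constant of CD45 on phospho-ITAM forms
Kcat_SHP1,0.5,0.005,50.0,True,per min,catalytic rate of active SHP1 dephosphorylating ITAM tyrosines
Km_SHP1,50.0,0.5,5000.0,False,au,Michaelis constant of SHP1 on phospho-ITAM forms
k_SHP1_act,0.1,0.001,10.0,True,per au per min,phospho-ITAM-driven SHP1 activation rate
k_SHP1_deact,0.5,0.005,50.0,True,per min,SHP1 deactivation rate
kon_ZAP,0.02,0.0002,2.0,True,per au per min,ZAP70 association with doubly phosphorylated ITAM
koff_ZAP,2.0,0.02,200.0,True,per min,ZAP70 dissociation from phospho-ITAM
Kcat_ZAP,15.0,0.15,1500.0,True,per min,catalytic rate of ITAM-docked ZAP70 phosphorylating LAT
Km_ZAP,100.0,1.0,10000.0,False,au,Michaelis constant of ZAP70 on LAT
CSKon,0.005,0.00005,0.5,True,per au per min,CSK association with active LCK
CSKoff,0.5,0.005,50.0,True,per min,CSK dissociation from LCK
kcat_CSK,2.0,0.02,200.0,True,per min,CSK-catalysed LCK inhibitory-site phosphorylation
Kcat_CD45_LCK505,0.4,0.004,40.0,True,per min,catalytic rate of CD45 reactivating inhibited LCK
Km_CD45_LCK505,100.0,1.0,10000.0,False,au,Michaelis constant of CD45 on inhibited LCK
k_LATase,0.7,0.007,70.0,True,per min,constitutive LAT dephosphorylation rate
k_SOS,300.0,3.0,30000.0,True,au per min,maximal SOS-mediated Ras exchange activity
Km_LAT_SOS,150.0,1.5,15000.0,False,au,half-saturation of SOS recruitment by phospho-LAT
Km_Ras,50.0,0.5,5000.0,False,au,Michaelis constant of SOS on Ras-GDP
k_GAP,1.0,0.01,100.0,True,per min,constitutive GAP-mediated Ras-GTP hydrolysis
k_Raf_act,2.0,0.02,200.0,True,per au per min,Ras-GTP-driven Raf activation
Km_Raf,200.0,2.0,20000.0,False,au,Michaelis constant of Raf activation
k_Raf_deact,1.0,0.01,100.0,True,per min,Raf deactivation rate
kcat_Raf_MEK,19.0,0.19,1900.0,True,per min,active Raf phosphorylating MEK (each site)
Km_MEK,10.0,0.1,1000.0,False,au,Michaelis constant of Raf on MEK forms
Vmax_MEKase,120.0,1.2,12000.0,True,au per min,MEK phosphatase maximal rate
Km_MEKase,10.0,0.1,1000.0,False,au,Michaelis constant of MEK phosphatase
kcat_MEK_ERK,2.4,0.024,240.0,True,per min,ppMEK phosphorylating ERK (each site)
Km_ERK,10.0,0.1,1000.0,False,au,Michaelis constant of MEK on ERK forms
Vmax_ERKase,120.0,1.2,12000.0,True,au per min,ERK phosphatase maximal rate
Km_ERKase,10.0,0.1,1000.0,False,au,Michaelis constant of ERK phosphatase
cd28_lck_boost,3.0,1.0,10.0,False,fold,CD28-mediated multiplicative boost of LCK catalytic rate
cd28_dock_frac,0.3,0.001,0.5,False,fraction,fraction of SOS docked per engaged CD28 adaptor route
cd28_route_eff,0.1,0.001,1.0,False,fraction,Ras-exchange efficiency of CD28-docked SOS
Km_CD28,30.0,0.3,3000.0,False,au,half-saturation of CD28-docked SOS by engaged CD28
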