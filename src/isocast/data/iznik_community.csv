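taxon,kind,status,n,mean15N,sd15N,mean13C,sd13C,mean_TL,mean_W
Atherina boyeri,fish,translocated,10,9.19,0.35,-21.44,0.29,93.10,5.15
Capoeta tinca,fish,native,11,5.72,,-19.88,,256.00,162.00
Carassius gibelio,fish,invasive,10,7.03,0.56,-21.12,1.30,137.80,44.35
Cyprinus carpio,fish,native,4,7.62,1.72,-20.06,0.97,104.00,17.63
Gambusia holbrooki,fish,invasive,10,10.65,0.85,-17.95,0.77,40.60,0.90
Knipowitschia caucasica,fish,native,7,8.46,1.01,-20.18,1.25,27.86,0.19
Proterorhinus semilunaris,fish,native,12,7.10,1.61,-21.54,1.35,42.55,1.03
Rutilus frisii,fish,native,10,9.44,0.91,-20.85,2.11,218.40,117.45
Rutilus rutilus,fish,native,10,9.25,0.33,-22.90,0.62,143.20,27.80
Salariopsis fluviatilis,fish,native,20,7.93,1.38,-19.98,1.36,30.33,0.27
Silurus glanis,fish,native,10,12.60,3.70,-24.65,2.35,,
Vimba vimba,fish,native,10,9.89,0.91,-22.38,0.99,143.10,26.60
Pelophylax ridibundus,amphibian,native,3,7.58,1.66,-17.19,1.72,,
Macrozoobenthos,invertebrate,,1,5.25,,-20.25,,,
Phytoplankton,plankton,,2,3.79,0.23,-22.00,0.07,,
Macrophytes,producer,,2,1.23,3.48,-10.10,0.56,,
Algae,producer,,1,2.09,,-20.58,,,
Detritus,detritus,,3,5.63,4.65,-16.60,4.73,,
Zooplankton,plankton,,2,5.63,0.43,-24.27,1.07,,
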