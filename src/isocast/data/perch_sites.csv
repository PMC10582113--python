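taxon,kind,status,system,site,mean15N,mean13C,mean_TL,mean_W
Perca fluviatilis (Gala),fish,native,lake,Gala,15.8,-27.5,153.0,59.9
Perca fluviatilis (Sigirci),fish,native,lake,Sigirci,15.2,-23.6,172.6,111.8
Perca fluviatilis (Bayat),fish,translocated,reservoir,Bayat,7.9,-28.5,158.0,44.8
Perca fluviatilis (Ozburun),fish,translocated,reservoir,Ozburun,13.2,-28.4,169.3,61.4
Perca fluviatilis (Seyitler),fish,translocated,reservoir,Seyitler,13.8,-21.9,229.3,174.2
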