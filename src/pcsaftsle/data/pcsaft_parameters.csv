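name,kind,Mw,m_over_Mw,sigma,u_kB,eps_assoc_kB,kappa_assoc,n_donor,n_acceptor
FEL,api,384.253,0.03000,3.2050,234.5000,1581.1000,0.02,2,2
GRI,api,352.767,0.04018,3.3720,221.3000,1985.5000,0.02,2,2
IBU,api,206.285,0.02637,4.0179,309.4000,516.4691,0.089457,2,2
IND,api,357.790,0.02207,3.8225,374.5100,1295.4320,0.011350,3,3
NAP,api,230.263,0.01916,4.1142,470.9200,1202.6520,0.009524,2,2
NIF,api,346.339,0.02347,3.5810,309.4400,1221.5800,0.02,2,2
PCM,api,151.165,0.02141,3.9819,432.0900,1635.9150,0.054320,2,2
PZQ,api,312.413,0.01991,4.0900,327.1000,0,0.02,0,2
PVP K12,polymer,2500,0.04070,2.7100,205.599,0,0.02,22,22
PVP VA 64,polymer,65000,0.03720,2.9470,205.271,0,0.02,653,653
SOL,polymer,118000,0.05400,2.8090,225.000,0,0.02,2486,2486
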