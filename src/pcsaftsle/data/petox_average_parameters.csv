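name,Mw,m_over_Mw,sigma,u_kB,eps_assoc_kB,kappa_assoc
PEtOx-5,5000,0.044196,2.880186,239.926701,0,0.02
PEtOx-50,50000,0.048508,2.823947,240.522609,0,0.02
PEtOx-500,500000,0.041947,2.855100,255.331741,0,0.02
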