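# Experimentally determined binding rate constants, dissociation constants
# for the ACTR-NCBD association (stopped-flow, 277 K, 20 mM NaPi pH 7.4,
# 150 mM NaCl; condition "TMAO" adds 0.7 M TMAO).
# kon in uM^-1 s^-1, koff in s^-1, kd in nM.
actr_variant,ncbd_variant,condition,koff,koff_err,kon,kon_err,kd,kd_err,temperature
WT,Y2108W,buffer,2.2,0.1,21.3,0.4,103,7,277
WT,Y2108W,TMAO,0.49,0.02,95,10,5.2,0.8,277
WT,Q2068A,buffer,2.7,0.1,28.1,0.6,96,6,277
WT,T2073A,buffer,1.08,0.03,41,2,26,2,277
WT,N2088A,buffer,2.3,0.1,22.2,0.8,104,8,277
WT,A2098G,TMAO,1.68,0.04,33.8,0.3,50,2,277
E1065A,Y2108W,buffer,2.2,0.1,21.3,0.6,104,8,277
E1066A,Y2108W,buffer,1.73,0.02,22.4,0.3,77,2,277
P1074A,Y2108W,buffer,1.9,0.1,18.5,0.6,103,9,277
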