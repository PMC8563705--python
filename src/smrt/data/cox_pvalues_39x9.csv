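dataset,SNF,CIMLR,NEMO,moCluster,iClusterBayes,LRACluster,MCCA,IntNMF,SMRT
ACC,4.34e-05,3.96e-01,2.07e-04,2.63e-09,4.26e-03,2.46e-03,1.24e-08,6.11e-03,1.33e-02
BLCA,1.09e-01,3.09e-01,6.74e-02,3.13e-01,4.95e-01,7.42e-02,3.57e-01,3.43e-02,1.95e-02
BRCA,1.19e-01,4.95e-03,2.93e-02,2.58e-01,3.07e-02,3.90e-01,3.80e-04,2.53e-01,1.96e-03
CESC,5.10e-01,1.90e-01,3.33e-01,1.81e-01,1.69e-01,2.90e-01,6.69e-01,8.89e-01,2.95e-02
CHOL,5.72e-01,3.35e-01,3.02e-01,5.17e-01,6.51e-01,6.93e-01,4.50e-01,9.63e-01,3.01e-02
COAD,1.28e-01,2.52e-01,6.76e-01,3.73e-01,6.47e-01,5.05e-01,6.20e-01,5.35e-01,1.44e-03
COADREAD,6.60e-01,1.35e-01,8.11e-01,4.72e-02,2.55e-01,7.47e-01,7.87e-01,4.76e-01,2.89e-03
DLBC,7.55e-01,7.44e-01,3.53e-01,9.82e-01,7.42e-01,8.94e-01,8.15e-01,7.28e-01,4.74e-01
ESCA,3.92e-01,3.91e-01,3.92e-01,5.01e-01,3.75e-01,1.71e-01,2.25e-01,4.90e-01,3.30e-01
GBM,2.08e-02,8.11e-02,1.49e-04,5.12e-01,1.24e-01,5.37e-01,3.69e-01,7.04e-01,8.75e-05
GBMLGG,4.75e-14,6.36e-10,2.31e-17,6.46e-16,8.66e-12,8.04e-14,3.83e-07,1.25e-10,7.48e-17
HNSC,3.66e-01,6.19e-01,7.41e-05,2.44e-01,1.42e-01,3.27e-01,9.88e-01,1.55e-01,4.56e-02
KICH,7.01e-01,4.63e-01,8.14e-14,0.00e+00,4.03e-01,2.10e-01,8.08e-01,6.61e-01,2.77e-02
KIPAN,2.11e-07,9.84e-05,4.81e-08,4.04e-13,2.16e-08,4.21e-08,3.82e-03,4.36e-04,1.16e-11
KIRC,6.91e-01,9.79e-01,2.46e-01,1.76e-01,6.70e-01,1.76e-01,1.32e-01,7.29e-01,5.98e-05
KIRP,5.33e-03,1.85e-02,8.42e-18,1.00e+00,4.60e-02,5.97e-03,2.49e-02,1.93e-01,1.15e-09
LAML,1.73e-03,1.24e-02,5.14e-04,7.00e-01,9.38e-01,1.19e-01,1.75e-02,7.78e-02,8.72e-04
LGG,1.60e-14,7.14e-15,1.17e-17,3.52e-01,6.08e-03,1.01e-01,1.16e-09,4.04e-02,4.26e-15
LIHC,3.34e-01,1.28e-01,1.09e-03,8.25e-01,2.57e-01,2.93e-01,5.04e-01,8.80e-01,7.04e-01
LUAD,5.01e-01,3.73e-01,7.51e-03,5.92e-01,2.55e-02,1.49e-01,2.08e-01,8.21e-03,4.66e-01
LUSC,8.71e-02,3.91e-02,1.32e-01,7.04e-01,5.11e-01,9.05e-01,2.88e-01,6.75e-01,8.37e-03
MESO,4.24e-04,1.72e-02,7.94e-04,7.29e-02,8.66e-05,2.77e-01,5.53e-04,3.85e-04,7.34e-04
OV,4.45e-01,5.88e-01,6.95e-01,9.73e-01,4.35e-01,6.47e-01,7.78e-01,9.60e-01,6.81e-01
PAAD,7.36e-04,2.03e-03,1.44e-03,2.96e-03,4.19e-03,4.86e-04,3.18e-01,3.45e-02,2.73e-04
PCPG,3.32e-01,4.57e-01,2.57e-01,3.11e-01,3.39e-01,1.41e-01,6.63e-01,7.67e-01,8.66e-01
PRAD,4.75e-01,6.95e-01,6.61e-01,9.56e-01,3.73e-01,4.97e-01,7.07e-01,3.90e-01,3.49e-01
READ,7.62e-01,3.35e-01,6.27e-01,1.00e+00,5.68e-01,2.72e-01,3.53e-01,3.41e-01,2.35e-02
SARC,4.37e-02,5.58e-02,7.23e-02,3.37e-02,3.07e-01,6.36e-01,9.54e-02,2.83e-01,3.03e-02
SKCM,4.78e-01,7.54e-05,6.37e-04,4.30e-03,4.67e-03,3.92e-02,1.90e-01,1.48e-03,1.05e-01
STAD,4.07e-02,5.11e-01,1.02e-01,4.83e-01,6.25e-01,3.08e-01,3.16e-01,5.55e-01,1.86e-04
STES,1.57e-01,3.41e-02,1.18e-01,4.97e-01,4.13e-03,5.92e-01,6.35e-02,8.45e-02,1.51e-02
TGCT,8.38e-01,8.39e-01,8.38e-01,5.89e-01,2.96e-01,3.74e-01,5.65e-01,5.41e-01,5.31e-01
THCA,6.20e-01,8.62e-03,3.87e-02,5.11e-01,7.42e-01,5.51e-01,3.87e-01,1.75e-02,8.82e-02
THYM,9.69e-02,1.15e-01,7.11e-02,8.89e-05,7.06e-02,5.96e-01,5.47e-02,1.38e-01,1.33e-02
UCEC,1.81e-02,1.70e-01,1.64e-01,6.88e-01,1.65e-01,8.61e-01,1.58e-02,3.02e-03,4.83e-03
UCS,8.59e-01,3.59e-01,7.16e-01,1.68e-01,8.76e-01,8.34e-01,5.85e-01,6.27e-01,4.26e-01
UVM,1.67e-04,5.80e-04,1.67e-04,5.50e-01,9.19e-02,4.92e-03,2.06e-04,2.20e-05,6.43e-03
M_Discovery,2.26e-05,3.15e-12,1.16e-11,2.87e-01,9.16e-01,4.32e-06,4.59e-10,2.01e-07,3.25e-10
M_Validation,1.04e-02,4.68e-06,2.75e-07,1.57e-01,1.97e-01,1.28e-01,7.46e-04,9.16e-04,2.66e-05
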