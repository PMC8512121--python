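function,EHOI,EHO,SCA,SSA,GOA,WOA,BBO,MFO,PSO,HHO,eHHO
CEC01,4.76e4,1.35e7,9.83e9,3.21e9,1.61e10,1.03e10,3.52e10,7.17e9,6.75e11,9.49e4,1.66e3
CEC02,1.70e1,1.72e1,1.75e1,1.73e1,1.74e1,1.73e1,8.87e1,1.74e1,8.56e2,2.42e1,1.25e0
CEC03,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1,1.27e1
CEC04,1.28e1,1.55e1,8.32e2,3.25e1,1.51e2,2.65e2,6.95e1,1.38e2,6.92e1,3.81e1,3.60e0
CEC05,1.05e0,1.07e0,2.23e0,1.35e0,1.33e0,1.67e0,1.31e0,1.13e0,1.55e0,1.14e0,1.01e0
CEC06,8.33e0,9.45e0,1.04e1,3.79e0,6.19e0,9.14e0,5.78e0,4.92e0,1.03e1,9.96e0,1.75e0
CEC07,1.42e2,1.81e2,6.38e2,2.89e2,2.87e2,4.53e2,4.92e0,3.19e2,5.97e2,4.31e2,4.98e0
CEC08,2.69e0,3.15e0,5.77e0,5.08e0,5.49e0,5.75e0,4.81e0,5.45e0,5.10e0,3.73e0,1.44e0
CEC09,2.29e0,2.41e0,8.75e1,2.38e0,2.45e0,5.16e0,3.75e0,2.46e0,2.65e0,4.78e0,1.63e0
CEC10,1.92e1,2.11e1,2.08e1,2.03e1,2.00e1,2.05e1,2.07e1,2.02e1,2.06e1,2.04e1,1.53e1
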