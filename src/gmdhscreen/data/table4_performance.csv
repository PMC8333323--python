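outcome,classifier,se,se_lo,se_hi,sp,sp_lo,sp_hi,pr,pr_lo,pr_hi,npv,npv_lo,npv_hi,acc,acc_lo,acc_hi,auc,auc_lo,auc_hi,dor,dor_lo,dor_hi,dp,dp_lo,dp_hi,mcc,mcc_lo,mcc_hi,kappa,kappa_lo,kappa_hi
depression,GMDH,79,77,81,97,96,97,87,85,88,95,94,95,93,93,94,0.88,0.87,0.89,121.6,103.2,143.4,2.04,1.97,2.11,0.79,0.78,0.80,0.79,0.77,0.80
depression,LDA,62,60,64,66,65,67,31,30,33,87,87,88,65,64,66,0.64,0.63,0.65,3.2,2.9,3.5,0.48,0.44,0.53,0.23,0.21,0.25,0.20,0.18,0.22
depression,SVM,19,17,21,91,91,92,36,33,39,82,81,83,77,76,78,0.55,0.54,0.57,2.5,2.2,2.9,0.39,0.33,0.45,0.14,0.12,0.15,0.13,0.10,0.16
depression,MLP,10,9,12,98,97,98,57,52,62,81,81,82,80,80,81,0.54,0.53,0.56,5.9,4.7,7.2,0.75,0.66,0.84,0.18,0.16,0.20,0.12,0.09,0.16
mild_moderate,GMDH,71,68,74,69,68,70,22,21,24,95,94,96,69,68,70,0.70,0.68,0.72,5.5,4.8,6.2,0.72,0.66,0.78,0.26,0.24,0.28,0.20,0.18,0.23
mild_moderate,LDA,64,62,67,70,69,71,21,20,23,94,94,95,70,69,71,0.67,0.66,0.69,4.3,3.7,4.8,0.62,0.56,0.67,0.23,0.21,0.25,0.18,0.16,0.21
mild_moderate,SVM,14,12,16,96,95,96,29,25,33,90,89,91,87,86,87,0.55,0.53,0.57,3.7,3.0,4.5,0.55,0.47,0.63,0.13,0.12,0.15,0.12,0.08,0.17
mild_moderate,MLP,4,3,6,99,99,100,50,40,60,89,89,90,89,88,89,0.52,0.51,0.54,8.4,5.6,12.4,0.90,0.73,1.07,0.12,0.10,0.14,0.06,0.01,0.11
worriedness,GMDH,71,69,73,86,85,88,61,59,63,91,90,91,82,81,83,0.79,0.77,0.80,15.0,13.5,16.8,1.15,1.10,1.20,0.54,0.53,0.56,0.54,0.52,0.56
worriedness,LDA,62,60,64,65,64,66,35,34,37,84,84,85,64,63,65,0.63,0.62,0.65,3.0,2.7,3.3,0.46,0.42,0.50,0.23,0.21,0.25,0.21,0.19,0.23
worriedness,SVM,23,22,25,88,87,89,38,35,40,79,78,80,73,72,74,0.56,0.54,0.57,2.2,2.0,2.5,0.34,0.29,0.39,0.14,0.12,0.16,0.13,0.10,0.16
worriedness,MLP,13,12,14,97,96,97,54,50,58,78,77,79,77,76,77,0.55,0.53,0.56,4.1,3.5,4.9,0.60,0.53,0.67,0.17,0.16,0.19,0.13,0.10,0.16
psychiatric,GMDH,78,77,79,71,70,72,59,58,61,86,85,87,73,72,75,0.75,0.73,0.76,8.7,7.9,9.5,0.92,0.88,0.96,0.47,0.45,0.48,0.46,0.44,0.47
psychiatric,LDA,63,61,64,66,65,67,50,48,51,76,75,78,65,63,66,0.64,0.63,0.65,3.2,3.0,3.5,0.50,0.46,0.53,0.27,0.26,0.29,0.27,0.25,0.29
psychiatric,SVM,32,30,33,87,86,87,56,54,58,70,69,71,67,66,68,0.59,0.58,0.60,3.0,2.7,3.3,0.47,0.43,0.51,0.22,0.20,0.24,0.20,0.18,0.23
psychiatric,MLP,33,31,34,88,87,89,60,58,62,71,70,72,69,68,70,0.60,0.59,0.61,3.6,3.3,4.0,0.54,0.50,0.59,0.25,0.23,0.27,0.23,0.21,0.25
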