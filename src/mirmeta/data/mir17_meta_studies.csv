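study,n1,mean1,sd1,n2,mean2,sd2,sample_type
GSE93415,20,0.834,1.089,20,-0.656,0.998,tissue
GSE78775,28,5.590,0.441,28,6.062,0.835,tissue
GSE63121,15,6.606,2.544,15,7.507,0.819,tissue
GSE54397,16,303.974,308.340,16,140.914,110.512,tissue
GSE26595,60,12.437,0.531,8,12.531,0.190,tissue
GSE33743,37,7.169,0.306,4,6.986,0.108,tissue
GSE30070,90,-0.272,0.278,34,-0.4851,0.178,tissue
GSE28770,22,399.372,336.723,22,285.519,229.129,tissue
TCGA,412,1224.398,1092.287,41,333.692,159.356,tissue
Chen,40,1.794,0.326,40,0.916,0.239,tissue
Zhang,56,2.427,1.664,56,1.605,1.601,tissue
Wu,28,3.595,2.699,28,2.273,2.270,tissue
WangJL,32,1.349,0.489,32,0.649,0.489,tissue
GSE85589,7,2.640,0.696,19,3.014,0.477,serum
GSE59856,50,3.722,0.982,150,4.393,0.730,serum
GSE61741,13,6442.375,2017.992,94,8987.255,4418.810,blood
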