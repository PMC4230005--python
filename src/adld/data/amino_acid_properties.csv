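symbol,name,mW,hI,pK1,pK2,pI,S,cN,F,vR
A,Alanine,89.079,1.8,2.34,9.69,6.01,167.2,4,7.8,67
C,Cysteine,121.145,2.5,1.96,10.28,5.07,0,2,1.9,86
D,Aspartic acid,133.089,-3.5,1.88,9.6,2.77,5,2,5.3,91
E,Glutamic acid,147.116,-3.5,2.19,9.67,3.22,8.5,2,6.3,109
F,Phenylalanine,165.177,2.8,1.83,9.13,5.48,27.6,2,3.9,135
G,Glycine,75.052,-0.4,2.34,9.6,5.97,249.9,4,7.2,48
H,Histidine,155.141,-3.2,1.82,9.17,7.59,0,2,2.3,118
I,Isoleucine,131.16,4.5,2.36,9.68,6.02,34.5,3,5.3,124
K,Lysine,146.17,-3.9,2.18,8.95,9.74,739,2,5.9,135
L,Leucine,131.16,3.8,2.36,9.6,5.98,21.7,6,9.1,124
M,Methionine,149.199,1.9,2.28,9.21,5.74,56.2,1,2.3,124
N,Asparagine,132.104,-3.5,2.02,8.8,5.41,28.5,2,4.3,96
P,Proline,115.117,1.6,1.99,10.96,6.48,1620,4,5.2,90
Q,Glutamine,146.131,-3.5,2.17,9.13,5.65,7.2,2,4.2,114
R,Arginine,174.188,-4.5,2.17,9.04,10.76,855.6,6,5.1,148
S,Serine,105.078,-0.8,2.21,9.15,5.68,422,6,6.8,73
T,Threonine,119.105,-0.7,2.11,9.62,5.87,13.2,4,5.9,93
V,Valine,117.133,4.2,2.32,9.62,5.97,58.1,4,6.6,105
W,Tryptophan,204.213,-0.9,2.38,9.39,5.89,13.6,1,1.4,163
Y,Tyrosine,181.176,-1.3,2.2,9.11,5.66,0.4,2,3.2,141
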