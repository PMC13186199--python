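residue,hydrophobicity_kd,molecular_weight,vdw_volume,polarity_grantham,isoelectric_point,net_charge_ph7,hbond_donors,hbond_acceptors,flexibility,helix_propensity,sheet_propensity,max_asa,aromaticity
A,1.8,89.09,67,8.1,6.00,0,0,0,0.984,1.42,0.83,129,0
C,2.5,121.16,86,5.5,5.07,0,1,0,0.906,0.70,1.19,167,0
D,-3.5,133.10,91,13.0,2.77,-1,0,2,1.068,1.01,0.54,193,0
E,-3.5,147.13,109,12.3,3.22,-1,0,2,1.094,1.51,0.37,223,0
F,2.8,165.19,135,5.2,5.48,0,0,0,0.915,1.13,1.38,240,1
G,-0.4,75.07,48,9.0,5.97,0,0,0,1.031,0.57,0.75,104,0
H,-3.2,155.16,118,10.4,7.59,0.1,1,1,0.950,1.00,0.87,224,1
I,4.5,131.17,124,5.2,6.02,0,0,0,0.927,1.08,1.60,197,0
K,-3.9,146.19,135,11.3,9.74,1,3,0,1.102,1.16,0.74,236,0
L,3.8,131.17,124,4.9,5.98,0,0,0,0.935,1.21,1.30,201,0
M,1.9,149.21,124,5.7,5.74,0,0,0,0.952,1.45,1.05,224,0
N,-3.5,132.12,96,11.6,5.41,0,2,1,1.048,0.67,0.89,195,0
P,-1.6,115.13,90,8.0,6.30,0,0,0,1.049,0.57,0.55,159,0
Q,-3.5,146.15,114,10.5,5.65,0,2,1,1.037,1.11,1.10,225,0
R,-4.5,174.20,148,10.5,10.76,1,5,0,1.008,0.98,0.93,274,0
S,-0.8,105.09,73,9.2,5.68,0,1,1,1.046,0.77,0.75,155,0
T,-0.7,119.12,93,8.6,5.60,0,1,1,0.997,0.83,1.19,172,0
V,4.2,117.15,105,5.9,5.96,0,0,0,0.931,1.06,1.70,174,0
W,-0.9,204.23,163,5.4,5.89,0,1,0,0.904,1.08,1.37,285,1
Y,-1.3,181.19,141,6.2,5.66,0,1,1,0.929,0.69,1.47,263,1
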