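# Synthetic quasi-chemical contact-energy surrogate (dimensionless).
# Generated from the Kyte-Doolittle hydropathy scale as
#   e(a,b) = -(h_a + h_b)/(2*4.5), shifted to zero mean over the 210
# unique pairs, so entries encode *relative* pairing propensities
# (hydrophobic-hydrophobic most attractive).  This is a stand-in for a
# statistical (Miyazawa-Jernigan-type) contact matrix, not a published
# parameter set; it is symmetric by construction.
	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.508889	-0.586667	0.080000	0.080000	-0.620000	-0.264444	0.046667	-0.808889	0.124444	-0.731111	-0.520000	0.080000	-0.131111	0.080000	0.191111	-0.220000	-0.231111	-0.775556	-0.208889	-0.164444
C	-0.586667	-0.664444	0.002222	0.002222	-0.697778	-0.342222	-0.031111	-0.886667	0.046667	-0.808889	-0.597778	0.002222	-0.208889	0.002222	0.113333	-0.297778	-0.308889	-0.853333	-0.286667	-0.242222
D	0.080000	0.002222	0.668889	0.668889	-0.031111	0.324444	0.635556	-0.220000	0.713333	-0.142222	0.068889	0.668889	0.457778	0.668889	0.780000	0.368889	0.357778	-0.186667	0.380000	0.424444
E	0.080000	0.002222	0.668889	0.668889	-0.031111	0.324444	0.635556	-0.220000	0.713333	-0.142222	0.068889	0.668889	0.457778	0.668889	0.780000	0.368889	0.357778	-0.186667	0.380000	0.424444
F	-0.620000	-0.697778	-0.031111	-0.031111	-0.731111	-0.375556	-0.064444	-0.920000	0.013333	-0.842222	-0.631111	-0.031111	-0.242222	-0.031111	0.080000	-0.331111	-0.342222	-0.886667	-0.320000	-0.275556
G	-0.264444	-0.342222	0.324444	0.324444	-0.375556	-0.020000	0.291111	-0.564444	0.368889	-0.486667	-0.275556	0.324444	0.113333	0.324444	0.435556	0.024444	0.013333	-0.531111	0.035556	0.080000
H	0.046667	-0.031111	0.635556	0.635556	-0.064444	0.291111	0.602222	-0.253333	0.680000	-0.175556	0.035556	0.635556	0.424444	0.635556	0.746667	0.335556	0.324444	-0.220000	0.346667	0.391111
I	-0.808889	-0.886667	-0.220000	-0.220000	-0.920000	-0.564444	-0.253333	-1.108889	-0.175556	-1.031111	-0.820000	-0.220000	-0.431111	-0.220000	-0.108889	-0.520000	-0.531111	-1.075556	-0.508889	-0.464444
K	0.124444	0.046667	0.713333	0.713333	0.013333	0.368889	0.680000	-0.175556	0.757778	-0.097778	0.113333	0.713333	0.502222	0.713333	0.824444	0.413333	0.402222	-0.142222	0.424444	0.468889
L	-0.731111	-0.808889	-0.142222	-0.142222	-0.842222	-0.486667	-0.175556	-1.031111	-0.097778	-0.953333	-0.742222	-0.142222	-0.353333	-0.142222	-0.031111	-0.442222	-0.453333	-0.997778	-0.431111	-0.386667
M	-0.520000	-0.597778	0.068889	0.068889	-0.631111	-0.275556	0.035556	-0.820000	0.113333	-0.742222	-0.531111	0.068889	-0.142222	0.068889	0.180000	-0.231111	-0.242222	-0.786667	-0.220000	-0.175556
N	0.080000	0.002222	0.668889	0.668889	-0.031111	0.324444	0.635556	-0.220000	0.713333	-0.142222	0.068889	0.668889	0.457778	0.668889	0.780000	0.368889	0.357778	-0.186667	0.380000	0.424444
P	-0.131111	-0.208889	0.457778	0.457778	-0.242222	0.113333	0.424444	-0.431111	0.502222	-0.353333	-0.142222	0.457778	0.246667	0.457778	0.568889	0.157778	0.146667	-0.397778	0.168889	0.213333
Q	0.080000	0.002222	0.668889	0.668889	-0.031111	0.324444	0.635556	-0.220000	0.713333	-0.142222	0.068889	0.668889	0.457778	0.668889	0.780000	0.368889	0.357778	-0.186667	0.380000	0.424444
R	0.191111	0.113333	0.780000	0.780000	0.080000	0.435556	0.746667	-0.108889	0.824444	-0.031111	0.180000	0.780000	0.568889	0.780000	0.891111	0.480000	0.468889	-0.075556	0.491111	0.535556
S	-0.220000	-0.297778	0.368889	0.368889	-0.331111	0.024444	0.335556	-0.520000	0.413333	-0.442222	-0.231111	0.368889	0.157778	0.368889	0.480000	0.068889	0.057778	-0.486667	0.080000	0.124444
T	-0.231111	-0.308889	0.357778	0.357778	-0.342222	0.013333	0.324444	-0.531111	0.402222	-0.453333	-0.242222	0.357778	0.146667	0.357778	0.468889	0.057778	0.046667	-0.497778	0.068889	0.113333
V	-0.775556	-0.853333	-0.186667	-0.186667	-0.886667	-0.531111	-0.220000	-1.075556	-0.142222	-0.997778	-0.786667	-0.186667	-0.397778	-0.186667	-0.075556	-0.486667	-0.497778	-1.042222	-0.475556	-0.431111
W	-0.208889	-0.286667	0.380000	0.380000	-0.320000	0.035556	0.346667	-0.508889	0.424444	-0.431111	-0.220000	0.380000	0.168889	0.380000	0.491111	0.080000	0.068889	-0.475556	0.091111	0.135556
Y	-0.164444	-0.242222	0.424444	0.424444	-0.275556	0.080000	0.391111	-0.464444	0.468889	-0.386667	-0.175556	0.424444	0.213333	0.424444	0.535556	0.124444	0.113333	-0.431111	0.135556	0.180000
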