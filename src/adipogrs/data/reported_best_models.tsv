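term	outcome	arm	coefficient	pc2
age	WCR	MHP	-0.052	0.014
baseline_wc	WCR	MHP	-0.067	0.025
wgrs	WCR	MHP	0.959	0.222
const	WCR	MHP	-3.304
sex	WCR	LF	1.636	0.031
mets	WCR	LF	0.182	0.078
energy100	WCR	LF	-0.083	0.052
ugrs	WCR	LF	3.250	0.174
ugrs:mets	WCR	LF	-0.081	0.088
const	WCR	LF	-15.425
age	TFATL	MHP	-0.043	0.037
baseline_tfat	TFATL	MHP	0.125	0.082
wgrs	TFATL	MHP	0.915	0.276
const	TFATL	MHP	-12.092
baseline_tfat	TFATL	LF	0.194	0.060
energy100	TFATL	LF	-0.107	0.053
wgrs	TFATL	LF	2.490	0.051
wgrs:energy100	TFATL	LF	0.020	0.029
wgrs:baseline_tfat	TFATL	LF	-0.052	0.048
const	TFATL	LF	-12.130
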