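variability	vocoder	training	jnd_mean_st	jnd_sd_st
variable	non-vocoded	trained	1.52	1.30
variable	non-vocoded	untrained	1.95	2.40
variable	vocoded	trained	10.41	3.03
variable	vocoded	untrained	9.31	4.48
fixed	non-vocoded	trained	1.43	2.29
fixed	non-vocoded	untrained	0.90	0.59
fixed	vocoded	trained	4.70	2.33
fixed	vocoded	untrained	4.91	3.20
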