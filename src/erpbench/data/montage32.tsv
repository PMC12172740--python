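label	x	y	z
Fp1	-0.309016994375	0.951056516295	0.000000000000
Fp2	0.309016994375	0.951056516295	0.000000000000
F7	-0.809016994375	0.587785252292	0.000000000000
F3	-0.560728574230	0.692442121905	0.453990499740
Fz	0.000000000000	0.707106781187	0.707106781187
F4	0.560728574230	0.692442121905	0.453990499740
F8	0.809016994375	0.587785252292	0.000000000000
FC5	-0.816527839214	0.452608772040	0.358367949545
FC1	-0.225777831538	0.462913155347	0.857167300702
FCz	0.000000000000	0.382683432365	0.923879532511
FC2	0.225777831538	0.462913155347	0.857167300702
FC6	0.816527839214	0.452608772040	0.358367949545
T7	-1.000000000000	0.000000000000	0.000000000000
C3	-0.707106781187	0.000000000000	0.707106781187
Cz	0.000000000000	0.000000000000	1.000000000000
C4	0.707106781187	0.000000000000	0.707106781187
T8	1.000000000000	0.000000000000	0.000000000000
TP9	-0.904508497187	-0.293892626146	-0.309016994375
CP5	-0.816527839214	-0.452608772040	0.358367949545
CP1	-0.225777831538	-0.462913155347	0.857167300702
CP2	0.225777831538	-0.462913155347	0.857167300702
CP6	0.816527839214	-0.452608772040	0.358367949545
TP10	0.904508497187	-0.293892626146	-0.309016994375
P7	-0.809016994375	-0.587785252292	0.000000000000
P3	-0.560728574230	-0.692442121905	0.453990499740
Pz	-0.000000000000	-0.707106781187	0.707106781187
P4	0.560728574230	-0.692442121905	0.453990499740
P8	0.809016994375	-0.587785252292	0.000000000000
POz	-0.000000000000	-0.923879532511	0.382683432365
O1	-0.309016994375	-0.951056516295	0.000000000000
Oz	-0.000000000000	-1.000000000000	0.000000000000
O2	0.309016994375	-0.951056516295	0.000000000000
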