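imgt	original
TRBV1	Vb2
TRBV2	Vb4
TRBV4	Vb10
TRBV5	Vb1
TRBV12-1	Vb5.1
TRBV12-2	Vb5.2
TRBV13-1	Vb8.3
TRBV13-2	Vb8.2
TRBV13-3	Vb8.1
TRBV14	Vb13
TRBV15	Vb12
TRBV16	Vb11
TRBV17	Vb9
TRBV19	Vb6
TRBV20	Vb15
TRBV26	Vb3
TRBV29	Vb7
TRBV30	Vb20
TRBV31	Vb14
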