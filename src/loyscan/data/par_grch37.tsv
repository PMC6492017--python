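chromosome	name	start	end
X	PAR1	60000	2699520
X	PAR2	154931043	155260560
Y	PAR1	10000	2649520
Y	PAR2	59034049	59363566
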