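esu	autochthonous
Southern Switzerland	1
Swiss Plateau	1
Central Europe	1
Western Europe	1
Eastern Europe	0
Italy	0
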