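ccmp2,ccmp3,ccmp5,ccmp10,chlorotype
239,106,104,115,A
239,107,104,115,B
239,106,105,116,C
240,106,105,116,D
240,107,105,116,E
240,107,104,115,F
239,107,105,115,G
240,106,104,116,H
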