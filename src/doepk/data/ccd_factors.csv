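name,symbol,low,centre,high,units
Methanol concentration,A,10,20,30,% v/v
Mobile phase pH,B,2.5,3.5,4.0,pH units
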