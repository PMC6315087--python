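((gambiae:0.08,coluzzii:0.08):0.12,arabiensis:0.25,(quadriannulatus:0.15,merus:0.15):0.1);
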