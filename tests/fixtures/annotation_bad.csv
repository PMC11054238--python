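foot,start_s,end_s
left,2.0,3.1
left,5.0,4.0
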