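foot,start_s,end_s
left,2.0,3.1
left,3.1,4.2
left,4.2,5.3
left,5.3,6.4
left,6.4,7.5
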