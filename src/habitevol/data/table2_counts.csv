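from_code,to_code,count
2,1,2
2,3,6
2,4,1
2,5,2
2,6,1
3,2,1
3,4,1
4,5,2
5,3,1
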