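# Synthetic reconstruction of a face-perception hypothesis graph
# (V1, OFA, FFA, STS, AMG; driving input 'faces+houses' into V1;
# modulatory inputs 'faces' and 'emotions' where present).
# Edge indices are 0-based [src, dst].
regions:
- V1
- OFA
- FFA
- STS
- AMG
a_edges:
- - 0
  - 1
- - 1
  - 2
- - 1
  - 3
- - 2
  - 4
- - 3
  - 4
c_edges:
- - 0
  - 0
stimuli: 1
b_edges:
- - - 1
    - 2
- - - 2
    - 4
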