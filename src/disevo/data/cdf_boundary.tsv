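# Default CDF boundary, version 1.
# calibrated on synthetic compositions v1: 200 ordered + 200 disordered
# length-300 sequences, window 51, seeds 20140101/20140102
threshold	boundary
0.1	0.450650
0.2	0.485075
0.3	0.494442
0.4	0.497417
0.5	0.499267
0.6	0.502158
0.7	0.512833
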