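9
11
13
28
30
37
47
57
60
61
67
70
71
74
78
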