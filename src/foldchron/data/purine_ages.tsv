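family	nd
c.37.1.12	0
c.37.1.20	0.004
c.94.1.1	0.033
c.23.16.1	0.057
c.37.1.10	0.057
c.30.1.1	0.061
d.142.1.2	0.061
c.61.1.1	0.069
c.37.1.1	0.073
a.127.1.1	0.094
d.143.1.1	0.188
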